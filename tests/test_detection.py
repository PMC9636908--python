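import warnings

import pytest

from conftest import bundle_variants, run_bundle

from bpscan.database import MergedBP
from bpscan.detection import (
    VariantRecord,
    classify_variant,
    detect,
    hit_offsets,
    undetected_variants,
)
from bpscan.fixtures import FixtureSpec, generate_fixture, mirror_bundle
from bpscan.io import GenomeSequence, TranscriptModel
from bpscan.introns import extract_introns, map_bp_to_introns


def snv(pos, contig="c", ref="A", alt="G"):
    return VariantRecord(contig, pos, ".", ref, alt, "snv", (pos, pos))


def deletion(start, length, contig="c"):
    return VariantRecord(
        contig, start, ".", "N" * length, "", f"{length} nt-deletion",
        (start, start + length - 1),
    )


def insertion(pos, seq="TT", contig="c"):
    return VariantRecord(
        contig, pos, ".", "", seq, f"{len(seq)} nt-insertion", (pos - 1, pos)
    )


def bp(pos, strand="+", contig="c"):
    return MergedBP(contig, pos, strand, "A", ("d1", "d2"), "mBP")


# --- variant typing ---------------------------------------------------------


@pytest.mark.parametrize(
    "ref,alt,var_type,interval,is_complex",
    [
        ("A", "T", "snv", (100, 100), False),
        ("ATTGC", "", "5 nt-deletion", (100, 104), False),
        ("", "TT", "2 nt-insertion", (99, 100), False),
        ("ATTG", "CC", "4 nt-deletion", (100, 103), True),
    ],
)
def test_classify_variant(ref, alt, var_type, interval, is_complex):
    assert classify_variant(ref, alt, pos=100) == (var_type, interval, is_complex)


def test_classify_variant_rejects_identity():
    with pytest.raises(ValueError):
        classify_variant("A", "A")


# --- hit offsets ------------------------------------------------------------


def test_snv_hits_plus_strand():
    assert hit_offsets(snv(100), bp(100)) == (0,)
    assert hit_offsets(snv(98), bp(100)) == (-2,)
    assert hit_offsets(snv(97), bp(100)) == ()  # BP-3: window boundary
    assert hit_offsets(snv(101), bp(100)) == ()  # BP+1


def test_snv_hits_minus_strand():
    # on minus, BP-2 lies at a *higher* genomic coordinate
    assert hit_offsets(snv(102), bp(100, "-")) == (-2,)
    assert hit_offsets(snv(98), bp(100, "-")) == ()


def test_deletion_hits_covered_offsets():
    assert hit_offsets(deletion(90, 20), bp(100)) == (-2, -1, 0)  # whole motif
    assert hit_offsets(deletion(98, 1), bp(100)) == (-2,)
    assert hit_offsets(deletion(99, 2), bp(100)) == (-1, 0)  # partial
    assert hit_offsets(deletion(101, 5), bp(100)) == ()
    # minus strand: BP-2 and BP-1 sit at genomic 102 and 101
    assert hit_offsets(deletion(101, 2), bp(100, "-")) == (-2, -1)


def test_insertion_hits_flanking_pair_only_inside_window():
    assert hit_offsets(insertion(100), bp(100)) == (-1, 0)
    assert hit_offsets(insertion(99), bp(100)) == (-2, -1)
    assert hit_offsets(insertion(98), bp(100)) == ()  # breakpoint at -3/-2
    assert hit_offsets(insertion(101), bp(100)) == ()  # breakpoint at 0/+1


def test_wrong_contig_never_hits():
    assert hit_offsets(snv(100, contig="other"), bp(100)) == ()


# --- detection window fuzzing ----------------------------------------------


def test_hits_occur_exactly_in_window():
    """SNVs planted at offsets -100..+10 hit their BP iff offset in {-2,-1,0}."""
    spec = FixtureSpec(
        seed=13,
        n_genes=40,
        intron_length_range=(150, 220),
        bp_per_intron=(1,),
        variant_offsets=tuple(range(-100, 11)),
    )
    bundle = generate_fixture(spec)
    variants = {v.id: v for v in bundle_variants(bundle)}
    checked = 0
    for entry in bundle.manifest["variants"]:
        variant = variants[entry["id"]]
        target = bp(entry["target_bp"], entry["strand"], entry["contig"])
        hits = hit_offsets(variant, target)
        if entry["offset"] in (-2, -1, 0):
            assert hits == (entry["offset"],)
        else:
            assert hits == ()
        checked += 1
    assert checked >= 100


# --- full detection vs brute force -----------------------------------------


def _brute_force(variants, mapped):
    found = set()
    for v in variants:
        for m in mapped:
            hits = hit_offsets(v, m)
            if hits:
                found.add((v.key, m.bp.bp_name, m.intron.key, hits))
    return found


def test_detect_agrees_with_brute_force_scan():
    spec = FixtureSpec(
        seed=29,
        n_genes=80,
        bp_per_intron=(1, 2, 3, 4),
        variant_offsets=tuple(range(-6, 4)) * 20,
        n_random_variants=900,
    )
    bundle = generate_fixture(spec)
    assert len(bundle.manifest["bps"]) >= 200
    assert {e["strand"] for e in bundle.manifest["bps"]} == {"+", "-"}
    variants = bundle_variants(bundle)
    assert len(variants) >= 1000
    run = run_bundle(bundle)
    got = {
        (r.variant.key, r.mapped.bp.bp_name, r.mapped.intron.key, r.hit_positions)
        for r in run.results
    }
    assert got == _brute_force(variants, run.mapped)


def test_strand_mirror_invariance():
    spec = FixtureSpec(
        seed=31,
        n_genes=30,
        bp_per_intron=(1, 2, 3),
        variant_offsets=tuple(range(-5, 3)) * 6,
        n_random_variants=120,
    )
    bundle = generate_fixture(spec)
    mirrored = mirror_bundle(bundle)

    def signature(run):
        sig = {}
        for r in run.results:
            sig.setdefault(r.variant.id, set()).add(
                (
                    r.hit_positions,
                    r.mapped.distance_to_3ss,
                    r.mapped.rank,
                    r.mapped.total_in_intron,
                )
            )
        return sig

    assert signature(run_bundle(bundle)) == signature(run_bundle(mirrored))


# --- detection bookkeeping --------------------------------------------------


def _toy_scene(n_transcripts=1):
    # exon1 [1,150], intron [151,240] with GT..AG, exon2 [241,390]
    seq = "G" * 150 + "GT" + "G" * 60 + "GGTTGATGG" + "G" * 17 + "AG" + "G" * 150
    genome = {"c": GenomeSequence("c", seq)}
    txs = [
        TranscriptModel(f"T{i}", "GENE", "c", "+", [(1, 150), (241, 390)], i == 0)
        for i in range(n_transcripts)
    ]
    introns = extract_introns(txs)
    bp_pos = 150 + 2 + 60 + 6  # the A of TTGAT
    mapped = map_bp_to_introns([bp(bp_pos)], introns, genome)
    return genome, mapped, bp_pos


def test_one_row_per_transcript_membership():
    _, mapped, bp_pos = _toy_scene(n_transcripts=2)
    results = detect([snv(bp_pos)], mapped)
    assert len(results) == 2
    assert {r.transcript_id for r in results} == {"T0", "T1"}
    assert len({r.mapped.bp.bp_name for r in results}) == 1

    canon = detect([snv(bp_pos)], mapped, canonical_only=True)
    assert [r.transcript_id for r in canon] == ["T0"]


def test_empty_input_and_unknown_contig():
    _, mapped, bp_pos = _toy_scene()
    assert detect([], mapped) == []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        results = detect([snv(bp_pos, contig="chrUn")], mapped)
    assert results == []
    assert any("absent" in str(w.message) for w in caught)


def test_min_score_filters_rows():
    _, mapped, bp_pos = _toy_scene()
    (kept,) = detect([snv(bp_pos)], mapped, min_score=1.0)
    above = kept.score.total + 0.1
    assert detect([snv(bp_pos)], mapped, min_score=above) == []


def test_undetected_side_report():
    _, mapped, bp_pos = _toy_scene()
    variants = [snv(bp_pos), snv(bp_pos - 50)]
    results = detect(variants, mapped)
    missed = undetected_variants(variants, results)
    assert [v.pos for v in missed] == [bp_pos - 50]


def test_output_order_is_deterministic():
    _, mapped, bp_pos = _toy_scene(n_transcripts=3)
    variants = [snv(bp_pos - 2), snv(bp_pos)]
    first = detect(variants, mapped)
    second = detect(list(reversed(variants)), mapped)
    key = lambda r: (r.variant.key, r.transcript_id)  # noqa: E731
    assert [key(r) for r in first] == [key(r) for r in second]
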