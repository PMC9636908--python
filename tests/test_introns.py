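import numpy as np
import pytest

from bpscan.database import MergedBP, reverse_complement
from bpscan.fixtures import FixtureSpec, generate_fixture
from bpscan.introns import (
    PROXIMAL_WINDOW,
    annotate_intron_dinucleotides,
    binding_energy,
    classify_intron,
    extract_introns,
    intron_bp_distribution,
    map_bp_to_introns,
)
from bpscan.io import GenomeSequence, TranscriptModel


def tx(tid="T1", strand="+", exons=((1, 100), (201, 300)), contig="c", gene="G"):
    return TranscriptModel(tid, gene, contig, strand, list(exons), True)


def merged(pos, strand="+", contig="c", base="A"):
    return MergedBP(contig, pos, strand, base, ("d1", "d2"), "mBP")


# --- extraction -------------------------------------------------------------


def test_extract_single_intron():
    (intron,) = extract_introns([tx()])
    assert (intron.start, intron.end, intron.length) == (101, 200, 100)
    assert intron.transcript_memberships == [("T1", 1, True, "G")]


def test_shared_intron_deduplicates():
    introns = extract_introns([tx("T1"), tx("T2")])
    assert len(introns) == 1
    assert [m[0] for m in introns[0].transcript_memberships] == ["T1", "T2"]


def test_minus_strand_numbering_and_dinucleotides():
    exons = ((1, 100), (201, 300), (401, 500))
    plus = extract_introns([tx(strand="+", exons=exons)])
    minus = extract_introns([tx(strand="-", exons=exons)])
    assert [m[1] for i in plus for m in i.transcript_memberships] == [1, 2]
    # transcript direction reversed: the genomically-last gap is intron 1
    assert {(i.start, m[1]) for i in minus for m in i.transcript_memberships} == {
        (101, 2),
        (301, 1),
    }
    # donor of a minus-strand intron reads from its genomic end, complemented
    seq = ["A"] * 500
    seq[198], seq[199] = "C", "T"  # genomic 199-200, the intron's high end
    seq[100], seq[101] = "A", "C"  # genomic 101-102, the intron's low end
    genome = {"c": GenomeSequence("c", "".join(seq))}
    annotate_intron_dinucleotides(genome, minus)
    intron = next(i for i in minus if i.start == 101)
    assert intron.donor_dinucleotide == reverse_complement("CT")  # "AG"
    assert intron.acceptor_dinucleotide == reverse_complement("AC")  # "GT"


def test_overlapping_exons_rejected():
    with pytest.raises(ValueError, match="overlap"):
        tx(exons=((1, 100), (50, 300)))


# --- spliceosome typing -----------------------------------------------------


def test_classify_intron_heuristic_and_override():
    (intron,) = extract_introns([tx()])
    intron.donor_dinucleotide, intron.acceptor_dinucleotide = "GT", "AG"
    assert classify_intron(None, intron) == "major"
    intron.donor_dinucleotide, intron.acceptor_dinucleotide = "AT", "AC"
    assert classify_intron(None, intron) == "minor"
    # a curated list overrides the dinucleotide heuristic: most minor
    # introns are in fact GT-AG
    intron.donor_dinucleotide, intron.acceptor_dinucleotide = "GT", "AG"
    assert classify_intron(None, intron, minor_list={intron.key}) == "minor"


# --- mapping ----------------------------------------------------------------


def test_distance_convention_last_base_is_minus_one():
    introns = extract_introns([tx()])  # intron [101, 200] on +
    # BP 20 bases from the intron 3' end (19 bases after it)
    (m,) = map_bp_to_introns([merged(181)], introns)
    assert m.distance_to_3ss == -20
    # the last intron base is -1, inside the acceptor AG: excluded
    assert map_bp_to_introns([merged(200)], introns) == []


def test_proximal_window_boundaries():
    exons = ((1, 100), (301, 400))  # intron [101, 300], length 200
    introns = extract_introns([tx(exons=exons)])
    inside_lo = map_bp_to_introns([merged(300 - 99)], introns)  # -100
    outside_lo = map_bp_to_introns([merged(300 - 100)], introns)  # -101
    inside_hi = map_bp_to_introns([merged(298)], introns)  # -3
    outside_hi = map_bp_to_introns([merged(299)], introns)  # -2
    assert len(inside_lo) == 1 and inside_lo[0].distance_to_3ss == -100
    assert outside_lo == []
    assert len(inside_hi) == 1 and inside_hi[0].distance_to_3ss == -3
    assert outside_hi == []


def test_ranks_by_proximity():
    introns = extract_introns([tx()])
    mapped = map_bp_to_introns([merged(200 - 23), merged(200 - 29)], introns)
    by_dist = {m.distance_to_3ss: m for m in mapped}
    assert by_dist[-24].rank == 1 and by_dist[-24].total_in_intron == 2
    assert by_dist[-30].rank == 2 and by_dist[-30].total_in_intron == 2


def test_mapping_agrees_with_all_pairs_scan():
    spec = FixtureSpec(seed=3, n_genes=25, bp_per_intron=(1, 2, 3, 4))
    bundle = generate_fixture(spec)
    transcripts = bundle.transcripts
    introns = extract_introns(transcripts)
    bps = [
        merged(e["pos"], strand=e["strand"], contig=e["contig"])
        for e in bundle.manifest["bps"]
    ]
    mapped = map_bp_to_introns(bps, introns)

    expected = set()
    for bp in bps:  # O(n*m) oracle
        for intron in introns:
            if (bp.contig, bp.strand) != (intron.contig, intron.strand):
                continue
            if not intron.start <= bp.pos <= intron.end:
                continue
            d = (
                -(intron.end - bp.pos + 1)
                if intron.strand == "+"
                else -(bp.pos - intron.start + 1)
            )
            if PROXIMAL_WINDOW[0] <= d <= PROXIMAL_WINDOW[1]:
                expected.add((bp.contig, bp.pos, intron.key, d))
    assert {
        (m.bp.contig, m.bp.pos, m.intron.key, m.distance_to_3ss) for m in mapped
    } == expected
    # rank permutation per intron
    per_intron = {}
    for m in mapped:
        per_intron.setdefault(m.intron.key, []).append(m)
    for group in per_intron.values():
        assert sorted(m.rank for m in group) == list(range(1, len(group) + 1))
        assert all(m.total_in_intron == len(group) for m in group)


def test_planted_distances_recovered():
    bundle = generate_fixture(FixtureSpec(seed=5, n_genes=10))
    introns = extract_introns(bundle.transcripts)
    for entry in bundle.manifest["bps"]:
        (m,) = map_bp_to_introns(
            [merged(entry["pos"], strand=entry["strand"], contig=entry["contig"])],
            introns,
        )
        assert m.distance_to_3ss == entry["distance"]


# --- distributions ----------------------------------------------------------


def test_intron_bp_distribution():
    introns = extract_introns([tx()])
    bps = [merged(200 - d) for d in (19, 24, 29)]
    dist_hist, count_hist = intron_bp_distribution(map_bp_to_introns(bps, introns))
    assert {d: n for d, n in dist_hist.items() if n} == {-20: 1, -25: 1, -30: 1}
    assert dist_hist[-50] == 0  # empty bins rendered as zero
    assert count_hist == {3: 1}
    with pytest.raises(ValueError):
        intron_bp_distribution([])


# --- binding energy ---------------------------------------------------------


def test_binding_energy_perfect_duplex():
    # flanks antiparallel-complement GUAGUA; the bulged BP 'A' at index 5.
    # Pairs U:A, A:U, C:G, U:A, A:U, C:G score 2+2+3+2+2+3 = 14.
    motif = "TACTA" + "A" + "C"
    be = binding_energy(motif, "U2")
    assert be.energy == -14.0


def test_binding_energy_all_mismatch_is_zero():
    # antiparallel partner bases of GUAGUA are A,U,G,A,U,G; C never pairs
    # A/U and A never pairs G, so CCACC|A pairs nothing at all
    assert binding_energy("CCACC" + "A" + "A", "U2").energy == 0.0


def test_binding_energy_monotone_under_mismatch():
    perfect = binding_energy("TACTAAC", "U2").energy
    for i in [0, 1, 2, 3, 4, 6]:
        motif = list("TACTAAC")
        motif[i] = "G" if motif[i] != "G" else "C"
        worse = binding_energy("".join(motif), "U2").energy
        assert worse > perfect


def test_binding_energy_rejects_bad_length():
    with pytest.raises(ValueError):
        binding_energy("TACTAA", "U2")
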