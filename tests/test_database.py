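import itertools

import numpy as np
import pytest

from bpscan.database import (
    BPRecord,
    adjust_bp_position,
    adjust_dataset,
    composition_summary,
    consensus_level,
    merge_datasets,
    motif_at,
    reverse_complement,
)
from bpscan.io import GenomeSequence


def make_genome(**contigs):
    return {name: GenomeSequence(name, seq) for name, seq in contigs.items()}


# --- consensus levels -------------------------------------------------------


@pytest.mark.parametrize(
    "motif,level",
    [
        ("TTGAT", 1),  # YTNAY
        ("CTAAC", 1),
        ("ATGAC", 3),  # fails Y at -3, passes TNA
        ("GCGAT", 4),  # -2 is C: Y but not T
        ("GGGCT", 0),  # no A at offset 0
        ("TTGAA", 2),  # YTNA but +1 not Y
        ("NTGAT", 0),  # N anywhere kills the match
    ],
)
def test_consensus_level_examples(motif, level):
    assert consensus_level(motif) == level


def test_consensus_level_rejects_wrong_length():
    with pytest.raises(ValueError):
        consensus_level("TTGA")


def _matches_pattern(motif, pattern):
    table = {"Y": "CT", "T": "T", "N": "ACGT", "A": "A"}
    return all(b in table[p] for b, p in zip(motif, pattern))


def test_consensus_nesting_over_all_5mers():
    """The reported level is the smallest index whose pattern matches.

    Independent re-statement: level-k predicates are checked one by one
    on every possible 5-mer (patterns anchored to the BP at index 3).
    """
    for motif in map("".join, itertools.product("ACGT", repeat=5)):
        predicates = {
            1: _matches_pattern(motif, "YTNAY"),
            2: _matches_pattern(motif[:4], "YTNA"),
            3: _matches_pattern(motif[1:4], "TNA"),
            4: _matches_pattern(motif[1:4], "YNA"),
        }
        expected = min((k for k, ok in predicates.items() if ok), default=0)
        assert consensus_level(motif) == expected
        if predicates[1]:  # nesting: the stringent implies the relaxed
            assert predicates[2] and predicates[3] and predicates[4]


# --- motif extraction -------------------------------------------------------


def test_motif_at_both_strands():
    genome = make_genome(c="ACGTACGT")
    assert motif_at(genome, "c", 4, "+", (-1, 1)) == "GTA"
    # minus strand: reverse complement of genomic positions 3..5
    assert motif_at(genome, "c", 4, "-", (-1, 1)) == reverse_complement("GTA")
    assert motif_at(genome, "c", 4, "-", (-1, 1)) == "TAC"
    assert motif_at(genome, "c", 4, "+", (0, 0)) == "T"


def test_motif_at_out_of_range():
    genome = make_genome(c="ACGT")
    with pytest.raises(IndexError):
        motif_at(genome, "c", 4, "+", (-1, 1))


# --- positional adjustment --------------------------------------------------


def _oracle_adjust(genome, rec):
    """Exhaustive scan over d in {0, +-1, +-2}, nearest first, ties
    broken toward the 3'ss (transcript-downstream)."""
    step = 1 if rec.strand == "+" else -1
    for d in (0, 1, -1, 2, -2):
        pos = rec.pos + step * d
        if consensus_level(motif_at(genome, rec.contig, pos, rec.strand, (-3, 1))) == 1:
            return pos
    return rec.pos


def test_adjust_matches_exhaustive_oracle():
    rng = np.random.default_rng(11)
    for trial in range(300):
        seq = "".join(rng.choice(list("ACGT"), size=30))
        genome = make_genome(c=seq)
        strand = "+" if trial % 2 else "-"
        rec = BPRecord("c", 15, strand, "d", "experimental")
        adjusted = adjust_bp_position(genome, rec)
        assert adjusted.pos == _oracle_adjust(genome, rec)
        # idempotence
        again = adjust_bp_position(genome, adjusted)
        assert again.pos == adjusted.pos


def test_ytnay_centered_record_is_fixed_point():
    genome = make_genome(c="GGGG" + "TTGAT" + "GGGG")
    rec = BPRecord("c", 8, "+", "d", "experimental")  # the A of TTGAT
    assert adjust_bp_position(genome, rec).pos == 8


def test_no_match_leaves_record_unchanged():
    genome = make_genome(c="G" * 20)
    rec = BPRecord("c", 10, "+", "d", "experimental")
    adj = adjust_bp_position(genome, rec)
    assert adj.pos == 10 and adj.bp_base == "G"


def test_off_by_one_neighbors_merge():
    genome = make_genome(c="GGGG" + "TTGAT" + "GGGGGG")
    recs = [
        BPRecord("c", 8, "+", "d", "experimental"),
        BPRecord("c", 9, "+", "d", "experimental"),  # raw call one nt off
    ]
    adjusted, report = adjust_dataset(genome, recs)
    assert [r.pos for r in adjusted] == [8]
    assert report.delta == -1
    assert report.n_adjusted_positions_moved == 1


def test_adjust_dataset_rejects_mixed_ids():
    genome = make_genome(c="G" * 20)
    recs = [
        BPRecord("c", 10, "+", "d1", "experimental"),
        BPRecord("c", 12, "+", "d2", "experimental"),
    ]
    with pytest.raises(ValueError, match="mixed"):
        adjust_dataset(genome, recs)


# --- merging ----------------------------------------------------------------


def _bp(pos, dataset, evidence, strand="+"):
    return BPRecord("c", pos, strand, dataset, evidence, bp_base="A")


def test_merge_classes_by_evidence():
    merged = merge_datasets(
        [[_bp(10, "e1", "experimental")], [_bp(10, "c1", "computational")]]
    )
    (m,) = merged
    assert m.bp_class == "mBP" and m.n_sources == 2
    assert m.bp_name == "mBP_c_10_+_A"

    (m,) = merge_datasets([[_bp(10, "e1", "experimental")], [_bp(10, "e2", "experimental")]])
    assert m.bp_class == "eBP" and m.n_sources == 2


def test_merge_keeps_opposite_strands_distinct():
    merged = merge_datasets(
        [[_bp(10, "e1", "experimental")], [_bp(10, "c1", "computational", strand="-")]]
    )
    assert len(merged) == 2
    assert {m.bp_class for m in merged} == {"eBP", "cBP"}


def test_merge_order_independent_and_matches_set_algebra():
    d1 = [_bp(p, "e1", "experimental") for p in (10, 20, 30)]
    d2 = [_bp(p, "e2", "experimental") for p in (20, 30, 40)]
    d3 = [_bp(p, "c1", "computational") for p in (30, 40, 50)]
    reference = merge_datasets([d1, d2, d3])
    # brute-force set algebra on positions
    e_pos, c_pos = {10, 20, 30, 40}, {30, 40, 50}
    assert {m.pos for m in reference if m.bp_class == "mBP"} == e_pos & c_pos
    assert {m.pos for m in reference if m.bp_class == "eBP"} == e_pos - c_pos
    assert {m.pos for m in reference if m.bp_class == "cBP"} == c_pos - e_pos
    for perm in itertools.permutations([d1, d2, d3]):
        assert merge_datasets(list(perm)) == reference


# --- composition ------------------------------------------------------------


def test_composition_summary():
    recs = [_bp(p, "d", "experimental") for p in range(4)]
    for r, base in zip(recs, "ACGT"):
        object.__setattr__(r, "bp_base", base)
    assert composition_summary(recs) == {"A": 25.0, "C": 25.0, "G": 25.0, "T": 25.0}

    counts = {"A": 46, "C": 22, "G": 18, "T": 14}
    planted = []
    for base, n in counts.items():
        for i in range(n):
            r = _bp(1000 + len(planted), "d", "experimental")
            object.__setattr__(r, "bp_base", base)
            planted.append(r)
    assert composition_summary(planted) == {b: float(n) for b, n in counts.items()}

    with pytest.raises(ValueError):
        composition_summary([])
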