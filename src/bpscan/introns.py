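"""Intron extraction, spliceosome typing, and BP-to-intron mapping.

Distance convention: the final intron nucleotide (the G of the acceptor
AG) is position -1, so a BP with 20 intron bases between itself and the
3' splice site, inclusive of the BP, sits at distance -20.  Only BPs in
the [-3, -100] window of the 3'ss ("3'-proximal") are retained; distal
BPs involve recursive splicing and long-range structure and are out of
scope here.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from intervaltree import IntervalTree

from .database import MergedBP, motif_at
from .io import GenomeSequence, TranscriptModel

__all__ = [
    "IntronRecord",
    "MappedBP",
    "BindingEnergy",
    "PROXIMAL_WINDOW",
    "extract_introns",
    "classify_intron",
    "map_bp_to_introns",
    "intron_bp_distribution",
    "binding_energy",
    "U2_BRANCH_HEXAMER",
    "U12_BRANCH_HEXAMER",
]

#: Retained BP-to-3'ss distances (inclusive, both negative).
PROXIMAL_WINDOW = (-100, -3)


@dataclass
class IntronRecord:
    """A unique intron shared by one or more transcripts."""

    contig: str
    strand: str
    start: int  # 1-based inclusive genomic bounds
    end: int
    donor_dinucleotide: str  # transcript-sense 2-mers
    acceptor_dinucleotide: str
    spliceosome_type: str = "major"
    #: (transcript_id, intron_number 5'->3', canonical flag, gene symbol)
    transcript_memberships: list[tuple[str, int, bool, str]] = None

    def __post_init__(self) -> None:
        if self.transcript_memberships is None:
            self.transcript_memberships = []
        if self.length < 4:
            raise ValueError(
                f"intron {self.key} shorter than 4 nt cannot carry splice sites"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def key(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}:{self.strand}"

    def three_prime_end(self) -> int:
        """Genomic position of the last intron base in transcript sense."""
        return self.end if self.strand == "+" else self.start


@dataclass
class MappedBP:
    """A merged BP attached to one 3'-proximal intron."""

    bp: MergedBP
    intron: IntronRecord
    distance_to_3ss: int  # in [-100, -3]
    rank: int  # 1 = closest to the 3'ss
    total_in_intron: int
    motif: str  # 13-mer covering offsets [-9, +3]
    consensus_level: int

    @property
    def rank_label(self) -> str:
        return f"#{self.rank}/{self.total_in_intron}"


def extract_introns(transcripts: list[TranscriptModel]) -> list[IntronRecord]:
    """Introns are the gaps between consecutive exons, deduplicated.

    Identity is (contig, start, end, strand); transcript memberships
    accumulate, with intron numbers counted 5'->3' in transcript
    orientation.  Terminal dinucleotides are filled in later by
    :func:`annotate_intron_dinucleotides` when a genome is available.
    """
    by_key: dict[tuple, IntronRecord] = {}
    for tx in transcripts:
        gaps = []
        for (s1, e1), (s2, e2) in zip(tx.exons, tx.exons[1:]):
            gaps.append((e1 + 1, s2 - 1))
        if tx.strand == "-":
            numbered = [(g, i + 1) for i, g in enumerate(reversed(gaps))]
        else:
            numbered = [(g, i + 1) for i, g in enumerate(gaps)]
        for (start, end), number in numbered:
            key = (tx.contig, start, end, tx.strand)
            rec = by_key.get(key)
            if rec is None:
                rec = IntronRecord(
                    contig=tx.contig,
                    strand=tx.strand,
                    start=start,
                    end=end,
                    donor_dinucleotide="NN",
                    acceptor_dinucleotide="NN",
                )
                by_key[key] = rec
            rec.transcript_memberships.append(
                (tx.transcript_id, number, tx.canonical_flag, tx.gene_symbol)
            )
    introns = sorted(
        by_key.values(), key=lambda r: (r.contig, r.start, r.end, r.strand)
    )
    return introns


def annotate_intron_dinucleotides(
    genome: dict[str, GenomeSequence], introns: list[IntronRecord]
) -> None:
    """Fill donor/acceptor dinucleotides (transcript sense) in place."""
    from .database import reverse_complement

    for intron in introns:
        seq = genome[intron.contig]
        first2 = seq.slice(intron.start, intron.start + 1)
        last2 = seq.slice(intron.end - 1, intron.end)
        if intron.strand == "+":
            intron.donor_dinucleotide = first2
            intron.acceptor_dinucleotide = last2
        else:
            intron.donor_dinucleotide = reverse_complement(last2)
            intron.acceptor_dinucleotide = reverse_complement(first2)


def classify_intron(
    genome: dict[str, GenomeSequence] | None,
    intron: IntronRecord,
    minor_list: set[str] | None = None,
) -> str:
    """Spliceosome type: an explicit minor list wins; else AT-AC => minor.

    Most minor (U12-type) introns in fact carry GT-AG termini, so the
    dinucleotide heuristic is only a default for when no curated list of
    minor introns is supplied.
    """
    if minor_list is not None and intron.key in minor_list:
        return "minor"
    if genome is not None and intron.donor_dinucleotide == "NN":
        annotate_intron_dinucleotides(genome, [intron])
    if (
        intron.donor_dinucleotide == "AT"
        and intron.acceptor_dinucleotide == "AC"
    ):
        return "minor"
    return "major"


def _distance_to_3ss(intron: IntronRecord, pos: int) -> int:
    """Distance of a genomic position from the intron 3'ss (last base = -1)."""
    if intron.strand == "+":
        return -(intron.end - pos + 1)
    return -(pos - intron.start + 1)


def map_bp_to_introns(
    merged_bp: list[MergedBP],
    introns: list[IntronRecord],
    genome: dict[str, GenomeSequence] | None = None,
) -> list[MappedBP]:
    """Attach BPs to 3'-proximal introns with distance and rank.

    A BP maps to an intron iff they share contig and strand, the BP lies
    inside the intron, and its distance to the 3'ss is within
    :data:`PROXIMAL_WINDOW`.  Ranks order BPs within one intron by
    ascending |distance| (rank 1 nearest the 3'ss).  A BP inside several
    overlapping introns maps once per intron.
    """
    trees: dict[tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
    for intron in introns:
        trees[(intron.contig, intron.strand)].addi(
            intron.start, intron.end + 1, intron
        )
    per_intron: dict[str, list[MappedBP]] = defaultdict(list)
    for bp in merged_bp:
        for iv in trees.get((bp.contig, bp.strand), IntervalTree())[bp.pos]:
            intron = iv.data
            dist = _distance_to_3ss(intron, bp.pos)
            if not PROXIMAL_WINDOW[0] <= dist <= PROXIMAL_WINDOW[1]:
                continue
            if genome is not None:
                motif13 = motif_at(genome, bp.contig, bp.pos, bp.strand, (-9, 3))
                motif5 = motif13[6:11]
                from .database import consensus_level as _level

                level = _level(motif5)
            else:
                motif13 = "." * 13
                level = 0
            per_intron[intron.key].append(
                MappedBP(
                    bp=bp,
                    intron=intron,
                    distance_to_3ss=dist,
                    rank=0,
                    total_in_intron=0,
                    motif=motif13,
                    consensus_level=level,
                )
            )
    mapped: list[MappedBP] = []
    for group in per_intron.values():
        group.sort(key=lambda m: abs(m.distance_to_3ss))
        for i, m in enumerate(group):
            if i and group[i - 1].distance_to_3ss == m.distance_to_3ss:
                raise AssertionError(
                    "two BPs at one position/strand cannot be equidistant"
                )
            m.rank = i + 1
            m.total_in_intron = len(group)
        mapped.extend(group)
    mapped.sort(key=lambda m: (m.bp.contig, m.bp.pos, m.bp.strand, m.intron.key))
    return mapped


def intron_bp_distribution(
    mapped: list[MappedBP],
) -> tuple[dict[int, int], dict[int, int]]:
    """Histograms of BP distances and of per-intron BP counts.

    Distance bins are the integer distances themselves; absent distances
    within the proximal window are rendered as explicit zero bins.
    """
    if not mapped:
        raise ValueError("distribution of an empty mapping is undefined")
    seen_introns: dict[str, int] = {}
    dist_hist = {d: 0 for d in range(PROXIMAL_WINDOW[1], PROXIMAL_WINDOW[0] - 1, -1)}
    for m in mapped:
        dist_hist[m.distance_to_3ss] += 1
        seen_introns[m.intron.key] = m.total_in_intron
    count_hist: dict[int, int] = defaultdict(int)
    for total in seen_introns.values():
        count_hist[total] += 1
    return dist_hist, dict(count_hist)


# --- BP/snRNA binding-energy estimate ---------------------------------------
#
# A deliberately simple duplex score: the BP nucleotide bulges out of the
# helix, and the six flanking motif positions (offsets [-5, -1] and +1)
# base-pair antiparallel with the snRNA branch-recognition hexamer.  Each
# pair contributes G:C = 3, A:U/A:T = 2, G:U/G:T = 1 (wobble); mismatches
# contribute 0.  The energy is the negated sum, so lower = stronger.
# This is a documented stand-in for a thermodynamic model and is never
# used by the prioritization score.

U2_BRANCH_HEXAMER = "GUAGUA"
#: Antiparallel complement of the minor-spliceosome BP consensus flanks;
#: configurable because the reference recognition register is uncertain.
U12_BRANCH_HEXAMER = "GAAGGA"

_PAIR_SCORE = {
    frozenset("GC"): 3,
    frozenset(("A", "U")): 2,
    frozenset(("G", "U")): 1,
}


@dataclass(frozen=True)
class BindingEnergy:
    energy: float  # arbitrary units; lower = stronger binding
    snrna: str  # "U2" | "U12"


def binding_energy(
    motif7: str, snrna: str = "U2", hexamer: str | None = None
) -> BindingEnergy:
    """Duplex energy of a BP motif [-5, +1] against a snRNA hexamer.

    The motif is DNA (transcript sense); position index 5 (offset 0, the
    BP) is bulged out and excluded from pairing.
    """
    if len(motif7) != 7:
        raise ValueError("binding motif must cover offsets [-5, +1] (7 nt)")
    if hexamer is None:
        hexamer = U2_BRANCH_HEXAMER if snrna == "U2" else U12_BRANCH_HEXAMER
    paired = (motif7[:5] + motif7[6]).upper().replace("T", "U")
    hexamer = hexamer.upper().replace("T", "U")
    score = 0
    for k, base in enumerate(paired):
        partner = hexamer[len(hexamer) - 1 - k]  # antiparallel register
        score += _PAIR_SCORE.get(frozenset((base, partner)), 0)
    return BindingEnergy(energy=-float(score), snrna=snrna)
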