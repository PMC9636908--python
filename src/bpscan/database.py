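"""Integrated branchpoint (BP) database construction.

A BP is the intronic nucleotide (usually an adenine) that attacks the 5'
splice site to form the lariat.  Raw BP calls from lariat-spanning
RNA-seq reads are frequently off by one or two nucleotides, so each raw
position is screened against the YTNAY consensus (Y = C/T, N = any, A =
the BP) within a [-2, +2] window and moved to the closest perfect match.
Adjusted datasets are then merged into a single database in which each
position is classed by its evidence:

* ``eBP`` -- experimentally identified only,
* ``cBP`` -- computationally predicted only,
* ``mBP`` -- mutually shared between both evidence classes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

from .io import GenomeSequence, normalize_strand

__all__ = [
    "BPRecord",
    "MergedBP",
    "AdjustmentReport",
    "COMPLEMENT",
    "reverse_complement",
    "motif_at",
    "consensus_level",
    "adjust_bp_position",
    "adjust_dataset",
    "merge_datasets",
    "composition_summary",
]

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Consensus patterns by level, most stringent first.  Each pattern maps
#: 5-mer offsets [-3..+1] (index 0 is offset -3, index 3 is the BP).
_Y = frozenset("CT")
_N = frozenset("ACGT")
_A = frozenset("A")
_T = frozenset("T")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class BPRecord:
    """One raw or adjusted branchpoint call from a single dataset."""

    contig: str
    pos: int  # 1-based genomic position of the BP nucleotide
    strand: str
    dataset_id: str
    evidence_class: str  # "experimental" | "computational"
    bp_base: str | None = None  # transcript-sense nucleotide, if known

    def __post_init__(self) -> None:
        object.__setattr__(self, "strand", normalize_strand(self.strand))
        if self.evidence_class not in ("experimental", "computational"):
            raise ValueError(f"bad evidence_class {self.evidence_class!r}")


@dataclass(frozen=True)
class MergedBP:
    """A unique branchpoint position after dataset integration."""

    contig: str
    pos: int
    strand: str
    bp_base: str
    sources: tuple[str, ...]
    bp_class: str  # "mBP" | "eBP" | "cBP"

    @property
    def n_sources(self) -> int:
        return len(self.sources)

    @property
    def bp_name(self) -> str:
        """Name grammar: ``{m|e|c}BP_{contig}_{pos}_{strand}_{base}``."""
        return f"{self.bp_class}_{self.contig}_{self.pos}_{self.strand}_{self.bp_base}"


@dataclass
class AdjustmentReport:
    """Bookkeeping for the consensus-guided adjustment of one dataset."""

    dataset_id: str
    n_raw: int
    n_adjusted_positions_moved: int
    n_after_dedup: int
    composition_before: dict[str, float] = field(default_factory=dict)
    composition_after: dict[str, float] = field(default_factory=dict)

    @property
    def delta(self) -> int:
        """Change in dataset size; merging can only shrink it (<= 0)."""
        return self.n_after_dedup - self.n_raw


def motif_at(
    genome: dict[str, GenomeSequence],
    contig: str,
    pos: int,
    strand: str,
    window: tuple[int, int],
) -> str:
    """Transcript-sense motif around a position.

    ``window`` gives (a, b) offsets in transcript orientation with the
    queried base at offset 0; the returned string has length b - a + 1
    and is reverse-complemented on the minus strand.
    """
    a, b = window
    if a > b:
        raise ValueError(f"window offsets {a} > {b}")
    strand = normalize_strand(strand)
    seq = genome[contig]
    if strand == "+":
        return seq.slice(pos + a, pos + b)
    return reverse_complement(seq.slice(pos - b, pos - a))


def _matches(motif5: str, spec: tuple[frozenset, ...], start: int) -> bool:
    return all(motif5[start + i] in allowed for i, allowed in enumerate(spec))


def consensus_level(motif5: str) -> int:
    """Consensus level of a 5-mer covering offsets [-3, +1] of a BP.

    1: YTNAY, 2: YTNA, 3: TNA, 4: YNA, 0: none.  The most stringent
    matching pattern wins; any N base in the input gives level 0.
    """
    if len(motif5) != 5:
        raise ValueError(f"consensus motif must have length 5, got {len(motif5)}")
    motif5 = motif5.upper()
    if "N" in motif5:
        return 0
    if _matches(motif5, (_Y, _T, _N, _A, _Y), 0):
        return 1
    if _matches(motif5, (_Y, _T, _N, _A), 0):
        return 2
    if _matches(motif5, (_T, _N, _A), 1):
        return 3
    if _matches(motif5, (_Y, _N, _A), 1):
        return 4
    return 0


#: Candidate offsets for positional adjustment, nearest first; on a tie in
#: |d| the transcript-downstream candidate (closer to the 3'ss) wins.
_ADJUST_ORDER = (0, 1, -1, 2, -2)


def adjust_bp_position(
    genome: dict[str, GenomeSequence], record: BPRecord, window: int = 2
) -> BPRecord:
    """Move a raw BP call to the closest YTNAY-centered neighbor.

    Candidate offsets d in {0, +-1, +-2} are evaluated in transcript
    orientation; the record is returned unchanged when no candidate 5-mer
    perfectly matches YTNAY.  The returned record carries the
    transcript-sense base at its (possibly moved) position.
    """
    step = 1 if record.strand == "+" else -1
    chosen = None
    for d in _ADJUST_ORDER:
        if abs(d) > window:
            continue
        pos = record.pos + step * d
        motif5 = motif_at(genome, record.contig, pos, record.strand, (-3, 1))
        if consensus_level(motif5) == 1:
            chosen = pos
            break
    pos = chosen if chosen is not None else record.pos
    base = motif_at(genome, record.contig, pos, record.strand, (0, 0))
    return replace(record, pos=pos, bp_base=base)


def composition_summary(records) -> dict[str, float]:
    """Percent A/C/G/T of the transcript-sense BP bases; sums to ~100."""
    records = list(records)
    if not records:
        raise ValueError("composition of an empty record set is undefined")
    counts = Counter(r.bp_base for r in records)
    total = len(records)
    return {b: 100.0 * counts.get(b, 0) / total for b in "ACGT"}


def adjust_dataset(
    genome: dict[str, GenomeSequence], records: list[BPRecord]
) -> tuple[list[BPRecord], AdjustmentReport]:
    """Adjust every record of one dataset and collapse duplicates.

    Neighboring raw calls that adjust onto the same position merge into a
    single record, so the dataset can only shrink (delta <= 0).
    """
    dataset_ids = {r.dataset_id for r in records}
    if len(dataset_ids) > 1:
        raise ValueError(f"mixed dataset_ids in one adjustment run: {dataset_ids}")
    raw = [
        r
        if r.bp_base is not None
        else replace(r, bp_base=motif_at(genome, r.contig, r.pos, r.strand, (0, 0)))
        for r in records
    ]
    adjusted = []
    n_moved = 0
    seen: set[tuple[str, int, str]] = set()
    for rec in raw:
        adj = adjust_bp_position(genome, rec)
        if adj.pos != rec.pos:
            n_moved += 1
        key = (adj.contig, adj.pos, adj.strand)
        if key not in seen:
            seen.add(key)
            adjusted.append(adj)
    report = AdjustmentReport(
        dataset_id=next(iter(dataset_ids)) if dataset_ids else "",
        n_raw=len(raw),
        n_adjusted_positions_moved=n_moved,
        n_after_dedup=len(adjusted),
        composition_before=composition_summary(raw) if raw else {},
        composition_after=composition_summary(adjusted) if adjusted else {},
    )
    return adjusted, report


def merge_datasets(datasets: list[list[BPRecord]]) -> list[MergedBP]:
    """Integrate adjusted datasets into unique, evidence-classed BPs.

    One :class:`MergedBP` per unique (contig, pos, strand); opposite
    strands at the same position remain distinct.  The result is sorted
    and independent of input dataset order.
    """
    by_pos: dict[tuple[str, int, str], dict] = {}
    for records in datasets:
        for rec in records:
            if rec.bp_base is None:
                raise ValueError("merge requires adjusted records with bp_base set")
            key = (rec.contig, rec.pos, rec.strand)
            entry = by_pos.setdefault(
                key, {"base": rec.bp_base, "sources": set(), "classes": set()}
            )
            entry["sources"].add(rec.dataset_id)
            entry["classes"].add(rec.evidence_class)
    merged = []
    for (contig, pos, strand), entry in by_pos.items():
        if entry["classes"] == {"experimental", "computational"}:
            bp_class = "mBP"
        elif entry["classes"] == {"experimental"}:
            bp_class = "eBP"
        else:
            bp_class = "cBP"
        merged.append(
            MergedBP(
                contig=contig,
                pos=pos,
                strand=strand,
                bp_base=entry["base"],
                sources=tuple(sorted(entry["sources"])),
                bp_class=bp_class,
            )
        )
    merged.sort(key=lambda m: (m.contig, m.pos, m.strand))
    return merged
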