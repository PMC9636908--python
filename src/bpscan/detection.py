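"""Core detection engine: variants that disrupt the BP [-2, 0] window.

Offsets are computed in transcript orientation: a genomic site ``s``
relative to a BP at ``b`` has offset ``s - b`` on the plus strand and
``b - s`` on the minus strand.  An SNV hits the single offset it sits
on; a deletion hits every offset whose genomic site it removes; an
insertion whose breakpoint falls strictly inside the window reports both
flanking offsets and is flagged low-confidence, because the splicing
impact of insertions is hard to predict.
"""

from __future__ import annotations

import warnings
from bisect import bisect_left, bisect_right
from collections import defaultdict
from dataclasses import dataclass, field

from .database import MergedBP, reverse_complement
from .introns import MappedBP
from .io import GenomeSequence, TrackTable
from .scoring import (
    DEFAULT_WEIGHTS,
    ScoreBreakdown,
    ScoreContext,
    ScoreWeights,
    priority_score,
)
from .tracks import MISSING, PositionAnnotation, annotate_position, bp2_genomic_position

__all__ = [
    "VariantRecord",
    "DetectionResult",
    "DetectionTally",
    "classify_variant",
    "hit_offsets",
    "detect",
    "tally_detections",
    "undetected_variants",
    "write_detection_tsv",
]

HIT_WINDOW = (-2, -1, 0)


@dataclass(frozen=True)
class VariantRecord:
    """A normalized (trimmed, bi-allelic) variant."""

    contig: str
    pos: int
    id: str
    ref: str
    alt: str
    var_type: str  # "snv" | "x nt-deletion" | "x nt-insertion"
    affected_interval: tuple[int, int]
    complex_flag: bool = False  # both alleles >1 nt after trimming

    @property
    def key(self) -> tuple:
        return (self.contig, self.pos, self.ref, self.alt)

    @property
    def is_deletion(self) -> bool:
        return "deletion" in self.var_type

    @property
    def is_insertion(self) -> bool:
        return "insertion" in self.var_type


def classify_variant(
    ref: str, alt: str, pos: int = 1
) -> tuple[str, tuple[int, int], bool]:
    """Type a trimmed REF/ALT pair; returns (var_type, interval, complex).

    SNV: [pos, pos].  Deletion of x nt: the deleted bases [pos, pos+x-1].
    Insertion of x nt: the breakpoint (pos-1, pos).  A complex
    substitution (both trimmed sides > 1 nt, or unequal sides with no
    shared anchor) is typed by its REF side and flagged.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref == alt:
        raise ValueError(f"REF equals ALT ({ref!r}); not a variant")
    if len(ref) == 1 and len(alt) == 1:
        return "snv", (pos, pos), False
    if len(ref) == 0:
        return f"{len(alt)} nt-insertion", (pos - 1, pos), False
    if len(alt) == 0:
        return f"{len(ref)} nt-deletion", (pos, pos + len(ref) - 1), False
    if len(ref) == 1:  # substitution plus net insertion
        return f"{len(alt) - 1} nt-insertion", (pos, pos + 1), True
    # REF side dominates: the reference bases it removes are what can
    # disrupt the BP window, whatever the ALT side re-inserts
    return f"{len(ref)} nt-deletion", (pos, pos + len(ref) - 1), True


def _offset(site: int, bp_pos: int, strand: str) -> int:
    return site - bp_pos if strand == "+" else bp_pos - site


def hit_offsets(variant: VariantRecord, bp: MergedBP | MappedBP) -> tuple[int, ...]:
    """Offsets in {-2, -1, 0} of the BP window that a variant disrupts.

    Returns a sorted tuple; empty means no detection.
    """
    target = bp.bp if isinstance(bp, MappedBP) else bp
    if variant.contig != target.contig:
        return ()
    lo, hi = variant.affected_interval
    if variant.var_type == "snv":
        o = _offset(variant.pos, target.pos, target.strand)
        return (o,) if o in HIT_WINDOW else ()
    if variant.is_deletion:
        hits = [
            o
            for o in HIT_WINDOW
            if lo <= _genomic_site(target, o) <= hi
        ]
        return tuple(sorted(hits))
    # insertion: breakpoint between genomic sites lo and hi = lo + 1
    o1, o2 = sorted((_offset(lo, target.pos, target.strand),
                     _offset(hi, target.pos, target.strand)))
    if o1 >= -2 and o2 <= 0:
        return (o1, o2)
    return ()


def _genomic_site(bp: MergedBP, offset: int) -> int:
    return bp.pos + offset if bp.strand == "+" else bp.pos - offset


@dataclass
class DetectionResult:
    """One output row: a (variant, BP, transcript-membership) hit."""

    variant: VariantRecord
    mapped: MappedBP
    transcript_id: str
    intron_number: int
    gene_symbol: str
    hit_positions: tuple[int, ...]
    annotation: PositionAnnotation
    score: ScoreBreakdown
    low_confidence: bool = False  # insertion hits

    @property
    def transcript_tag(self) -> str:
        return f"{self.transcript_id}_IVS{self.intron_number}"

    @property
    def hit_label(self) -> str:
        return "|".join(str(o) for o in self.hit_positions)


def _transcript_sense_alleles(variant: VariantRecord, strand: str) -> tuple[str, str]:
    if variant.var_type != "snv":
        return variant.ref, variant.alt
    if strand == "+":
        return variant.ref, variant.alt
    return reverse_complement(variant.ref), reverse_complement(variant.alt)


def detect(
    variants: list[VariantRecord],
    mapped_bp: list[MappedBP],
    tracks: dict[str, TrackTable] | None = None,
    canonical_only: bool = False,
    min_score: float | None = None,
    weights: ScoreWeights = DEFAULT_WEIGHTS,
) -> list[DetectionResult]:
    """Scan variants against the mapped-BP index.

    Emits one row per (variant, BP, intron transcript-membership) with a
    nonempty hit-offset set, scored and sorted deterministically by
    (contig, pos, bp_name, transcript).  ``min_score`` filters rows only
    when set; ``canonical_only`` restricts to canonical memberships.
    """
    tracks = tracks or {}
    index: dict[str, list[tuple[int, MappedBP]]] = defaultdict(list)
    for m in mapped_bp:
        index[m.bp.contig].append((m.bp.pos, m))
    for entries in index.values():
        entries.sort(key=lambda e: e[0])
    unknown_contigs: set[str] = set()

    results: list[DetectionResult] = []
    for variant in variants:
        entries = index.get(variant.contig)
        if entries is None:
            if variant.contig not in unknown_contigs:
                unknown_contigs.add(variant.contig)
                warnings.warn(
                    f"contig {variant.contig!r} absent from BP database; "
                    "variant(s) skipped"
                )
            continue
        lo, hi = variant.affected_interval
        positions = [e[0] for e in entries]
        for i in range(bisect_left(positions, lo - 2), bisect_right(positions, hi + 2)):
            mapped = entries[i][1]
            hits = hit_offsets(variant, mapped)
            if not hits:
                continue
            bp = mapped.bp
            ann = annotate_position(
                tracks,
                bp.contig,
                bp.pos,
                bp2_genomic_position(bp.pos, bp.strand),
            )
            ref_ts, alt_ts = _transcript_sense_alleles(variant, bp.strand)
            ctx = ScoreContext(
                hit_positions=hits,
                var_type=variant.var_type,
                rank=mapped.rank,
                total_in_intron=mapped.total_in_intron,
                consensus_level=mapped.consensus_level,
                n_sources=bp.n_sources,
                bp_class=bp.bp_class,
                annotation=ann,
                ref_ts=ref_ts,
                alt_ts=alt_ts,
            )
            breakdown = priority_score(ctx, weights)
            if min_score is not None and breakdown.total < min_score:
                continue
            for tid, number, canonical, gene in mapped.intron.transcript_memberships:
                if canonical_only and not canonical:
                    continue
                results.append(
                    DetectionResult(
                        variant=variant,
                        mapped=mapped,
                        transcript_id=tid,
                        intron_number=number,
                        gene_symbol=gene,
                        hit_positions=hits,
                        annotation=ann,
                        score=breakdown,
                        low_confidence=variant.is_insertion,
                    )
                )
    results.sort(
        key=lambda r: (
            r.variant.contig,
            r.variant.pos,
            r.variant.ref,
            r.variant.alt,
            r.mapped.bp.bp_name,
            r.transcript_id,
        )
    )
    return results


def undetected_variants(
    variants: list[VariantRecord], results: list[DetectionResult]
) -> list[VariantRecord]:
    """Variants producing no detection row (for the audit side report)."""
    detected = {r.variant.key for r in results}
    return [v for v in variants if v.key not in detected]


@dataclass
class DetectionTally:
    """Per-variant summary counts; each variant counted under its best hit."""

    n_variants: int = 0
    by_hit: dict[str, int] = field(default_factory=lambda: defaultdict(int))
    by_rank: dict[str, int] = field(default_factory=lambda: defaultdict(int))
    by_consensus: dict[int, int] = field(default_factory=lambda: defaultdict(int))
    by_bp_class: dict[str, int] = field(default_factory=lambda: defaultdict(int))


def _hit_category(result: DetectionResult) -> str:
    v = result.variant
    hits = set(result.hit_positions)
    if v.is_deletion:
        if hits == set(HIT_WINDOW):
            return "deletion_full_motif"
        if len(hits) == 1:
            return f"deletion_{next(iter(hits))}"
        return "deletion_partial"
    if v.is_insertion:
        return "insertion"
    return f"snv_{result.hit_positions[0]}"


def _best_row(rows: list[DetectionResult]) -> DetectionResult:
    return max(
        rows,
        key=lambda r: (
            len(r.hit_positions),
            0 in r.hit_positions,
            -r.mapped.rank,
            r.score.total,
        ),
    )


def tally_detections(results: list[DetectionResult]) -> DetectionTally:
    """Summaries matching the retrospective-validation breakdown."""
    by_variant: dict[tuple, list[DetectionResult]] = defaultdict(list)
    for r in results:
        by_variant[r.variant.key].append(r)
    tally = DetectionTally(n_variants=len(by_variant))
    for rows in by_variant.values():
        best = _best_row(rows)
        tally.by_hit[_hit_category(best)] += 1
        if best.mapped.total_in_intron == 1:
            tally.by_rank["only"] += 1
        elif best.mapped.rank == 1:
            tally.by_rank["first"] += 1
        else:
            tally.by_rank["nonfirst"] += 1
        tally.by_consensus[best.mapped.consensus_level] += 1
        tally.by_bp_class[best.mapped.bp.bp_class] += 1
    return tally


DETECTION_COLUMNS = [
    "chrom",
    "pos",
    "id",
    "ref",
    "alt",
    "var_type",
    "gene",
    "bp_name",
    "bp_rank",
    "bp_hit_pos",
    "distance_to_3ss",
    "consensus_level",
    "n_sources",
    "sources",
    "maf_bp",
    "maf_bp2",
    "gerp_bp",
    "gerp_bp2",
    "phylop_bp",
    "phylop_bp2",
    "intron_type",
    "intron_length",
    "transcript_ivs",
    "score",
]


def write_detection_tsv(results: list[DetectionResult], path) -> None:
    """Tab-delimited output, one header line, '.' for missing values."""
    with open(path, "w") as fh:
        fh.write("\t".join(DETECTION_COLUMNS) + "\n")
        for r in results:
            ann = r.annotation
            row = [
                r.variant.contig,
                str(r.variant.pos),
                r.variant.id,
                r.variant.ref or MISSING,
                r.variant.alt or MISSING,
                r.variant.var_type,
                r.gene_symbol,
                r.mapped.bp.bp_name,
                r.mapped.rank_label,
                r.hit_label,
                str(r.mapped.distance_to_3ss),
                str(r.mapped.consensus_level),
                str(r.mapped.bp.n_sources),
                ",".join(r.mapped.bp.sources),
                ann.render(ann.maf_bp),
                ann.render(ann.maf_bp2),
                ann.render(ann.gerp_bp),
                ann.render(ann.gerp_bp2),
                ann.render(ann.phylop_bp),
                ann.render(ann.phylop_bp2),
                r.mapped.intron.spliceosome_type,
                str(r.mapped.intron.length),
                r.transcript_tag,
                format(r.score.total, "g"),
            ]
            fh.write("\t".join(row) + "\n")
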