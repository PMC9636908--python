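"""Prioritization score (0-10) and strategy flags for BP-hit variants.

The score is an additive reconstruction of the published prioritization
strategy: it rewards central hits, low rank, stringent consensus,
multi-source support, absence of population variation, and positive
conservation, and penalizes the benign-leaning T<>C substitution at the
BP-2 position.  Weights honor every ordinal statement of the strategy
(items 1-7) and the 0-10 range with a recommended threshold of >= 3; the
exact published weight table is not public, so all weights live in
:class:`ScoreWeights` and can be overridden wholesale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

from .tracks import PositionAnnotation

__all__ = [
    "ScoreWeights",
    "ScoreContext",
    "ScoreBreakdown",
    "DEFAULT_WEIGHTS",
    "SCORE_THRESHOLD",
    "priority_score",
    "prioritization_flags",
]

#: Recommended minimum score for a candidate worth follow-up.
SCORE_THRESHOLD = 3.0


@dataclass(frozen=True)
class ScoreWeights:
    """Additive term weights; every term is bounded by its maximum here."""

    hit_full_or_bp: float = 3.0  # full-motif deletion or offset 0
    hit_minus2: float = 2.0
    hit_minus1: float = 1.0
    rank_only: float = 2.0  # the single BP of its intron
    rank_first_of_few: float = 1.5  # rank 1 of a <=3-BP intron
    rank_second_of_few: float = 1.0  # rank 2 of a <=3-BP intron
    consensus: tuple[float, ...] = (0.0, 2.0, 1.5, 1.0, 0.5)  # index = level
    source_multi: float = 1.0
    source_mbp_bonus: float = 0.5  # capped at source_multi
    population_clean: float = 1.0
    population_rare: float = 0.5
    conservation_positive: float = 1.0
    conservation_missing: float = 0.5
    bp2_transition_penalty: float = -1.0
    clamp: tuple[float, float] = (0.0, 10.0)

    def override(self, **kwargs) -> "ScoreWeights":
        return replace(self, **kwargs)

    @classmethod
    def from_mapping(cls, mapping: dict[str, float]) -> "ScoreWeights":
        """Build weights from ``key=value`` overrides (CLI score-config)."""
        valid = {f.name for f in fields(cls)}
        unknown = set(mapping) - valid
        if unknown:
            raise ValueError(f"unknown score weight(s): {sorted(unknown)}")
        return cls(**mapping)


DEFAULT_WEIGHTS = ScoreWeights()


@dataclass
class ScoreContext:
    """Everything the score needs about one (variant, BP) hit."""

    hit_positions: tuple[int, ...]  # nonempty subset of (-2, -1, 0)
    var_type: str  # "snv" | "x nt-deletion" | "x nt-insertion"
    rank: int
    total_in_intron: int
    consensus_level: int
    n_sources: int
    bp_class: str  # mBP | eBP | cBP
    annotation: PositionAnnotation = field(default_factory=PositionAnnotation)
    #: transcript-sense ref/alt of an SNV, for the BP-2 transition penalty
    ref_ts: str | None = None
    alt_ts: str | None = None

    @property
    def is_full_motif_deletion(self) -> bool:
        return "deletion" in self.var_type and set(self.hit_positions) == {-2, -1, 0}


@dataclass
class ScoreBreakdown:
    hit_term: float
    rank_term: float
    consensus_term: float
    source_term: float
    population_term: float
    conservation_term: float
    bp2_transition_penalty: float
    total: float

    def terms(self) -> dict[str, float]:
        return {
            "hit": self.hit_term,
            "rank": self.rank_term,
            "consensus": self.consensus_term,
            "source": self.source_term,
            "population": self.population_term,
            "conservation": self.conservation_term,
            "bp2_penalty": self.bp2_transition_penalty,
        }


def _hit_term(ctx: ScoreContext, w: ScoreWeights) -> float:
    if ctx.is_full_motif_deletion or 0 in ctx.hit_positions:
        return w.hit_full_or_bp
    if -2 in ctx.hit_positions:
        return w.hit_minus2
    return w.hit_minus1


def _rank_term(ctx: ScoreContext, w: ScoreWeights) -> float:
    if ctx.total_in_intron == 1:
        return w.rank_only
    if ctx.total_in_intron <= 3:
        if ctx.rank == 1:
            return w.rank_first_of_few
        if ctx.rank == 2:
            return w.rank_second_of_few
    return 0.0


def _population_term(ann: PositionAnnotation, w: ScoreWeights) -> float:
    mafs = [m for m in (ann.maf_bp, ann.maf_bp2) if m is not None]
    if not mafs:
        return w.population_clean
    if any(m >= 0.01 for m in mafs):
        return 0.0
    return w.population_rare


def _conservation_term(ann: PositionAnnotation, w: ScoreWeights) -> float:
    scores = [s for s in (ann.gerp_bp, ann.phylop_bp) if s is not None]
    if not scores:
        # conservation may not track functional importance; stay neutral
        return w.conservation_missing
    return w.conservation_positive if any(s > 0 for s in scores) else 0.0


def _bp2_penalty(ctx: ScoreContext, w: ScoreWeights) -> float:
    if (
        ctx.var_type == "snv"
        and ctx.hit_positions == (-2,)
        and ctx.ref_ts is not None
        and ctx.alt_ts is not None
        and {ctx.ref_ts.upper(), ctx.alt_ts.upper()} == {"C", "T"}
    ):
        return w.bp2_transition_penalty
    return 0.0


def priority_score(
    ctx: ScoreContext, weights: ScoreWeights = DEFAULT_WEIGHTS
) -> ScoreBreakdown:
    """Additive 0-10 prioritization score for one hit."""
    if not ctx.hit_positions:
        raise ValueError("cannot score a hit with no disrupted BP position")
    w = weights
    breakdown = ScoreBreakdown(
        hit_term=_hit_term(ctx, w),
        rank_term=_rank_term(ctx, w),
        consensus_term=w.consensus[ctx.consensus_level],
        source_term=min(
            (w.source_multi if ctx.n_sources >= 2 else 0.0)
            + (w.source_mbp_bonus if ctx.bp_class == "mBP" else 0.0),
            w.source_multi,
        ),
        population_term=_population_term(ctx.annotation, w),
        conservation_term=_conservation_term(ctx.annotation, w),
        bp2_transition_penalty=_bp2_penalty(ctx, w),
        total=0.0,
    )
    raw = sum(breakdown.terms().values())
    breakdown.total = min(max(raw, w.clamp[0]), w.clamp[1])
    return breakdown


@dataclass(frozen=True)
class StrategyFlags:
    """Boolean mirrors of the seven prioritization-strategy items."""

    central_hit: bool  # 1) full-motif deletion, or BP / BP-2 disrupted
    favored_rank: bool  # 2) only BP, or rank 1-2 of a <=3-BP intron
    consensus_match: bool  # 3) YTNAY motif (or slightly relaxed, see below)
    consensus_relaxed: bool  # sub-tag of 3): YTNA rather than YTNAY
    multi_source: bool  # 4) more than one supporting source
    population_clean: bool  # 5) no or only rare population variants
    conserved: bool  # 6) positive GERP or PhyloP
    deprioritize_bp2_transition: bool  # 7) C>T / T>C at BP-2

    def as_tuple(self) -> tuple[bool, ...]:
        return (
            self.central_hit,
            self.favored_rank,
            self.consensus_match or self.consensus_relaxed,
            self.multi_source,
            self.population_clean,
            self.conserved,
            self.deprioritize_bp2_transition,
        )


def prioritization_flags(ctx: ScoreContext) -> StrategyFlags:
    ann = ctx.annotation
    mafs = [m for m in (ann.maf_bp, ann.maf_bp2) if m is not None]
    scores = [s for s in (ann.gerp_bp, ann.phylop_bp) if s is not None]
    return StrategyFlags(
        central_hit=(
            ctx.is_full_motif_deletion
            or 0 in ctx.hit_positions
            or -2 in ctx.hit_positions
        ),
        favored_rank=(
            ctx.total_in_intron == 1
            or (ctx.total_in_intron <= 3 and ctx.rank <= 2)
        ),
        consensus_match=ctx.consensus_level == 1,
        consensus_relaxed=ctx.consensus_level == 2,
        multi_source=ctx.n_sources > 1,
        population_clean=not any(m >= 0.01 for m in mafs),
        conserved=any(s > 0 for s in scores),
        deprioritize_bp2_transition=_bp2_penalty(ctx, DEFAULT_WEIGHTS) != 0.0,
    )
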