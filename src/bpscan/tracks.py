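"""Population-variation and conservation context for BP positions.

Tracks are optional; a missing track or a position absent from a track
yields a missing value, rendered ``"."`` in text output.  MAF classes
follow the usual population-genetics cuts: singleton (AC = 1), rare
(MAF < 1%), common (MAF >= 1%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import TrackTable

__all__ = ["PositionAnnotation", "annotate_position", "summarize_occupancy"]

MISSING = "."


@dataclass
class PositionAnnotation:
    """Per-BP annotation at the BP and the BP-2 genomic positions."""

    maf_bp: float | None = None
    maf_bp2: float | None = None
    ac_bp: float | None = None
    gerp_bp: float | None = None
    gerp_bp2: float | None = None
    phylop_bp: float | None = None
    phylop_bp2: float | None = None
    maf_class: str = "none"  # singleton | rare | common | none

    def render(self, value: float | None) -> str:
        return MISSING if value is None else format(value, "g")


def _maf_class(maf: float | None, ac: float | None) -> str:
    if maf is None:
        return "none"
    if ac is not None and ac == 1:
        return "singleton"
    return "rare" if maf < 0.01 else "common"


def bp2_genomic_position(pos: int, strand: str) -> int:
    """Genomic position of BP-2, two bases upstream in transcript sense."""
    return pos - 2 if strand == "+" else pos + 2


def annotate_position(
    tracks: dict[str, TrackTable],
    contig: str,
    pos_bp: int,
    pos_bp2: int,
) -> PositionAnnotation:
    """Look up MAF/AC/GERP/PhyloP at the BP and BP-2 positions.

    ``tracks`` maps track kind ("MAF", "AC", "GERP", "PhyloP") to a
    :class:`~bpscan.io.TrackTable`; any subset may be supplied.  When a
    position overlaps several population alleles the track is expected to
    carry the maximum MAF, which is what gets reported.
    """

    def get(kind: str, pos: int) -> float | None:
        table = tracks.get(kind)
        return None if table is None else table.lookup(contig, pos)

    ann = PositionAnnotation(
        maf_bp=get("MAF", pos_bp),
        maf_bp2=get("MAF", pos_bp2),
        ac_bp=get("AC", pos_bp),
        gerp_bp=get("GERP", pos_bp),
        gerp_bp2=get("GERP", pos_bp2),
        phylop_bp=get("PhyloP", pos_bp),
        phylop_bp2=get("PhyloP", pos_bp2),
    )
    ann.maf_class = _maf_class(ann.maf_bp, ann.ac_bp)
    return ann


@dataclass
class OccupancySummary:
    n_positions: int
    n_covered: int
    class_counts: dict[str, int] = field(default_factory=dict)

    @property
    def fraction(self) -> float:
        return self.n_covered / self.n_positions


def summarize_occupancy(
    positions: list[tuple[str, int]],
    maf_track: TrackTable,
    ac_track: TrackTable | None = None,
) -> OccupancySummary:
    """Fraction of a position set harboring any population variant.

    Also tallies covered positions by MAF class.  An empty position set
    is an error; an empty track gives occupancy 0.0.
    """
    if not positions:
        raise ValueError("occupancy of an empty position set is undefined")
    counts: dict[str, int] = {"singleton": 0, "rare": 0, "common": 0}
    covered = 0
    for contig, pos in positions:
        maf = maf_track.lookup(contig, pos)
        if maf is None:
            continue
        covered += 1
        ac = ac_track.lookup(contig, pos) if ac_track is not None else None
        counts[_maf_class(maf, ac)] += 1
    return OccupancySummary(
        n_positions=len(positions), n_covered=covered, class_counts=counts
    )
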