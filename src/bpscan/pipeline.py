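"""End-to-end orchestration: datasets -> database -> mapping -> detection.

The database artifact written by :func:`write_db_tsv` is a flat TSV of
mapped branchpoints (one row per BP-intron association) and is exactly
what :func:`load_db_tsv` reconstructs, so detection can run either from
in-memory objects or from a previously built database file.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from .database import (
    AdjustmentReport,
    BPRecord,
    MergedBP,
    adjust_dataset,
    merge_datasets,
)
from .detection import DetectionResult, VariantRecord, detect
from .introns import (
    IntronRecord,
    MappedBP,
    annotate_intron_dinucleotides,
    classify_intron,
    extract_introns,
    map_bp_to_introns,
)
from .io import GenomeSequence, TrackTable, TranscriptModel
from .scoring import DEFAULT_WEIGHTS, ScoreWeights

__all__ = [
    "build_database",
    "prepare_introns",
    "run_detection",
    "DetectionRun",
    "write_db_tsv",
    "load_db_tsv",
]


def build_database(
    genome: dict[str, GenomeSequence], bp_records: list[BPRecord]
) -> tuple[list[MergedBP], list[AdjustmentReport]]:
    """Adjust each dataset independently, then integrate."""
    by_dataset: dict[str, list[BPRecord]] = defaultdict(list)
    for rec in bp_records:
        by_dataset[rec.dataset_id].append(rec)
    adjusted, reports = [], []
    for dataset_id in sorted(by_dataset):
        records, report = adjust_dataset(genome, by_dataset[dataset_id])
        adjusted.append(records)
        reports.append(report)
    return merge_datasets(adjusted), reports


def prepare_introns(
    genome: dict[str, GenomeSequence],
    transcripts: list[TranscriptModel],
    minor_list: set[str] | None = None,
) -> list[IntronRecord]:
    introns = extract_introns(transcripts)
    annotate_intron_dinucleotides(genome, introns)
    for intron in introns:
        intron.spliceosome_type = classify_intron(genome, intron, minor_list)
    return introns


@dataclass
class DetectionRun:
    """All intermediate artifacts of one end-to-end run."""

    merged: list[MergedBP]
    reports: list[AdjustmentReport]
    introns: list[IntronRecord]
    mapped: list[MappedBP]
    results: list[DetectionResult]
    variants: list[VariantRecord] = field(default_factory=list)


def run_detection(
    genome: dict[str, GenomeSequence],
    transcripts: list[TranscriptModel],
    bp_records: list[BPRecord],
    variants: list[VariantRecord],
    tracks: dict[str, TrackTable] | None = None,
    canonical_only: bool = False,
    min_score: float | None = None,
    weights: ScoreWeights = DEFAULT_WEIGHTS,
    minor_list: set[str] | None = None,
) -> DetectionRun:
    merged, reports = build_database(genome, bp_records)
    introns = prepare_introns(genome, transcripts, minor_list)
    mapped = map_bp_to_introns(merged, introns, genome)
    results = detect(
        variants,
        mapped,
        tracks=tracks,
        canonical_only=canonical_only,
        min_score=min_score,
        weights=weights,
    )
    return DetectionRun(
        merged=merged,
        reports=reports,
        introns=introns,
        mapped=mapped,
        results=results,
        variants=variants,
    )


_DB_COLUMNS = [
    "bp_name",
    "contig",
    "pos",
    "strand",
    "base",
    "bp_class",
    "n_sources",
    "sources",
    "intron_key",
    "intron_type",
    "intron_length",
    "transcript_ids",
    "intron_numbers",
    "genes",
    "canonical_flags",
    "distance_to_3ss",
    "rank",
    "total_in_intron",
    "consensus_level",
    "motif",
]


def write_db_tsv(mapped: list[MappedBP], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_DB_COLUMNS) + "\n")
        for m in mapped:
            members = m.intron.transcript_memberships
            fh.write(
                "\t".join(
                    [
                        m.bp.bp_name,
                        m.bp.contig,
                        str(m.bp.pos),
                        m.bp.strand,
                        m.bp.bp_base,
                        m.bp.bp_class,
                        str(m.bp.n_sources),
                        ",".join(m.bp.sources),
                        m.intron.key,
                        m.intron.spliceosome_type,
                        str(m.intron.length),
                        ",".join(t[0] for t in members),
                        ",".join(str(t[1]) for t in members),
                        ",".join(t[3] for t in members),
                        ",".join("1" if t[2] else "0" for t in members),
                        str(m.distance_to_3ss),
                        str(m.rank),
                        str(m.total_in_intron),
                        str(m.consensus_level),
                        m.motif,
                    ]
                )
                + "\n"
            )


def load_db_tsv(path) -> list[MappedBP]:
    """Reconstruct mapped BPs (with shared intron objects) from a DB TSV."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _DB_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: not a bpscan database (missing {missing})")
    introns: dict[str, IntronRecord] = {}
    mapped: list[MappedBP] = []
    for row in df.itertuples(index=False):
        key = row.intron_key
        if key not in introns:
            loc, span, strand = key.rsplit(":", 2)
            start, end = (int(x) for x in span.split("-"))
            intron = IntronRecord(
                contig=loc,
                strand=strand,
                start=start,
                end=end,
                donor_dinucleotide="NN",
                acceptor_dinucleotide="NN",
                spliceosome_type=row.intron_type,
            )
            intron.transcript_memberships = [
                (tid, int(num), flag == "1", gene)
                for tid, num, flag, gene in zip(
                    row.transcript_ids.split(","),
                    row.intron_numbers.split(","),
                    row.canonical_flags.split(","),
                    row.genes.split(","),
                )
            ]
            introns[key] = intron
        bp = MergedBP(
            contig=row.contig,
            pos=int(row.pos),
            strand=row.strand,
            bp_base=row.base,
            sources=tuple(row.sources.split(",")),
            bp_class=row.bp_class,
        )
        mapped.append(
            MappedBP(
                bp=bp,
                intron=introns[key],
                distance_to_3ss=int(row.distance_to_3ss),
                rank=int(row.rank),
                total_in_intron=int(row.total_in_intron),
                motif=row.motif,
                consensus_level=int(row.consensus_level),
            )
        )
    return mapped
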