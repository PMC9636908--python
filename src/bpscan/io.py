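"""Readers and writers for the standard formats the tool touches.

Coordinate contract
-------------------
Every in-memory position is **1-based inclusive**, matching VCF and the
``g.`` genomic notation used in clinical genetics.  BED-dialect inputs are
converted at the boundary (``start + 1``).  Strand is ``"+"`` or ``"-"``;
the Unicode minus sign is accepted on input and normalized.
"""

from __future__ import annotations

import os
import tempfile
import warnings
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

__all__ = [
    "GenomeSequence",
    "TranscriptModel",
    "TrackTable",
    "FormatError",
    "load_genome",
    "load_transcript_models",
    "load_bp_records",
    "load_variants",
    "load_position_track",
    "trim_alleles",
    "normalize_strand",
]

VALID_BASES = frozenset("ACGTN")

#: GTF attribute tags recognized as marking a canonical transcript.
CANONICAL_TAGS = ("Ensembl_canonical", "MANE_Select", "canonical", "basic_canonical")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def normalize_strand(symbol: str) -> str:
    """Map a strand symbol to ``+``/``-``; reject anything else."""
    s = str(symbol).strip().replace("−", "-")  # Unicode minus
    if s not in ("+", "-"):
        raise FormatError(f"unknown strand symbol: {symbol!r}")
    return s


@dataclass(frozen=True)
class GenomeSequence:
    """One contig of the reference genome, uppercase {A,C,G,T,N}."""

    contig_name: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, pos: int) -> str:
        """Base at 1-based position ``pos``; out-of-range is an error."""
        if not 1 <= pos <= len(self.sequence):
            raise IndexError(
                f"position {pos} outside contig {self.contig_name} "
                f"(length {len(self.sequence)})"
            )
        return self.sequence[pos - 1]

    def slice(self, start: int, end: int) -> str:
        """Bases on [start, end], 1-based inclusive, genomic orientation."""
        if start > end:
            raise ValueError(f"start {start} > end {end}")
        if start < 1 or end > len(self.sequence):
            raise IndexError(
                f"[{start},{end}] outside contig {self.contig_name} "
                f"(length {len(self.sequence)})"
            )
        return self.sequence[start - 1 : end]


@dataclass
class TranscriptModel:
    """A transcript as an ordered list of exons on one contig/strand."""

    transcript_id: str
    gene_symbol: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]  # 1-based inclusive, sorted by genomic start
    canonical_flag: bool = False

    def __post_init__(self) -> None:
        self.strand = normalize_strand(self.strand)
        self.exons = sorted(tuple(e) for e in self.exons)
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"{self.transcript_id}: exon start {s} > end {e}")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
            prev_end = e
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript without exons")


@dataclass
class TrackTable:
    """Per-position numeric annotation (MAF, AC, GERP, PhyloP).

    Missing positions are represented by absence, distinct from value 0.
    """

    track_kind: str
    values: dict[tuple[str, int], float] = field(default_factory=dict)

    def lookup(self, contig: str, pos: int) -> float | None:
        return self.values.get((contig, pos))

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self.values

    def __len__(self) -> int:
        return len(self.values)


def load_genome(path: str | os.PathLike) -> dict[str, GenomeSequence]:
    """Load a FASTA file into a contig-name -> GenomeSequence mapping.

    Bases are uppercased on load.  An empty file yields an empty mapping;
    a non-empty file that does not start with a FASTA header is an error.
    """
    with open(path) as handle:
        head = handle.read(1)
        if head and head != ">":
            raise FormatError(f"{path}: line 1: expected FASTA header '>'")
    genome: dict[str, GenomeSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - VALID_BASES
        if bad:
            raise FormatError(f"{path}: contig {rec.id}: invalid bases {sorted(bad)}")
        genome[rec.id] = GenomeSequence(rec.id, seq)
    return genome


def _gtf_attributes(feature) -> dict:
    return {k: list(v) for k, v in feature.attributes.items()}


def _is_canonical(attrs: dict) -> bool:
    for tag_values in attrs.values():
        for v in tag_values:
            if v in CANONICAL_TAGS:
                return True
    for tag in CANONICAL_TAGS:
        if attrs.get(tag, [""])[0] in ("1", "true", "True"):
            return True
    return False


def load_transcript_models(
    path: str | os.PathLike, canonical_only: bool = False
) -> list[TranscriptModel]:
    """Load transcript models from a GTF file (exon features).

    Exon lines lacking a ``transcript_id`` attribute are skipped with a
    single summary warning.  ``canonical_only`` keeps transcripts carrying
    a recognized canonical tag (:data:`CANONICAL_TAGS`).
    """
    import gffutils

    n_skipped = 0
    kept_lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}: malformed GTF line: {line[:80]!r}")
            if fields[2] == "exon" and "transcript_id" not in fields[8]:
                n_skipped += 1
                continue
            kept_lines.append(line)
    if n_skipped:
        warnings.warn(f"{path}: skipped {n_skipped} exon line(s) without transcript_id")

    db = gffutils.create_db(
        "".join(kept_lines),
        dbfn=":memory:",
        from_string=True,
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    grouped: dict[str, dict] = {}
    for exon in db.features_of_type("exon"):
        attrs = _gtf_attributes(exon)
        tid = attrs["transcript_id"][0]
        entry = grouped.setdefault(
            tid,
            {
                "gene": attrs.get("gene_name", attrs.get("gene_id", ["?"]))[0],
                "contig": exon.seqid,
                "strand": exon.strand,
                "exons": [],
                "canonical": False,
            },
        )
        entry["exons"].append((exon.start, exon.end))
        entry["canonical"] = entry["canonical"] or _is_canonical(attrs)

    models = [
        TranscriptModel(
            transcript_id=tid,
            gene_symbol=entry["gene"],
            contig=entry["contig"],
            strand=entry["strand"],
            exons=entry["exons"],
            canonical_flag=entry["canonical"],
        )
        for tid, entry in grouped.items()
    ]
    if canonical_only:
        models = [m for m in models if m.canonical_flag]
        if not models:
            warnings.warn(f"{path}: canonical_only=True but no transcript is tagged")
    models.sort(key=lambda m: (m.contig, m.exons[0][0], m.transcript_id))
    return models


_EVIDENCE_ALIASES = {
    "experimental": "experimental",
    "e": "experimental",
    "computational": "computational",
    "c": "computational",
}


def load_bp_records(path: str | os.PathLike, dialect: str = "tsv") -> list:
    """Load a branchpoint dataset from a TSV (or BED-dialect) file.

    TSV columns: ``contig  pos  strand  dataset_id  evidence_class`` with a
    header line.  BED dialect uses 0-based starts which are converted on
    load.  Duplicate rows within the dataset are collapsed.
    """
    from .database import BPRecord  # local import to avoid a cycle

    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["contig", "pos", "strand", "dataset_id", "evidence_class"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    records = []
    seen = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            strand = normalize_strand(row.strand)
        except FormatError as exc:
            raise FormatError(f"{path}: line {i}: {exc}") from None
        evidence = _EVIDENCE_ALIASES.get(str(row.evidence_class).strip().lower())
        if evidence is None:
            raise FormatError(
                f"{path}: line {i}: unknown evidence_class {row.evidence_class!r}"
            )
        pos = int(row.pos)
        if dialect == "bed":
            pos += 1
        elif dialect != "tsv":
            raise ValueError(f"unknown dialect {dialect!r}")
        key = (row.contig, pos, strand, row.dataset_id)
        if key in seen:
            continue
        seen.add(key)
        records.append(
            BPRecord(
                contig=row.contig,
                pos=pos,
                strand=strand,
                dataset_id=row.dataset_id,
                evidence_class=evidence,
            )
        )
    return records


def trim_alleles(ref: str, alt: str) -> tuple[str, str, int]:
    """Strip the shared suffix then shared prefix of a REF/ALT pair.

    Returns ``(ref, alt, pos_shift)`` where ``pos_shift`` is the number of
    leading bases removed (to be added to POS).  At least one base or an
    empty string remains on each side; trimming is idempotent.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    shift = 0
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        shift += 1
    # a remaining shared single leading base anchors an indel
    if len(ref) != len(alt) and ref and alt and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        shift += 1
    return ref, alt, shift


def load_variants(path: str | os.PathLike) -> list:
    """Load VCF 4.x variants; the first five columns are the contract.

    Multi-allelic rows are split into one record per ALT.  Shared
    prefix/suffix bases are trimmed before typing; left-alignment is *not*
    performed (inputs are expected to be normalized).  Symbolic or
    breakend ALT alleles are skipped with a warning.
    """
    from cyvcf2 import VCF

    from .detection import VariantRecord, classify_variant

    records: list[VariantRecord] = []
    n_symbolic = 0
    vcf = VCF(str(path))
    try:
        for v in vcf:
            ref = v.REF.upper()
            if set(ref) - VALID_BASES:
                raise FormatError(
                    f"{path}: {v.CHROM}:{v.POS}: REF {v.REF!r} has non-ACGTN bases"
                )
            for alt in v.ALT:
                alt = alt.upper()
                if set(alt) - VALID_BASES or alt.startswith("<"):
                    n_symbolic += 1
                    continue
                t_ref, t_alt, shift = trim_alleles(ref, alt)
                var_type, interval, is_complex = classify_variant(
                    t_ref, t_alt, pos=v.POS + shift
                )
                records.append(
                    VariantRecord(
                        contig=v.CHROM,
                        pos=v.POS + shift,
                        id=v.ID or ".",
                        ref=t_ref,
                        alt=t_alt,
                        var_type=var_type,
                        affected_interval=interval,
                        complex_flag=is_complex,
                    )
                )
    finally:
        vcf.close()
    if n_symbolic:
        warnings.warn(f"{path}: skipped {n_symbolic} symbolic/non-ACGTN ALT allele(s)")
    return records


def load_variants_from_text(text: str) -> list:
    """Convenience wrapper: parse a VCF given as a string."""
    with tempfile.NamedTemporaryFile("w", suffix=".vcf", delete=False) as fh:
        fh.write(text)
        tmp = fh.name
    try:
        return load_variants(tmp)
    finally:
        os.unlink(tmp)


_TRACK_KINDS = ("MAF", "AC", "GERP", "PhyloP")


def load_position_track(path: str | os.PathLike, track_kind: str) -> TrackTable:
    """Load a per-position numeric track: TSV ``contig  pos  value``."""
    if track_kind not in _TRACK_KINDS:
        raise ValueError(f"track_kind must be one of {_TRACK_KINDS}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["contig", "pos", "value"]
    if [c for c in required if c not in df.columns]:
        raise FormatError(f"{path}: expected columns {required}")
    table = TrackTable(track_kind=track_kind)
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            value = float(row.value)
        except (TypeError, ValueError):
            raise FormatError(
                f"{path}: line {i}: non-numeric value {row.value!r}"
            ) from None
        table.values[(row.contig, int(row.pos))] = value
    return table


def write_fasta(genome: dict[str, GenomeSequence], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name].sequence
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_vcf(
    rows: list[tuple],
    path: str | os.PathLike,
    contigs: dict[str, GenomeSequence] | None = None,
) -> None:
    """Write minimal VCF body rows ``(chrom, pos, id, ref, alt)``."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, seq in (contigs or {}).items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, vid, ref, alt in rows:
            fh.write(f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\t.\t.\n")
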