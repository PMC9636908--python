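"""Deterministic synthetic data: toy genomes, annotations, BP sets, VCFs.

Two generators are provided:

* :func:`generate_fixture` builds randomized single-intron genes with
  planted branchpoints of controlled consensus level, optional off-by-one
  raw calls (to exercise consensus-guided adjustment), and planted
  variants at chosen offsets.  Every planted feature is recorded in a
  machine-readable manifest, so tests read expectations from the
  manifest rather than from the generator's code paths.

* :func:`build_validation_panel` reconstructs the *geometry* of the 48
  published pathogenic branchpoint variants (gene, variant type,
  distance to the 3'ss, rank among the intron's BPs, and disrupted
  offsets) on synthetic loci -- one gene per reported variant, with
  real genomic coordinates deliberately not reproduced.  Running
  detection on the bundle reproduces the published validation tallies.

Motif planting uses G-padded cassettes: the planted 9-mer carries G at
offsets -5, -4, +2, +3 around the 5-mer consensus core, which provably
blocks any YTNAY match at shifts of one or two nucleotides regardless of
the random background, so planted positions are stable under positional
adjustment.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np

from .database import BPRecord, reverse_complement
from .io import GenomeSequence, TrackTable, TranscriptModel, write_fasta, write_vcf

__all__ = [
    "FixtureSpec",
    "FixtureBundle",
    "generate_fixture",
    "build_validation_panel",
    "mirror_bundle",
    "PANEL_ROWS",
]

_BASES = "ACGT"
_Y = "CT"
_R = "AG"


# --------------------------------------------------------------------------
# sequence assembly helpers


class _ContigBuilder:
    def __init__(self, length: int, rng: np.random.Generator):
        self.chars = list(rng.choice(list(_BASES), size=length))

    def set_genomic(self, start: int, seq: str) -> None:
        """Write genomic-sense bases at 1-based start."""
        for i, b in enumerate(seq):
            self.chars[start - 1 + i] = b

    def set_ts(self, pos: int, strand: str, offset_a: int, seq: str) -> None:
        """Write transcript-sense bases starting at offset_a from pos."""
        if strand == "+":
            self.set_genomic(pos + offset_a, seq)
        else:
            self.set_genomic(pos - offset_a - len(seq) + 1, reverse_complement(seq))

    def get(self, start: int, end: int) -> str:
        return "".join(self.chars[start - 1 : end])

    def finish(self, name: str) -> GenomeSequence:
        return GenomeSequence(name, "".join(self.chars))


def _consensus_core(level: int, rng: np.random.Generator, fixed: dict | None = None):
    """A 5-mer (offsets -3..+1) matching exactly the requested level.

    ``fixed`` maps offsets to required bases (e.g. a variant's reference
    base); incompatible requests raise.
    """
    fixed = fixed or {}
    pick = lambda pool: str(rng.choice(list(pool)))  # noqa: E731
    if level == 1:
        core = {-3: pick(_Y), -2: "T", -1: pick(_BASES), 0: "A", 1: pick(_Y)}
    elif level == 2:
        core = {-3: pick(_Y), -2: "T", -1: pick(_BASES), 0: "A", 1: pick(_R)}
    elif level == 3:
        core = {-3: pick(_R), -2: "T", -1: pick(_BASES), 0: "A", 1: pick(_BASES)}
    elif level == 4:
        core = {-3: pick(_BASES), -2: "C", -1: pick(_BASES), 0: "A", 1: pick(_BASES)}
    elif level == 0:
        core = {-3: pick(_BASES), -2: "G", -1: pick(_BASES), 0: "A", 1: pick(_BASES)}
    else:
        raise ValueError(f"no such consensus level: {level}")
    for off, base in fixed.items():
        if off in core:
            allowed = {
                (1, -3): _Y, (1, -2): "T", (1, 1): _Y,
                (2, -3): _Y, (2, -2): "T", (2, 1): _R,
                (3, -3): _R, (3, -2): "T",
                (4, -2): "C", (0, -2): "G",
            }.get((level, off))
            if off == 0 and base != "A":
                raise ValueError("BP base must be A in planted consensus cores")
            if allowed is not None and base not in allowed:
                raise ValueError(
                    f"base {base} at offset {off} incompatible with level {level}"
                )
            core[off] = base
    return "".join(core[o] for o in (-3, -2, -1, 0, 1))


def _plant_bp(
    builder: _ContigBuilder,
    pos: int,
    strand: str,
    level: int,
    rng: np.random.Generator,
    fixed: dict | None = None,
) -> None:
    core = _consensus_core(level, rng, fixed)
    builder.set_ts(pos, strand, -5, "GG" + core + "GG")


# --------------------------------------------------------------------------
# bundle


@dataclass
class FixtureBundle:
    """An in-memory fixture with optional on-disk serialization."""

    genome: dict[str, GenomeSequence]
    transcripts: list[TranscriptModel]
    bp_rows: list[dict]  # contig,pos,strand,dataset_id,evidence_class
    vcf_rows: list[tuple]  # (chrom,pos,id,ref,alt)
    tracks: dict[str, TrackTable] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def bp_records(self) -> list[BPRecord]:
        return [
            BPRecord(
                contig=r["contig"],
                pos=r["pos"],
                strand=r["strand"],
                dataset_id=r["dataset_id"],
                evidence_class=r["evidence_class"],
            )
            for r in self.bp_rows
        ]

    def write(self, out_dir: str | os.PathLike) -> dict[str, str]:
        """Serialize to plain-text files; returns a name -> path map."""
        out_dir = str(out_dir)
        os.makedirs(out_dir, exist_ok=True)
        paths = {
            "genome": os.path.join(out_dir, "genome.fa"),
            "gtf": os.path.join(out_dir, "annotation.gtf"),
            "bp": os.path.join(out_dir, "bp_datasets.tsv"),
            "vcf": os.path.join(out_dir, "variants.vcf"),
            "manifest": os.path.join(out_dir, "manifest.json"),
        }
        write_fasta(self.genome, paths["genome"])
        with open(paths["gtf"], "w") as fh:
            for tx in self.transcripts:
                for start, end in tx.exons:
                    attrs = (
                        f'gene_id "{tx.gene_symbol}"; '
                        f'transcript_id "{tx.transcript_id}"; '
                        f'gene_name "{tx.gene_symbol}";'
                    )
                    if tx.canonical_flag:
                        attrs += ' tag "Ensembl_canonical";'
                    fh.write(
                        f"{tx.contig}\tbpscan\texon\t{start}\t{end}\t.\t"
                        f"{tx.strand}\t.\t{attrs}\n"
                    )
        with open(paths["bp"], "w") as fh:
            fh.write("contig\tpos\tstrand\tdataset_id\tevidence_class\n")
            for r in self.bp_rows:
                fh.write(
                    f"{r['contig']}\t{r['pos']}\t{r['strand']}\t"
                    f"{r['dataset_id']}\t{r['evidence_class']}\n"
                )
        write_vcf(self.vcf_rows, paths["vcf"], contigs=self.genome)
        for kind, table in self.tracks.items():
            p = os.path.join(out_dir, f"track_{kind.lower()}.tsv")
            paths[f"track_{kind}"] = p
            with open(p, "w") as fh:
                fh.write("contig\tpos\tvalue\n")
                for (contig, pos), value in sorted(table.values.items()):
                    fh.write(f"{contig}\t{pos}\t{value!r}\n")
        with open(paths["manifest"], "w") as fh:
            json.dump(self.manifest, fh, indent=1, default=str)
        return paths


# --------------------------------------------------------------------------
# randomized fixtures


@dataclass
class FixtureSpec:
    """Parameters of a randomized fixture; same spec + seed = same bytes."""

    seed: int
    n_genes: int = 10
    exon_length: int = 150
    intron_length_range: tuple[int, int] = (100, 200)
    bp_per_intron: tuple[int, ...] = (1, 2, 3)
    consensus_levels: tuple[int, ...] = (1, 1, 1, 2, 3, 4)
    minus_strand_fraction: float = 0.5
    n_off_by_one: int = 0  # planted raw calls one nt off a level-1 BP
    variant_offsets: tuple[int, ...] = ()  # SNVs planted at these BP offsets
    n_random_variants: int = 0  # uniform SNVs/deletions inside introns
    datasets: tuple[tuple[str, str], ...] = (
        ("lariat_a", "experimental"),
        ("pred_a", "computational"),
    )


def _pick_distances(
    k: int, intron_len: int, rng: np.random.Generator
) -> list[int]:
    """k BP distances in [-min(90, L-10), -10] with >= 7 nt spacing."""
    low = -min(90, intron_len - 10)
    for _ in range(1000):
        ds = sorted(rng.choice(range(low, -9), size=k, replace=False).tolist())
        if all(b - a >= 7 for a, b in zip(ds, ds[1:])):
            return ds
    raise RuntimeError("could not place BPs with required spacing")


def generate_fixture(spec: FixtureSpec) -> FixtureBundle:
    rng = np.random.default_rng(spec.seed)
    genome: dict[str, GenomeSequence] = {}
    transcripts: list[TranscriptModel] = []
    bp_rows: list[dict] = []
    vcf_rows: list[tuple] = []
    manifest: dict = {"bps": [], "off_by_one": [], "variants": [], "spec_seed": spec.seed}

    planted: list[dict] = []  # for variant placement
    for g in range(spec.n_genes):
        contig = f"g{g:03d}"
        intron_len = int(rng.integers(*spec.intron_length_range, endpoint=True))
        exon = spec.exon_length
        i_start, i_end = exon + 1, exon + intron_len
        length = 2 * exon + intron_len
        strand = "-" if rng.random() < spec.minus_strand_fraction else "+"
        builder = _ContigBuilder(length, rng)
        # transcript-sense splice dinucleotides
        if strand == "+":
            builder.set_genomic(i_start, "GT")
            builder.set_genomic(i_end - 1, "AG")
            three_prime = i_end
        else:
            builder.set_genomic(i_end - 1, "AC")
            builder.set_genomic(i_start, "CT")
            three_prime = i_start
        k = int(rng.choice(spec.bp_per_intron))
        distances = _pick_distances(k, intron_len, rng)
        for d in distances:
            pos = three_prime + 1 + d if strand == "+" else three_prime - 1 - d
            level = int(rng.choice(spec.consensus_levels))
            _plant_bp(builder, pos, strand, level, rng)
            entry = {
                "contig": contig,
                "pos": pos,
                "strand": strand,
                "level": level,
                "distance": d,
                "intron": (i_start, i_end),
            }
            planted.append(entry)
            manifest["bps"].append(entry)
            for dataset_id, evidence in spec.datasets:
                bp_rows.append(
                    {
                        "contig": contig,
                        "pos": pos,
                        "strand": strand,
                        "dataset_id": dataset_id,
                        "evidence_class": evidence,
                    }
                )
        genome[contig] = builder.finish(contig)
        transcripts.append(
            TranscriptModel(
                transcript_id=f"ENST{g:08d}",
                gene_symbol=f"GENE{g:03d}",
                contig=contig,
                strand=strand,
                exons=[(1, exon), (i_end + 1, length)],
                canonical_flag=True,
            )
        )

    # off-by-one raw calls duplicating level-1 planted BPs
    level1 = [p for p in planted if p["level"] == 1]
    if spec.n_off_by_one > len(level1):
        raise ValueError("not enough level-1 BPs to plant off-by-one calls")
    dataset_id, evidence = spec.datasets[0]
    for p in level1[: spec.n_off_by_one]:
        step = 1 if p["strand"] == "+" else -1
        raw_pos = p["pos"] + step  # one nt transcript-downstream
        bp_rows.append(
            {
                "contig": p["contig"],
                "pos": raw_pos,
                "strand": p["strand"],
                "dataset_id": dataset_id,
                "evidence_class": evidence,
            }
        )
        manifest["off_by_one"].append(
            {"contig": p["contig"], "raw_pos": raw_pos, "true_pos": p["pos"]}
        )

    # planted SNVs at requested transcript offsets from planted BPs
    vid = 0
    for i, off in enumerate(spec.variant_offsets):
        p = planted[i % len(planted)]
        pos = p["pos"] + off if p["strand"] == "+" else p["pos"] - off
        contig_seq = genome[p["contig"]]
        if not 1 <= pos <= len(contig_seq):
            continue
        ref = contig_seq.base(pos)
        alt = str(rng.choice([b for b in _BASES if b != ref]))
        vid += 1
        vcf_rows.append((p["contig"], pos, f"v{vid}", ref, alt))
        manifest["variants"].append(
            {
                "id": f"v{vid}",
                "contig": p["contig"],
                "pos": pos,
                "offset": off,
                "target_bp": p["pos"],
                "strand": p["strand"],
            }
        )

    # random variants anywhere in introns (for brute-force comparisons)
    contig_names = sorted(genome)
    for _ in range(spec.n_random_variants):
        contig = str(rng.choice(contig_names))
        seq = genome[contig]
        tx = next(t for t in transcripts if t.contig == contig)
        i_start, i_end = tx.exons[0][1] + 1, tx.exons[1][0] - 1
        if rng.random() < 0.5:
            pos = int(rng.integers(i_start, i_end + 1))
            ref = seq.base(pos)
            alt = str(rng.choice([b for b in _BASES if b != ref]))
        else:
            dlen = int(rng.integers(1, 26))
            pos0 = int(rng.integers(i_start, max(i_start + 1, i_end - dlen)))
            ref = seq.slice(pos0 - 1, pos0 - 1 + dlen)
            alt = ref[0]
            pos = pos0 - 1
        vid += 1
        vcf_rows.append((contig, pos, f"v{vid}", ref, alt))

    return FixtureBundle(
        genome=genome,
        transcripts=transcripts,
        bp_rows=bp_rows,
        vcf_rows=vcf_rows,
        manifest=manifest,
    )


# --------------------------------------------------------------------------
# the 48-variant pathogenic panel
#
# Row fields: gene; printed genomic REF/ALT (SNVs) or deletion length;
# distance of the documented BP to the 3'ss; rank/total among the
# intron's BPs; disrupted offsets (None = not detected, the variant sits
# 10 nt transcript-downstream of the documented BP); assigned consensus
# level, BP evidence class, population and conservation context.  The
# level / class / population / conservation columns reproduce the
# published aggregate mixes (24/8/7/1 levels; 19 mBP / 1 eBP / 20 cBP;
# 38 clean + 2 rare; 33 conserved / 5 non-conserved / 2 mixed) -- the
# per-row attribution is not public, so it is fixed here arbitrarily but
# consistently with those totals.

PANEL_ROWS: tuple[dict, ...] = (
    dict(gene="ABCC8", ref="T", alt="C", dist=-20, rank=1, total=2, hits=(0,), level=2, bp_class="mBP", pop="none", cons="pos"),
    dict(gene="ALPL", del_len=20, dist=-33, rank=1, total=1, hits=(-2, -1, 0), level=1, bp_class="mBP", pop="none", cons="pos", strand="+"),
    dict(gene="BBS1", ref="A", alt="T", dist=-21, rank=1, total=1, hits=(0,), level=1, bp_class="mBP", pop="rare", cons="pos"),
    dict(gene="BTK", ref="T", alt="C", dist=-23, rank=1, total=1, hits=(0,), level=1, bp_class="mBP", pop="none", cons="pos"),
    dict(gene="C21orf2", ref="T", alt="A", dist=-23, rank=2, total=3, hits=(0,), level=3, bp_class="mBP", pop="none", cons="pos"),
    dict(gene="CAPN3", del_len=1, dist=-29, rank=1, total=1, hits=(-2,), level=1, bp_class="mBP", pop="none", cons="pos", strand="+"),
    dict(gene="CD40LG", del_len=8, dist=-32, rank=1, total=1, hits=(-2, -1, 0), level=1, bp_class="mBP", pop="none", cons="pos", strand="+"),
    dict(gene="CDT1", ref="A", alt="G", dist=-24, rank=1, total=1, hits=(0,), level=2, bp_class="mBP", pop="none", cons="pos"),
    dict(gene="COL4A5", ref="A", alt="G", dist=-40, rank=1, total=1, hits=(0,), level=1, bp_class="mBP", pop="none", cons="mixed"),
    dict(gene="COL5A1", ref="T", alt="G", dist=-25, rank=1, total=2, hits=(-2,), level=3, bp_class="mBP", pop="none", cons="pos"),
    dict(gene="COL7A1", ref="T", alt="C", dist=-23, rank=1, total=1, hits=(0,), level=1, bp_class="mBP", pop="none", cons="pos"),
    dict(gene="CPS1", ref="A", alt="G", dist=-24, rank=1, total=2, hits=(0,), level=2, bp_class="mBP", pop="none", cons="neg"),
    dict(gene="DYSF", ref="A", alt="G", dist=-33, rank=2, total=2, hits=(0,), level=4, bp_class="mBP", pop="none", cons="pos"),
    dict(gene="ENG", ref="A", alt="G", dist=-22, rank=1, total=2, hits=(-2,), level=2, bp_class="mBP", pop="none", cons="pos"),
    dict(gene="F8", ref="T", alt="C", dist=-27, rank=1, total=1, hits=(0,), level=1, bp_class="mBP", pop="none", cons="neg"),
    dict(gene="F9", ref="A", alt="G", dist=-25, rank=1, total=1, hits=(0,), level=2, bp_class="mBP", pop="none", cons="pos"),
    dict(gene="FAS", ref="A", alt="G", dist=-16, rank=1, total=1, hits=None, level=1, bp_class="cBP", pop="none", cons="pos"),
    dict(gene="FBN2", ref="A", alt="C", dist=-26, rank=1, total=1, hits=(-2,), level=1, bp_class="mBP", pop="none", cons="neg"),
    dict(gene="FBN2", ref="T", alt="C", dist=-15, rank=1, total=1, hits=None, level=1, bp_class="cBP", pop="none", cons="pos"),
    dict(gene="FGD1", del_len=1, dist=-35, rank=1, total=1, hits=(0,), level=1, bp_class="mBP", pop="none", cons="pos", strand="-"),
    dict(gene="HEXB", ref="A", alt="G", dist=-17, rank=1, total=1, hits=None, level=1, bp_class="cBP", pop="none", cons="pos"),
    dict(gene="IKBKG", ref="A", alt="T", dist=-23, rank=1, total=1, hits=(0,), level=1, bp_class="mBP", pop="none", cons="mixed"),
    dict(gene="ITGB2", ref="A", alt="C", dist=-12, rank=1, total=1, hits=None, level=1, bp_class="cBP", pop="none", cons="pos"),
    dict(gene="ITGB4", ref="T", alt="A", dist=-25, rank=1, total=1, hits=(-2,), level=1, bp_class="cBP", pop="none", cons="pos"),
    dict(gene="ITGB4", ref="T", alt="A", dist=-19, rank=1, total=1, hits=(-2,), level=1, bp_class="cBP", pop="none", cons="neg"),
    dict(gene="KCNH2", ref="T", alt="C", dist=-28, rank=1, total=1, hits=(0,), level=1, bp_class="cBP", pop="none", cons="neg"),
    dict(gene="L1CAM", ref="T", alt="G", dist=-19, rank=2, total=3, hits=(0,), level=1, bp_class="cBP", pop="none", cons="pos"),
    dict(gene="LCAT", ref="A", alt="G", dist=-22, rank=1, total=2, hits=(-2,), level=2, bp_class="cBP", pop="none", cons="pos"),
    dict(gene="LIPC", ref="A", alt="G", dist=-14, rank=1, total=1, hits=None, level=1, bp_class="cBP", pop="none", cons="pos"),
    dict(gene="LMX1B", del_len=17, dist=-37, rank=1, total=1, hits=(-2, -1, 0), level=1, bp_class="cBP", pop="none", cons="pos", strand="-"),
    dict(gene="MLH1", ref="T", alt="G", dist=-26, rank=2, total=3, hits=(-2,), level=3, bp_class="cBP", pop="none", cons="pos"),
    dict(gene="MLH1", ref="A", alt="G", dist=-24, rank=2, total=3, hits=(0,), level=1, bp_class="cBP", pop="none", cons="pos"),
    dict(gene="MSH2", ref="A", alt="G", dist=-24, rank=1, total=1, hits=(0,), level=1, bp_class="cBP", pop="rare", cons="pos"),
    dict(gene="MSH6", ref="T", alt="G", dist=-26, rank=2, total=3, hits=(-2,), level=3, bp_class="cBP", pop="none", cons="pos"),
    dict(gene="NPC1", ref="T", alt="C", dist=-28, rank=1, total=1, hits=(0,), level=1, bp_class="cBP", pop="none", cons="pos"),
    dict(gene="NTRK1", ref="T", alt="A", dist=-33, rank=1, total=1, hits=(-2,), level=1, bp_class="eBP", pop="none", cons="pos"),
    dict(gene="RB1", ref="A", alt="T", dist=-26, rank=1, total=2, hits=(-1,), level=1, bp_class="cBP", pop="none", cons="pos"),
    dict(gene="SLC25A20", ref="A", alt="C", dist=-10, rank=1, total=1, hits=None, level=1, bp_class="cBP", pop="none", cons="pos"),
    dict(gene="SLC5A2", del_len=22, dist=-31, rank=1, total=2, hits=(-2, -1, 0), level=1, bp_class="cBP", pop="none", cons="pos", strand="-"),
    dict(gene="TH", ref="A", alt="T", dist=-24, rank=3, total=3, hits=(-2,), level=3, bp_class="cBP", pop="none", cons="pos"),
    dict(gene="TSC2", ref="A", alt="G", dist=-18, rank=1, total=2, hits=(0,), level=2, bp_class="cBP", pop="none", cons="pos"),
    dict(gene="UROS", ref="A", alt="C", dist=-31, rank=1, total=1, hits=(-2,), level=2, bp_class="cBP", pop="none", cons="pos"),
    dict(gene="USH2A", ref="T", alt="C", dist=-17, rank=1, total=1, hits=None, level=1, bp_class="cBP", pop="none", cons="pos"),
    dict(gene="VMA21", ref="A", alt="C", dist=-27, rank=1, total=1, hits=(0,), level=1, bp_class="cBP", pop="none", cons="pos"),
    dict(gene="VMA21", ref="A", alt="T", dist=-27, rank=1, total=1, hits=(0,), level=1, bp_class="cBP", pop="none", cons="pos"),
    dict(gene="VWF", ref="T", alt="A", dist=-20, rank=1, total=2, hits=(0,), level=3, bp_class="cBP", pop="none", cons="pos"),
    dict(gene="XPC", ref="A", alt="T", dist=-9, rank=1, total=1, hits=None, level=1, bp_class="cBP", pop="none", cons="pos"),
    dict(gene="XPC", ref="T", alt="C", dist=-24, rank=1, total=1, hits=(0,), level=3, bp_class="cBP", pop="none", cons="pos"),
)

_PANEL_EXON = 150
_PANEL_INTRON = 140

#: genomic offset of the BP-2 variant window entry, by strand, used to
#: choose each SNV row's strand so that the printed genomic alleles are
#: consistent with the consensus core in transcript sense.
_EXPECTED_TS_REF = {0: "A", -2: "T"}


def _panel_strand(row: dict) -> str:
    if "strand" in row:
        return row["strand"]
    if row["hits"] is None:
        return "-" if row["dist"] % 2 else "+"
    offset = row["hits"][0] if len(row["hits"]) == 1 else 0
    expected = _EXPECTED_TS_REF.get(offset)
    if expected is None:  # offset -1: no consensus constraint on the base
        return "+"
    if row["ref"] == expected:
        return "+"
    if reverse_complement(row["ref"]) == expected:
        return "-"
    raise ValueError(f"panel row {row['gene']}: ref {row['ref']} unusable")


def _co_bp_distances(row: dict) -> list[int]:
    d, rank, total = row["dist"], row["rank"], row["total"]
    if total == 1:
        return []
    if total == 2:
        return [d - 7] if rank == 1 else [d + 7]
    if rank == 2:
        return [d + 7, d - 7]
    if rank == 3:
        return [d + 7, d + 14]
    raise ValueError(f"unsupported rank geometry {rank}/{total}")


_CONS_VALUES = {
    "pos": (1.9, 2.4),
    "neg": (-1.2, -0.8),
    "mixed": (-0.3, 0.4),
}

_CLASS_SOURCES = {
    "mBP": (("lariat_a", "experimental"), ("pred_a", "computational")),
    "eBP": (("lariat_a", "experimental"),),
    "cBP": (("pred_a", "computational"), ("pred_b", "computational")),
}


def build_validation_panel(seed: int = 0) -> FixtureBundle:
    """Synthetic loci reproducing the published panel's detection geometry."""
    rng = np.random.default_rng(seed)
    genome: dict[str, GenomeSequence] = {}
    transcripts: list[TranscriptModel] = []
    bp_rows: list[dict] = []
    vcf_rows: list[tuple] = []
    tracks = {
        "MAF": TrackTable("MAF"),
        "GERP": TrackTable("GERP"),
        "PhyloP": TrackTable("PhyloP"),
    }
    manifest_rows = []

    for i, row in enumerate(PANEL_ROWS):
        contig = f"ctg{i + 1:02d}"
        strand = _panel_strand(row)
        i_start, i_end = _PANEL_EXON + 1, _PANEL_EXON + _PANEL_INTRON
        length = 2 * _PANEL_EXON + _PANEL_INTRON
        builder = _ContigBuilder(length, rng)
        if strand == "+":
            builder.set_genomic(i_start, "GT")
            builder.set_genomic(i_end - 1, "AG")
            three_prime = i_end
        else:
            builder.set_genomic(i_end - 1, "AC")
            builder.set_genomic(i_start, "CT")
            three_prime = i_start

        def ts_pos(distance: int) -> int:
            return (
                three_prime + 1 + distance
                if strand == "+"
                else three_prime - 1 - distance
            )

        detected = row["hits"] is not None
        bp_dist = row["dist"] if detected else row["dist"] - 10
        bp_pos = ts_pos(bp_dist)

        # consensus core, honoring the variant's transcript-sense ref base
        fixed: dict[int, str] = {}
        if detected and "del_len" not in row and len(row["hits"]) == 1:
            off = row["hits"][0]
            ts_ref = row["ref"] if strand == "+" else reverse_complement(row["ref"])
            fixed[off] = ts_ref
        _plant_bp(builder, bp_pos, strand, row["level"], rng, fixed)
        for co_d in _co_bp_distances(row):
            _plant_bp(builder, ts_pos(co_d), strand, 1, rng)

        # the variant itself
        if "del_len" in row:
            L = row["del_len"]
            # deleted transcript offsets [o0, o0 + L - 1] relative to the BP
            o0 = row["hits"][0]
            if strand == "+":
                ds, de = bp_pos + o0, bp_pos + o0 + L - 1
            else:
                de = bp_pos - o0
                ds = de - (L - 1)
            seq = builder.get(ds - 1, de)
            vcf_rows.append((contig, ds - 1, f"p{i + 1}", seq, seq[0]))
            var_type = f"{L} nt-deletion"
        else:
            if detected:
                off = row["hits"][0]
                var_pos = bp_pos + off if strand == "+" else bp_pos - off
            else:
                var_pos = ts_pos(row["dist"])
                builder.set_genomic(var_pos, row["ref"])
            assert builder.get(var_pos, var_pos) == row["ref"], row["gene"]
            vcf_rows.append((contig, var_pos, f"p{i + 1}", row["ref"], row["alt"]))
            var_type = "snv"

        genome[contig] = builder.finish(contig)
        transcripts.append(
            TranscriptModel(
                transcript_id=f"ENST{90000000 + i + 1}",
                gene_symbol=row["gene"],
                contig=contig,
                strand=strand,
                exons=[(1, _PANEL_EXON), (i_end + 1, length)],
                canonical_flag=True,
            )
        )

        # BP dataset rows: the documented BP with its class-defining
        # sources, co-BPs as two-source computational calls
        for dataset_id, evidence in _CLASS_SOURCES[row["bp_class"]]:
            bp_rows.append(
                dict(contig=contig, pos=bp_pos, strand=strand,
                     dataset_id=dataset_id, evidence_class=evidence)
            )
        for co_d in _co_bp_distances(row):
            for dataset_id, evidence in _CLASS_SOURCES["cBP"]:
                bp_rows.append(
                    dict(contig=contig, pos=ts_pos(co_d), strand=strand,
                         dataset_id=dataset_id, evidence_class=evidence)
                )

        # annotation tracks at BP and BP-2 genomic positions
        bp2_pos = bp_pos - 2 if strand == "+" else bp_pos + 2
        gerp, phylop = _CONS_VALUES[row["cons"]]
        tracks["GERP"].values[(contig, bp_pos)] = gerp
        tracks["GERP"].values[(contig, bp2_pos)] = gerp
        tracks["PhyloP"].values[(contig, bp_pos)] = phylop
        tracks["PhyloP"].values[(contig, bp2_pos)] = phylop
        if row["pop"] == "rare":
            tracks["MAF"].values[(contig, bp_pos)] = 5e-06

        manifest_rows.append(
            dict(
                gene=row["gene"],
                contig=contig,
                strand=strand,
                var_type=var_type,
                detected=detected,
                hits=list(row["hits"]) if detected else None,
                distance=row["dist"],
                rank=row["rank"],
                total=row["total"],
                level=row["level"],
                bp_class=row["bp_class"],
            )
        )

    manifest = {"rows": manifest_rows, "expected": expected_panel_tallies()}
    return FixtureBundle(
        genome=genome,
        transcripts=transcripts,
        bp_rows=bp_rows,
        vcf_rows=vcf_rows,
        tracks=tracks,
        manifest=manifest,
    )


def expected_panel_tallies() -> dict:
    """Ground-truth tallies counted directly from the embedded panel table."""
    detected = [r for r in PANEL_ROWS if r["hits"] is not None]
    snv = [r for r in detected if "del_len" not in r]
    dels = [r for r in detected if "del_len" in r]
    by_level: dict[int, int] = {}
    by_class: dict[str, int] = {}
    for r in detected:
        by_level[r["level"]] = by_level.get(r["level"], 0) + 1
        by_class[r["bp_class"]] = by_class.get(r["bp_class"], 0) + 1
    bp_window_snv = [r for r in snv if r["hits"][0] in (0, -2)]
    return {
        "n_detected": len(detected),
        "n_not_detected": len(PANEL_ROWS) - len(detected),
        "snv_0": sum(1 for r in snv if r["hits"] == (0,)),
        "snv_-1": sum(1 for r in snv if r["hits"] == (-1,)),
        "snv_-2": sum(1 for r in snv if r["hits"] == (-2,)),
        "deletion_full_motif": sum(1 for r in dels if len(r["hits"]) == 3),
        "deletion_0": sum(1 for r in dels if r["hits"] == (0,)),
        "deletion_-2": sum(1 for r in dels if r["hits"] == (-2,)),
        "rank_only": sum(1 for r in detected if r["total"] == 1),
        "rank_first": sum(1 for r in detected if r["total"] > 1 and r["rank"] == 1),
        "rank_nonfirst": sum(1 for r in detected if r["rank"] > 1),
        "by_level": by_level,
        "by_class": by_class,
        "snv_bp_window_single_bp": sum(1 for r in bp_window_snv if r["total"] == 1),
        "snv_bp_window_total": len(bp_window_snv),
    }


# --------------------------------------------------------------------------
# strand mirroring


def _mirror_variant_row(
    row: tuple, genome: dict[str, GenomeSequence], mirrored: dict[str, GenomeSequence]
) -> tuple:
    from .io import trim_alleles

    chrom, pos, vid, ref, alt = row
    L = len(genome[chrom])
    t_ref, t_alt, shift = trim_alleles(ref, alt)
    pos += shift
    if len(t_ref) == 1 and len(t_alt) == 1:  # snv
        return (chrom, L - pos + 1, vid, reverse_complement(t_ref),
                reverse_complement(t_alt))
    if t_alt == "":  # deletion of [pos, pos+len-1]
        s, e = pos, pos + len(t_ref) - 1
        ms, me = L - e + 1, L - s + 1
        anchor = ms - 1
        seq = mirrored[chrom].slice(anchor, me)
        return (chrom, anchor, vid, seq, seq[0])
    if t_ref == "":  # insertion between pos-1 and pos
        b = pos - 1
        anchor = L - b
        base = mirrored[chrom].base(anchor)
        return (chrom, anchor, vid, base, base + reverse_complement(t_alt))
    raise ValueError("cannot mirror a complex substitution row")


def mirror_bundle(bundle: FixtureBundle) -> FixtureBundle:
    """Reverse-complement an entire fixture.

    Every contig is flipped, coordinates are remapped (p -> L - p + 1),
    strands invert, and variants are re-anchored against the mirrored
    genome.  Detection on the mirror must reproduce identical distances,
    ranks, and hit offsets, keyed by variant id.
    """
    mirrored_genome = {
        name: GenomeSequence(name, reverse_complement(g.sequence))
        for name, g in bundle.genome.items()
    }
    flip = {"+": "-", "-": "+"}

    def mpos(contig: str, pos: int) -> int:
        return len(bundle.genome[contig]) - pos + 1

    transcripts = [
        replace(
            tx,
            strand=flip[tx.strand],
            exons=[(mpos(tx.contig, e), mpos(tx.contig, s)) for s, e in tx.exons],
        )
        for tx in bundle.transcripts
    ]
    bp_rows = [
        {**r, "pos": mpos(r["contig"], r["pos"]), "strand": flip[r["strand"]]}
        for r in bundle.bp_rows
    ]
    vcf_rows = [
        _mirror_variant_row(row, bundle.genome, mirrored_genome)
        for row in bundle.vcf_rows
    ]
    tracks = {
        kind: TrackTable(
            kind,
            {(c, mpos(c, p)): v for (c, p), v in table.values.items()},
        )
        for kind, table in bundle.tracks.items()
    }
    return FixtureBundle(
        genome=mirrored_genome,
        transcripts=transcripts,
        bp_rows=bp_rows,
        vcf_rows=vcf_rows,
        tracks=tracks,
        manifest={"mirrored_from": bundle.manifest},
    )
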