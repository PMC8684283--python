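"""Readers and writers for the formats the pipeline touches.

Covers: multi-sample VCF (read via cyvcf2, GT-only v4.2 write), the
vcftools ``--freq2`` frequency-table dialect, BED, gene annotation
(GFF3/GTF via gffutils) and the GATK-style hard-filter site predicate.

Coordinate conventions: VCF and GFF intervals are 1-based inclusive
internally; BED output is 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

FREQ2_HEADER = "CHROM\tPOS\tN_ALLELES\tN_CHR\t{ALLELE:FREQ}"

#: GATK VariantFiltration predicates: a site FAILS iff the inequality holds
#: strictly.  Metrics absent from a record are not evaluated (cannot fail),
#: mirroring VariantFiltration's behaviour for missing annotations.
HARD_FILTERS: tuple[tuple[str, str, float], ...] = (
    ("QD", "<", 2.0),
    ("QUAL", "<", 30.0),
    ("MQ", "<", 40.0),
    ("SOR", ">", 3.0),
    ("FS", ">", 60.0),
    ("MQRankSum", "<", -12.5),
    ("ReadPosRankSum", "<", -8.0),
)


@dataclass
class SiteRecord:
    """One variant site with per-sample alt-allele dosages.

    ``dosages`` holds 0/1/2 per sample, or None where the genotype is
    missing or non-diploid.
    """

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_alleles: tuple[str, ...]
    dosages: tuple[int | None, ...]
    info_metrics: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.alt_alleles:
            raise ValueError(f"site {self.chrom}:{self.pos} has no alt allele")

    @property
    def n_alleles(self) -> int:
        return 1 + len(self.alt_alleles)

    @property
    def is_multiallelic(self) -> bool:
        return len(self.alt_alleles) > 1


@dataclass(frozen=True)
class FreqRecord:
    """One site of a per-breed allele-frequency table (reference allele first)."""

    chrom: str
    pos: int
    n_alleles: int
    n_chr: int
    freqs: tuple[float, ...]

    def __post_init__(self):
        if len(self.freqs) != self.n_alleles:
            raise ValueError(
                f"{self.chrom}:{self.pos}: {len(self.freqs)} frequencies for "
                f"{self.n_alleles} alleles"
            )
        if self.n_chr < 0:
            raise ValueError("n_chr must be non-negative")
        total = sum(self.freqs)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"{self.chrom}:{self.pos}: frequencies sum to {total}, not 1")

    @property
    def alt_freq(self) -> float:
        """Frequency of the (first) alternative allele."""
        return self.freqs[1]


@dataclass
class GeneModel:
    """A gene with the union of its transcript intervals (1-based inclusive)."""

    gene_id: str
    gene_name: str
    chrom: str
    transcripts: list[tuple[int, int]]

    def __post_init__(self):
        for start, end in self.transcripts:
            if start > end:
                raise ValueError(f"gene {self.gene_id}: interval {start}-{end} inverted")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_INFO_METRICS = ("QD", "MQ", "SOR", "FS", "MQRankSum", "ReadPosRankSum")


def read_vcf_sites(path: str | Path, samples: Sequence[str] | None = None) -> Iterator[SiteRecord]:
    """Stream SiteRecords from a VCF in file order.

    Multi-allelic sites are preserved with all alt alleles.  Missing or
    non-diploid GT calls yield dosage None for that sample.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    if samples is not None:
        vcf.set_samples(list(samples))
    try:
        for var in vcf:
            dosages: list[int | None] = []
            for gt in var.genotypes:  # [allele1, allele2, ..., phased]
                alleles = gt[:-1]
                if len(alleles) != 2 or any(a < 0 for a in alleles):
                    dosages.append(None)
                else:
                    dosages.append(int(alleles[0] > 0) + int(alleles[1] > 0))
            info = {}
            if var.QUAL is not None:
                info["QUAL"] = float(var.QUAL)
            for key in _INFO_METRICS:
                value = var.INFO.get(key)
                if value is not None:
                    info[key] = float(value)
            yield SiteRecord(
                chrom=var.CHROM,
                pos=var.POS,
                ref_allele=var.REF,
                alt_alleles=tuple(var.ALT),
                dosages=tuple(dosages),
                info_metrics=info,
            )
    finally:
        vcf.close()


def write_vcf(
    path: str | Path,
    sample_names: Sequence[str],
    sites: Iterable[SiteRecord],
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write a minimal GT-only VCF v4.2 (diploid, unphased)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contig_lengths:
            for name, length in contig_lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(sample_names) + "\n")
        gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", None: "./."}
        for site in sites:
            gts = "\t".join(gt_strings[d] for d in site.dosages)
            alt = ",".join(site.alt_alleles)
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref_allele}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# freq2 dialect
# ---------------------------------------------------------------------------


def write_freq2_table(records: Iterable[FreqRecord], path: str | Path) -> None:
    """Write a vcftools ``--freq2``-dialect table.

    Frequencies are serialized with the shortest decimal representation
    that round-trips exactly (at least 6 significant digits where needed),
    so read∘write is the identity.
    """
    with open(path, "w") as fh:
        fh.write(FREQ2_HEADER + "\n")
        for rec in records:
            freqs = "\t".join(repr(float(f)) for f in rec.freqs)
            fh.write(f"{rec.chrom}\t{rec.pos}\t{rec.n_alleles}\t{rec.n_chr}\t{freqs}\n")


def read_freq2_table(path: str | Path) -> list[FreqRecord]:
    """Read a ``--freq2``-dialect table; validates each row's frequency sum."""
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("CHROM\tPOS"):
            raise ValueError(f"{path}: unrecognized freq2 header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected >= 6 columns")
            try:
                records.append(
                    FreqRecord(
                        chrom=fields[0],
                        pos=int(fields[1]),
                        n_alleles=int(fields[2]),
                        n_chr=int(fields[3]),
                        freqs=tuple(float(f) for f in fields[4:]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return records


def freq2_to_dataframe(records: Iterable[FreqRecord]) -> pd.DataFrame:
    """Biallelic-view DataFrame (chrom, pos, n_alleles, n_chr, alt_freq)."""
    rows = [(r.chrom, r.pos, r.n_alleles, r.n_chr, r.freqs[1]) for r in records]
    return pd.DataFrame(rows, columns=["chrom", "pos", "n_alleles", "n_chr", "alt_freq"])


# ---------------------------------------------------------------------------
# Hard filters
# ---------------------------------------------------------------------------


def apply_hard_filters(site: SiteRecord) -> tuple[bool, list[str]]:
    """GATK-style hard-filter predicate.

    Returns ``(passed, failed_reasons)``.  A site fails iff any configured
    inequality holds strictly; values exactly at a threshold pass.
    """
    reasons = []
    for metric, op, threshold in HARD_FILTERS:
        value = site.info_metrics.get(metric)
        if value is None:
            continue
        if (op == "<" and value < threshold) or (op == ">" and value > threshold):
            reasons.append(f"{metric} {op} {threshold}")
    return (not reasons, reasons)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def write_bed(
    intervals: Iterable[tuple], path: str | Path, *, extra_float_cols: bool = False
) -> None:
    """Write BED rows ``(chrom, start, end[, name, score...])`` (0-based half-open)."""
    with open(path, "w") as fh:
        for row in intervals:
            chrom, start, end, *rest = row
            fields = [str(chrom), str(int(start)), str(int(end))]
            fields += [repr(x) if isinstance(x, float) else str(x) for x in rest]
            fh.write("\t".join(fields) + "\n")


def read_bed(path: str | Path) -> list[tuple]:
    """Read BED rows back as ``(chrom, start, end, *extra)`` tuples."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        extra = []
        for f in fields[3:]:
            try:
                extra.append(float(f) if "." in f or "e" in f else int(f))
            except ValueError:
                extra.append(f)
        rows.append((fields[0], int(fields[1]), int(fields[2]), *extra))
    return rows


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

_TRANSCRIPT_TYPES = {"mRNA", "transcript", "lnc_RNA", "ncRNA", "rRNA", "tRNA", "miRNA"}


def read_gene_annotation(path: str | Path, fmt: str | None = None) -> list[GeneModel]:
    """Load gene models from GFF3 or GTF.

    Each gene carries the union of its transcript intervals; a gene with no
    annotated transcript contributes its own span as a single interval.
    Features that cannot be tied to a gene id are skipped (count logged).
    """
    import gffutils

    path = Path(path)
    if fmt is None:
        fmt = "GTF" if path.suffix.lower() in {".gtf"} else "GFF3"
    if fmt.upper() not in {"GFF3", "GTF"}:
        raise ValueError(f"unknown annotation format {fmt!r}")

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    def _gene_id_of(feature) -> str | None:
        if "gene_id" in feature.attributes:
            return feature.attributes["gene_id"][0].removeprefix("gene:")
        for parent in feature.attributes.get("Parent", []):
            return parent.removeprefix("gene:")
        return None

    # transcripts grouped by gene id, independent of whether the dialect
    # carries explicit gene features (GFF3) or only transcripts (GTF)
    intervals: dict[str, list[tuple[int, int]]] = {}
    chrom_of: dict[str, str] = {}
    name_of: dict[str, str] = {}
    skipped = 0
    for feature in db.all_features():
        if feature.featuretype == "gene":
            gid = feature.attributes.get("gene_id", [feature.id])[0].removeprefix("gene:")
            chrom_of.setdefault(gid, feature.seqid)
            name = feature.attributes.get("gene_name", []) or feature.attributes.get("Name", [])
            if name:
                name_of.setdefault(gid, name[0])
            intervals.setdefault(gid, [])
        elif feature.featuretype in _TRANSCRIPT_TYPES:
            gid = _gene_id_of(feature)
            if gid is None:
                skipped += 1
                continue
            intervals.setdefault(gid, []).append((feature.start, feature.end))
            chrom_of.setdefault(gid, feature.seqid)
            name = feature.attributes.get("gene_name", [])
            if name:
                name_of.setdefault(gid, name[0])
    if skipped:
        log.info("skipped %d transcript features without a gene id", skipped)

    genes: list[GeneModel] = []
    for gid in intervals:
        spans = sorted(set(intervals[gid]))
        if not spans:
            try:
                gene = db[f"gene:{gid}"]
            except gffutils.FeatureNotFoundError:
                gene = db[gid]
            spans = [(gene.start, gene.end)]
        genes.append(GeneModel(gid, name_of.get(gid, gid), chrom_of[gid], spans))
    return genes
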