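"""Gene assignment to flagged segments and cross-referencing.

Segments come from the scan in window (Mb) units; genes come from
GFF3/GTF as transcript intervals in bp.  A gene is assigned to a
segment when at least one transcript lies entirely within it
(``contained`` mode, the default) or intersects it (``overlap`` mode).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

from .scan import SegmentSet
from .vcfio import GeneModel


@dataclass
class GeneAssignment:
    """Per-segment gene assignments.  ``table`` columns: chrom, start_mb,
    end_mb, gene_id, gene_name.  ``mode`` is recorded for provenance."""

    table: pd.DataFrame
    mode: str

    def genes_in_segment(self, chrom: str, start_mb: int) -> list[str]:
        sel = (self.table["chrom"] == chrom) & (self.table["start_mb"] == start_mb)
        return sorted(self.table.loc[sel, "gene_name"])

    @property
    def n_genes(self) -> int:
        """Distinct genes assigned to at least one segment."""
        return self.table["gene_id"].nunique()


def assign_genes_to_segments(
    genes: list[GeneModel], segments: SegmentSet, mode: str = "contained"
) -> GeneAssignment:
    """Assign genes to segments by transcript position.

    ``contained``: >= 1 transcript entirely within the segment;
    ``overlap``: >= 1 transcript intersecting it.  A gene may appear in
    several segments; duplicate gene/segment pairs are deduplicated.
    """
    if mode not in ("contained", "overlap"):
        raise ValueError(f"mode must be 'contained' or 'overlap', got {mode!r}")
    w = segments.grid.width
    lengths = segments.grid.layout.lengths
    for gene in genes:
        limit = lengths.get(gene.chrom)
        if limit is not None and any(end > limit for _, end in gene.transcripts):
            raise ValueError(
                f"gene {gene.gene_id} exceeds {gene.chrom} bounds; coordinate system mismatch?"
            )
    rows = []
    for seg in segments.table.itertuples():
        seg_start = seg.start_mb * w + 1  # 1-based inclusive
        seg_end = seg.end_mb * w
        for gene in genes:
            if gene.chrom != seg.chrom:
                continue
            if mode == "contained":
                hit = any(s >= seg_start and e <= seg_end for s, e in gene.transcripts)
            else:
                hit = any(s <= seg_end and e >= seg_start for s, e in gene.transcripts)
            if hit:
                rows.append((seg.chrom, seg.start_mb, seg.end_mb, gene.gene_id, gene.gene_name))
    table = pd.DataFrame(
        rows, columns=["chrom", "start_mb", "end_mb", "gene_id", "gene_name"]
    ).drop_duplicates(["chrom", "start_mb", "gene_id"], ignore_index=True)
    return GeneAssignment(table=table, mode=mode)


def crossref_gene_list(assignment: GeneAssignment, reference_list: list[str]) -> pd.DataFrame:
    """Intersect assigned genes with a reference symbol list (case-insensitive).

    Returns one row per segment with its matched symbols; the totals are
    available via :func:`crossref_totals`.
    """
    if not reference_list:
        warnings.warn("empty reference gene list; report will be empty")
    wanted = {name.strip().upper() for name in reference_list if name.strip()}
    rows = []
    for (chrom, start_mb, end_mb), sub in assignment.table.groupby(
        ["chrom", "start_mb", "end_mb"], sort=False
    ):
        matches = sorted(n for n in sub["gene_name"] if n.upper() in wanted)
        rows.append((chrom, start_mb, end_mb, len(matches), ", ".join(matches)))
    return pd.DataFrame(
        rows, columns=["chrom", "start_mb", "end_mb", "n_matched", "matched_genes"]
    )


def crossref_totals(report: pd.DataFrame) -> tuple[int, int]:
    """(total matched genes, segments with >= 1 match) from a crossref report."""
    total = int(report["n_matched"].sum())
    segments = int((report["n_matched"] > 0).sum())
    return total, segments


def expected_gene_count(
    total_genes: int, flagged_fraction: float, observed: int | None = None
) -> tuple[int, int | None]:
    """Expected-by-chance gene count in flagged regions, and the deficit.

    Expectation = total_genes * flagged_fraction, rounded half away from
    zero (genes uniform over windows); deficit = expectation - observed.
    """
    if not 0 <= flagged_fraction <= 1:
        raise ValueError("flagged_fraction must lie in [0, 1]")
    raw = total_genes * flagged_fraction
    expectation = int(math.floor(abs(raw) + 0.5)) * (1 if raw >= 0 else -1)
    deficit = expectation - observed if observed is not None else None
    return expectation, deficit


def segment_report(
    segments: SegmentSet, assignment: GeneAssignment, positive_list: list[str] | None = None
) -> pd.DataFrame:
    """Segment table with annotated genes (and positive-selection matches)."""
    wanted = {n.strip().upper() for n in positive_list} if positive_list else set()
    rows = []
    for seg in segments.table.itertuples():
        names = assignment.genes_in_segment(seg.chrom, seg.start_mb)
        positives = sorted(n for n in names if n.upper() in wanted)
        rows.append(
            (
                seg.chrom,
                seg.start_mb,
                seg.end_mb,
                seg.total_delta,
                seg.size_mb,
                "; ".join(names),
                "; ".join(positives),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start_mb", "end_mb", "total_delta", "size_mb", "genes", "positive_genes"],
    )
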