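"""Reference-haplotype validation: pseudo-sample, merge, partition, PCA.

The reference assembly itself is placed into genotype space as a
pseudo-individual that is homozygous for the reference allele at every
variant position (dosage 0 everywhere).  After merging per-breed
genotype matrices and removing sites with more than two observed
alleles, PCA on dosages restricted to inside- versus outside-segment
sites shows which ancestry cluster the assembly locally belongs to.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .scan import SegmentSet

log = logging.getLogger(__name__)

REFERENCE_HAPLOTYPE_ID = "reference_haplotype"


@dataclass
class GenotypeMatrix:
    """samples x biallelic-sites alt-allele dosage matrix, no missing values.

    ``sites`` columns: chrom, pos, ref, alt.  ``labels`` carries the
    population label per sample (e.g. breed or subspecies).
    """

    sample_ids: list[str]
    labels: list[str]
    sites: pd.DataFrame
    dosages: np.ndarray  # (n_samples, n_sites), values in {0, 1, 2}

    def __post_init__(self):
        n_samples, n_sites = self.dosages.shape
        if len(self.sample_ids) != n_samples or len(self.labels) != n_samples:
            raise ValueError("sample ids/labels do not match dosage matrix rows")
        if len(self.sites) != n_sites:
            raise ValueError("site table does not match dosage matrix columns")
        if len(set(self.sample_ids)) != n_samples:
            raise ValueError("duplicate sample ids")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]


@dataclass
class PcaResult:
    sample_ids: list[str]
    labels: list[str]
    coordinates: np.ndarray  # (n_samples, n_components)
    eigenvalues: np.ndarray  # non-increasing
    variance_fractions: np.ndarray
    provenance: dict = field(default_factory=dict)

    def coordinate_of(self, sample_id: str, component: int = 0) -> float:
        return float(self.coordinates[self.sample_ids.index(sample_id), component])


def build_reference_haplotype(
    site_index: pd.DataFrame, sample_id: str = REFERENCE_HAPLOTYPE_ID
) -> GenotypeMatrix:
    """Pseudo-individual homozygous for the reference allele at every site."""
    if len(site_index) == 0:
        raise ValueError("empty site index")
    return GenotypeMatrix(
        sample_ids=[sample_id],
        labels=["reference"],
        sites=site_index.reset_index(drop=True),
        dosages=np.zeros((1, len(site_index)), dtype=np.int8),
    )


def merge_and_biallelicize(matrices: list[GenotypeMatrix]) -> GenotypeMatrix:
    """Merge per-breed matrices on (chrom, pos), keeping clean biallelic sites.

    Sites are intersected across all inputs (so no dosage is missing).
    A site is dropped when the union of observed alleles exceeds two
    (multi-/triallelic) or when allele pairs are irreconcilable; a site
    whose ref/alt are swapped between inputs is reconciled by flipping
    dosages (2 - dosage).  Drop and flip counts are logged.
    """
    if not matrices:
        raise ValueError("nothing to merge")
    all_ids = [sid for m in matrices for sid in m.sample_ids]
    if len(set(all_ids)) != len(all_ids):
        dupes = sorted({s for s in all_ids if all_ids.count(s) > 1})
        raise ValueError(f"duplicate sample ids across inputs: {dupes}")

    keyed = []
    for m in matrices:
        idx = pd.MultiIndex.from_frame(m.sites[["chrom", "pos"]])
        if idx.has_duplicates:
            raise ValueError("duplicate (chrom, pos) within one input matrix")
        keyed.append(idx)
    common = keyed[0]
    for idx in keyed[1:]:
        common = common.intersection(idx)
    common = common.sort_values()

    n_multi = n_flip = n_irrec = 0
    kept_keys = []
    columns: list[np.ndarray] = []  # per kept site, concatenated dosage column
    lookups = [pd.Series(np.arange(len(idx)), index=idx) for idx in keyed]
    for key in common:
        site_cols = []
        ref0 = alt0 = None
        ok = True
        flip_count = 0
        alleles_union: set[str] = set()
        for m, lookup in zip(matrices, lookups):
            j = int(lookup[key])
            ref, alt = m.sites.iloc[j]["ref"], m.sites.iloc[j]["alt"]
            alleles_union.update((ref, alt))
            if ref0 is None:
                ref0, alt0 = ref, alt
                site_cols.append(m.dosages[:, j])
            elif (ref, alt) == (ref0, alt0):
                site_cols.append(m.dosages[:, j])
            elif (ref, alt) == (alt0, ref0):
                site_cols.append(2 - m.dosages[:, j])
                flip_count += 1
            else:
                ok = False
        if len(alleles_union) > 2:
            n_multi += 1
            continue
        if not ok:
            n_irrec += 1
            continue
        n_flip += flip_count
        kept_keys.append(key)
        columns.append(np.concatenate(site_cols))

    if n_multi or n_irrec or n_flip:
        log.info(
            "merge: dropped %d multiallelic and %d irreconcilable sites; "
            "flipped %d swapped ref/alt columns",
            n_multi,
            n_irrec,
            n_flip,
        )
    first_sites = matrices[0].sites.set_index(
        pd.MultiIndex.from_frame(matrices[0].sites[["chrom", "pos"]])
    )
    sites = first_sites.loc[kept_keys, ["chrom", "pos", "ref", "alt"]].reset_index(drop=True)
    dosages = (
        np.stack(columns, axis=1)
        if columns
        else np.zeros((len(all_ids), 0), dtype=np.int8)
    )
    return GenotypeMatrix(
        sample_ids=all_ids,
        labels=[lab for m in matrices for lab in m.labels],
        sites=sites,
        dosages=dosages,
    )


def merge_dense(matrices: list[GenotypeMatrix]) -> GenotypeMatrix:
    """Fast merge for matrices known to share an identical biallelic site index."""
    if not matrices:
        raise ValueError("nothing to merge")
    all_ids = [sid for m in matrices for sid in m.sample_ids]
    if len(set(all_ids)) != len(all_ids):
        raise ValueError("duplicate sample ids across inputs")
    base = matrices[0].sites
    for m in matrices[1:]:
        if not base[["chrom", "pos", "ref", "alt"]].equals(m.sites[["chrom", "pos", "ref", "alt"]]):
            raise ValueError("site indexes differ; use merge_and_biallelicize")
    return GenotypeMatrix(
        sample_ids=all_ids,
        labels=[lab for m in matrices for lab in m.labels],
        sites=base.reset_index(drop=True),
        dosages=np.vstack([m.dosages for m in matrices]),
    )


def partition_sites_by_segments(
    matrix: GenotypeMatrix, segments: SegmentSet
) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Split sites into (inside-segments, outside-segments) matrices.

    Segments are half-open in window units: a 1-based position pos is
    inside [start_mb, end_mb) iff start_mb*W < pos <= end_mb*W.
    """
    w = segments.grid.width
    inside = np.zeros(matrix.n_sites, dtype=bool)
    pos = matrix.sites["pos"].to_numpy()
    chroms = matrix.sites["chrom"].to_numpy()
    for row in segments.table.itertuples():
        sel = (chroms == row.chrom) & (pos > row.start_mb * w) & (pos <= row.end_mb * w)
        inside |= sel

    def _subset(mask: np.ndarray) -> GenotypeMatrix:
        return GenotypeMatrix(
            sample_ids=list(matrix.sample_ids),
            labels=list(matrix.labels),
            sites=matrix.sites.loc[mask].reset_index(drop=True),
            dosages=matrix.dosages[:, mask],
        )

    return _subset(inside), _subset(~inside)


def run_pca(matrix: GenotypeMatrix, n_components: int = 5) -> PcaResult:
    """PCA of the sample x site dosage matrix.

    Sites are mean-centered and variance-standardized (zero-variance
    sites dropped first), matching the usual genotype-PCA convention.
    Deterministic up to per-component sign.  If fewer samples than
    requested components are available the count is truncated with a
    warning.
    """
    if matrix.n_samples < 2 or matrix.n_sites < 2:
        raise ValueError("PCA needs at least 2 samples and 2 sites")
    x = np.ascontiguousarray(matrix.dosages, dtype=np.float32)
    n = x.shape[0]
    mean = x.mean(axis=0)
    var = np.einsum("ij,ij->j", x, x) / n - mean**2
    keep = var > 1e-12
    if not keep.any():
        raise ValueError("no polymorphic sites")
    x = (x[:, keep] - mean[keep]) / np.sqrt(var[keep])

    max_comp = min(matrix.n_samples - 1, x.shape[1])
    if n_components > max_comp:
        log.warning("truncating PCA from %d to %d components", n_components, max_comp)
        n_components = max_comp

    # samples << sites: exact PCA via the sample-sample Gram matrix
    gram = (x @ x.T).astype(np.float64)
    eigvals, eigvecs = np.linalg.eigh(gram)
    order = np.argsort(eigvals)[::-1][:n_components]
    lam = np.clip(eigvals[order], 0.0, None)
    coords = eigvecs[:, order] * np.sqrt(lam)
    total_var = float(np.trace(gram))
    return PcaResult(
        sample_ids=list(matrix.sample_ids),
        labels=list(matrix.labels),
        coordinates=coords,
        eigenvalues=lam / (matrix.n_samples - 1),
        variance_fractions=lam / total_var if total_var > 0 else np.zeros_like(lam),
        provenance={"standardized": True, "n_sites_used": int(keep.sum())},
    )


def nearest_label_on_pc(
    pca: PcaResult, sample_id: str, candidate_labels: list[str], component: int = 0
) -> str:
    """Label whose centroid on one PC is nearest to the given sample."""
    coord = pca.coordinate_of(sample_id, component)
    centroids = {}
    axis = pca.coordinates[:, component]
    for label in candidate_labels:
        member = [i for i, lab in enumerate(pca.labels) if lab == label]
        if not member:
            raise ValueError(f"no samples labelled {label!r}")
        centroids[label] = float(np.mean(axis[member]))
    return min(centroids, key=lambda lab: abs(coord - centroids[lab]))


# ---------------------------------------------------------------------------
# Admixture-tool I/O (model fitting is delegated to the external tool)
# ---------------------------------------------------------------------------


def export_admixture_input(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Transposed text genotypes: one row per site, one column per sample."""
    np.savetxt(path, matrix.dosages.T, fmt="%d", delimiter=" ")


def ingest_q_matrix(path: str | Path, sample_ids: list[str] | None = None) -> pd.DataFrame:
    """Parse a K-column ancestry-fraction (Q) table; rows must sum to 1 +- 1e-4."""
    q = np.loadtxt(path, ndmin=2)
    bad = np.abs(q.sum(axis=1) - 1.0) > 1e-4
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(f"Q row {row} sums to {q[row].sum():.6f}, not 1")
    df = pd.DataFrame(q, columns=[f"K{i + 1}" for i in range(q.shape[1])])
    if sample_ids is not None:
        if len(sample_ids) != len(df):
            raise ValueError("sample id count does not match Q rows")
        df.insert(0, "sample", sample_ids)
    return df
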