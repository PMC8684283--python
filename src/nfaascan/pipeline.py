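"""End-to-end helpers chaining the generator, filters and scan."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layout import WindowGrid
from .scan import (
    DeltaTrack,
    FlaggedWindows,
    SegmentSet,
    WindowCountTrack,
    compact_segments,
    count_in_windows,
    delta_track,
    flag_windows,
    group_mean_track,
)
from .sitefilter import AlleleFrequencySet, select_nfaa
from .simulate import SimulatedDataset


@dataclass
class ScanResult:
    group_track: WindowCountTrack
    delta: DeltaTrack
    flags: FlaggedWindows
    segments: SegmentSet
    grid: WindowGrid


def scan_breeds(
    dataset: SimulatedDataset,
    breeds: list[str] | None = None,
    window: int = 1_000_000,
    nfaa_threshold: float = 0.95,
    k_sd: float = 1.5,
) -> ScanResult:
    """Scan the group-mean NFAA track of the given breeds of a simulated dataset.

    ``breeds`` defaults to the pure subspecies-A breeds (the group whose
    ancestry is discordant with the bulk of the reference).
    """
    cfg = dataset.config
    if breeds is None:
        breeds = [b.name for b in cfg.breeds if b.subspecies == "A" and b.q == 1.0]
    grid = WindowGrid(cfg.layout(), window)
    tracks = []
    for name in breeds:
        freqs = AlleleFrequencySet(name, "synthetic", dataset.breed_frequency_table(name))
        nfaa = select_nfaa(freqs, nfaa_threshold)
        tracks.append(count_in_windows(nfaa, grid))
    group = group_mean_track(tracks, label="+".join(breeds))
    delta = delta_track(group)
    flags = flag_windows(delta, k_sd=k_sd)
    segments = compact_segments(flags, delta)
    return ScanResult(group, delta, flags, segments, grid)


def reference_placement(
    dataset: SimulatedDataset,
    result: ScanResult | None = None,
    max_pca_sites: int = 30_000,
) -> tuple[str, str]:
    """Which ancestry cluster the all-reference pseudo-sample joins on PC1.

    Runs the scan (unless given), merges all breeds' genotypes with the
    reference-haplotype pseudo-sample, partitions sites by the detected
    segments and returns the nearest pure-subspecies label
    ``(inside_segments, outside_segments)``.
    """
    from .validation import (
        GenotypeMatrix,
        REFERENCE_HAPLOTYPE_ID,
        build_reference_haplotype,
        merge_dense,
        nearest_label_on_pc,
        partition_sites_by_segments,
        run_pca,
    )

    if not dataset.genotypes:
        raise ValueError("dataset was simulated without genotypes")
    if result is None:
        result = scan_breeds(dataset)
    site_index = dataset.sites[["chrom", "pos", "ref", "alt"]]
    mats = []
    for b in dataset.config.breeds:
        label = b.subspecies if b.q in (0.0, 1.0) else "admixed"
        mats.append(
            GenotypeMatrix(
                sample_ids=[f"{b.name}_{i + 1}" for i in range(b.n_individuals)],
                labels=[label] * b.n_individuals,
                sites=site_index,
                dosages=dataset.genotypes[b.name],
            )
        )
    mats.append(build_reference_haplotype(site_index))
    merged = merge_dense(mats)
    inside, outside = partition_sites_by_segments(merged, result.segments)

    def _thin(m):
        # deterministic stride subsampling keeps the PCA cheap without
        # changing which cluster the pseudo-sample joins
        if m.n_sites <= max_pca_sites:
            return m
        step = m.n_sites // max_pca_sites + 1
        idx = np.arange(0, m.n_sites, step)
        return GenotypeMatrix(
            sample_ids=list(m.sample_ids),
            labels=list(m.labels),
            sites=m.sites.iloc[idx].reset_index(drop=True),
            dosages=m.dosages[:, idx],
        )

    pca_in = run_pca(_thin(inside), 5)
    pca_out = run_pca(_thin(outside), 5)
    return (
        nearest_label_on_pc(pca_in, REFERENCE_HAPLOTYPE_ID, ["A", "B"]),
        nearest_label_on_pc(pca_out, REFERENCE_HAPLOTYPE_ID, ["A", "B"]),
    )
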