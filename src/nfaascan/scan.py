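"""The windowed NFAA depletion scan.

Per 1-Mb window i the statistic is

    A_i     = number of NFAA sites in window i,
    delta_i = mu(A) - A_i,

with mu(A) the genome-wide mean over all autosomal windows (zero-count
and truncated terminal windows included).  Windows whose delta exceeds
mu(delta) + k*sd(delta) (strict inequality, default k = 1.5) are
flagged as NFAA-depleted — candidate regions where the reference
assembly locally shares ancestry with the scanned breed group — and
maximal runs of flagged windows are compacted into segments.

Standard deviations are sample standard deviations (n-1 denominator);
terminal partial windows keep raw counts (no length normalization).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .layout import WindowGrid
from .sitefilter import NfaaSiteSet

DEFAULT_K_SD = 1.5


@dataclass
class WindowCountTrack:
    """Per-window NFAA counts A_i for one breed (ints) or group mean (floats)."""

    label: str
    grid: WindowGrid
    counts: dict[str, np.ndarray]

    def values(self) -> np.ndarray:
        return self.grid.flatten(self.counts)

    def total(self) -> float:
        return float(self.values().sum())


@dataclass
class DeltaTrack:
    """Per-window delta_i = mu(A) - A_i plus the moments used to build it."""

    label: str
    grid: WindowGrid
    deltas: dict[str, np.ndarray]
    mu_a: float
    sd_a: float
    mu_delta: float
    sd_delta: float

    def values(self) -> np.ndarray:
        return self.grid.flatten(self.deltas)


@dataclass
class FlaggedWindows:
    """The thresholded window set T as per-chromosome boolean masks."""

    grid: WindowGrid
    mask: dict[str, np.ndarray]
    k_sd: float
    threshold: float

    @property
    def n_flagged(self) -> int:
        return int(sum(m.sum() for m in self.mask.values()))

    def window_set(self) -> set[tuple[str, int]]:
        return {
            (chrom, int(k))
            for chrom, m in self.mask.items()
            for k in np.flatnonzero(m)
        }


@dataclass
class SegmentSet:
    """Compacted maximal runs of flagged windows.

    ``table`` columns: chrom, start_mb (inclusive), end_mb (exclusive),
    total_delta, size_mb.  Window addresses are in units of the grid
    width (Mb for the default 1-Mb grid).
    """

    table: pd.DataFrame
    grid: WindowGrid
    k_sd: float
    member_windows: list[list[int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.table)

    def to_bed_rows(self) -> list[tuple]:
        """0-based half-open bp intervals with total_delta as score."""
        w = self.grid.width
        return [
            (r.chrom, int(r.start_mb) * w, min(int(r.end_mb) * w, self.grid.layout.lengths[r.chrom]), f"segment_{i}", float(r.total_delta))
            for i, r in enumerate(self.table.itertuples())
        ]


def count_in_windows(nfaa: NfaaSiteSet, grid: WindowGrid, label: str | None = None) -> WindowCountTrack:
    """Assign each NFAA site to its window and count (Notation: A_i).

    Every grid window is present, zero-count windows included.  A site
    beyond its chromosome's length raises with the offending site named.
    """
    counts = {chrom: np.zeros(grid.n_windows[chrom], dtype=float) for chrom in grid.chroms}
    for chrom, sub in nfaa.table.groupby("chrom", sort=False):
        if chrom not in counts:
            raise ValueError(f"NFAA site on {chrom!r}, which is not in the grid")
        pos = sub["pos"].to_numpy()
        length = grid.layout.lengths[chrom]
        bad = (pos < 1) | (pos > length)
        if bad.any():
            p = int(pos[bad][0])
            raise ValueError(f"site {chrom}:{p} beyond chromosome length {length}")
        idx = (pos - 1) // grid.width
        counts[chrom] += np.bincount(idx, minlength=grid.n_windows[chrom])
    return WindowCountTrack(label=label or nfaa.breed, grid=grid, counts=counts)


def group_mean_track(tracks: list[WindowCountTrack], label: str = "group") -> WindowCountTrack:
    """Per-window arithmetic mean across breed tracks sharing one grid."""
    if not tracks:
        raise ValueError("no tracks to average")
    grid = tracks[0].grid
    for t in tracks[1:]:
        if not grid.same_grid(t.grid):
            raise ValueError(f"track {t.label!r} uses a different window grid")
    counts = {
        chrom: np.mean([t.counts[chrom] for t in tracks], axis=0) for chrom in grid.chroms
    }
    return WindowCountTrack(label=label, grid=grid, counts=counts)


def zscore_track(track: WindowCountTrack) -> dict[str, np.ndarray]:
    """Per-window z_i = (A_i - mu(A)) / sd(A); sd is the sample sd."""
    values = track.values()
    mu = values.mean()
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("constant track: standard deviation is zero")
    return {chrom: (track.counts[chrom] - mu) / sd for chrom in track.grid.chroms}


def delta_track(track: WindowCountTrack) -> DeltaTrack:
    """delta_i = mu(A) - A_i, mu(A) over ALL grid windows.

    Large positive delta marks NFAA-depleted windows.  By construction
    sum(delta) = 0 and mu(delta) = 0 up to rounding.
    """
    values = track.values()
    if values.size == 0:
        raise ValueError("empty grid")
    mu_a = float(values.mean())
    sd_a = float(values.std(ddof=1)) if values.size > 1 else 0.0
    deltas = {chrom: mu_a - track.counts[chrom] for chrom in track.grid.chroms}
    dvals = mu_a - values
    return DeltaTrack(
        label=track.label,
        grid=track.grid,
        deltas=deltas,
        mu_a=mu_a,
        sd_a=sd_a,
        mu_delta=float(dvals.mean()),
        sd_delta=float(dvals.std(ddof=1)) if values.size > 1 else 0.0,
    )


def flag_windows(delta: DeltaTrack, k_sd: float = DEFAULT_K_SD) -> FlaggedWindows:
    """Flag windows with delta_i > mu(delta) + k_sd * sd(delta) (strict)."""
    if k_sd <= 0:
        raise ValueError(f"k_sd must be positive, got {k_sd}")
    if delta.sd_delta <= 0:
        raise ValueError("sd(delta) is zero; cannot threshold a constant track")
    threshold = delta.mu_delta + k_sd * delta.sd_delta
    mask = {chrom: delta.deltas[chrom] > threshold for chrom in delta.grid.chroms}
    return FlaggedWindows(grid=delta.grid, mask=mask, k_sd=k_sd, threshold=threshold)


def compact_segments(flags: FlaggedWindows, delta: DeltaTrack) -> SegmentSet:
    """Merge maximal runs of consecutive flagged windows into segments.

    Each segment reports start (inclusive) and end (exclusive) in window
    units, size = end - start, and total delta summed over its windows.
    """
    if not flags.grid.same_grid(delta.grid):
        raise ValueError("flags and delta tracks use different grids")
    rows = []
    members: list[list[int]] = []
    for chrom in flags.grid.chroms:
        m = np.asarray(flags.mask[chrom], dtype=bool)
        if not m.any():
            continue
        # run boundaries of the boolean mask
        padded = np.concatenate([[False], m, [False]])
        edges = np.flatnonzero(padded[1:] != padded[:-1])
        for start, end in zip(edges[::2], edges[1::2]):
            total = float(delta.deltas[chrom][start:end].sum())
            rows.append((chrom, int(start), int(end), total, int(end - start)))
            members.append(list(range(start, end)))
    table = pd.DataFrame(rows, columns=["chrom", "start_mb", "end_mb", "total_delta", "size_mb"])
    order = [flags.grid.chroms.index(c) for c in table["chrom"]] if len(table) else []
    table = table.assign(_ord=order).sort_values(["_ord", "start_mb"], kind="stable")
    members = [members[i] for i in table.index]
    table = table.drop(columns="_ord").reset_index(drop=True)
    return SegmentSet(table=table, grid=flags.grid, k_sd=flags.k_sd, member_windows=members)


def genome_fraction(flags: FlaggedWindows) -> float:
    """Flagged-window count / total grid windows."""
    total = flags.grid.total_windows
    return flags.n_flagged / total if total else 0.0


def windows_report(
    track: WindowCountTrack, delta: DeltaTrack, flags: FlaggedWindows
) -> pd.DataFrame:
    """Per-window table: chrom, start_mb, A, z, delta, flagged."""
    z = zscore_track(track)
    rows = []
    for chrom in track.grid.chroms:
        for k in range(track.grid.n_windows[chrom]):
            rows.append(
                (
                    chrom,
                    k,
                    track.counts[chrom][k],
                    z[chrom][k],
                    delta.deltas[chrom][k],
                    bool(flags.mask[chrom][k]),
                )
            )
    return pd.DataFrame(rows, columns=["chrom", "start_mb", "A", "z", "delta", "flagged"])


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def window_classification_scores(
    flags: FlaggedWindows, truth_windows: set[tuple[str, int]]
) -> tuple[float, float]:
    """(precision, recall) of the flagged set against a ground-truth window set."""
    predicted = flags.window_set()
    tp = len(predicted & truth_windows)
    precision = tp / len(predicted) if predicted else 0.0
    recall = tp / len(truth_windows) if truth_windows else 0.0
    return precision, recall


def ashman_d(values: np.ndarray, random_state: int = 0) -> float:
    """Ashman's D for a two-component normal mixture fit of the values.

    D = |mu1 - mu2| / sqrt((s1^2 + s2^2) / 2); D > 2 indicates a clearly
    bimodal density (the two modes separate).
    """
    from sklearn.mixture import GaussianMixture

    x = np.asarray(values, dtype=float).reshape(-1, 1)
    gm = GaussianMixture(n_components=2, random_state=random_state, n_init=3).fit(x)
    m1, m2 = gm.means_.ravel()
    v1, v2 = gm.covariances_.ravel()
    return float(abs(m1 - m2) / np.sqrt((v1 + v2) / 2.0))


def is_bimodal(values: np.ndarray, min_d: float = 2.0, random_state: int = 0) -> bool:
    return ashman_d(values, random_state=random_state) > min_d
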