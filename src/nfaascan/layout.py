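"""Genome layout and scanning-window grid.

The scan operates on non-overlapping fixed-width windows tiling each
autosome.  Window ``k`` of a chromosome covers 1-based positions
``[k*W + 1, (k+1)*W]``; the final window is truncated at the chromosome
end but still counts as one window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_WINDOW_BP = 1_000_000


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names, lengths (bp) and the autosome subset."""

    lengths: dict[str, int]
    autosomes: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.lengths:
            raise ValueError("layout has no chromosomes")
        for name, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        if not self.autosomes:
            object.__setattr__(self, "autosomes", tuple(self.lengths))
        unknown = set(self.autosomes) - set(self.lengths)
        if unknown:
            raise ValueError(f"autosome names not in layout: {sorted(unknown)}")

    def is_autosome(self, chrom: str) -> bool:
        return chrom in set(self.autosomes)

    @property
    def total_bp(self) -> int:
        return sum(self.lengths.values())

    @classmethod
    def from_tsv(cls, path: str | Path, autosomes: list[str] | None = None) -> "GenomeLayout":
        """Read a two-column tab-separated ``name<TAB>length_bp`` table."""
        lengths: dict[str, int] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, length = line.split("\t")
            lengths[name] = int(length)
        return cls(lengths, tuple(autosomes) if autosomes else ())

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in self.lengths.items():
                fh.write(f"{name}\t{length}\n")


@dataclass(frozen=True)
class WindowGrid:
    """Non-overlapping window tiling of the autosomes of a layout."""

    layout: GenomeLayout
    width: int = DEFAULT_WINDOW_BP
    n_windows: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("window width must be positive")
        counts = {
            chrom: math.ceil(self.layout.lengths[chrom] / self.width)
            for chrom in self.layout.autosomes
        }
        object.__setattr__(self, "n_windows", counts)

    @property
    def chroms(self) -> tuple[str, ...]:
        return self.layout.autosomes

    @property
    def total_windows(self) -> int:
        return sum(self.n_windows.values())

    def window_index(self, chrom: str, pos: int) -> int:
        """Window holding 1-based position ``pos``: ``floor((pos-1)/W)``."""
        if chrom not in self.n_windows:
            raise KeyError(f"{chrom!r} is not an autosome of this grid")
        if not 1 <= pos <= self.layout.lengths[chrom]:
            raise ValueError(f"position {chrom}:{pos} outside chromosome bounds")
        return (pos - 1) // self.width

    def windows_df(self) -> pd.DataFrame:
        """One row per window: chrom, win, start_bp (1-based), end_bp (inclusive)."""
        rows = []
        for chrom in self.chroms:
            n = self.n_windows[chrom]
            length = self.layout.lengths[chrom]
            for k in range(n):
                rows.append((chrom, k, k * self.width + 1, min((k + 1) * self.width, length)))
        return pd.DataFrame(rows, columns=["chrom", "win", "start_bp", "end_bp"])

    def same_grid(self, other: "WindowGrid") -> bool:
        return (
            self.width == other.width
            and self.chroms == other.chroms
            and all(self.n_windows[c] == other.n_windows[c] for c in self.chroms)
        )

    def flatten(self, per_chrom: dict[str, np.ndarray]) -> np.ndarray:
        """Concatenate per-chromosome arrays in grid chromosome order."""
        return np.concatenate([np.asarray(per_chrom[c], dtype=float) for c in self.chroms])
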