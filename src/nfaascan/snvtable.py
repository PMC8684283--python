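"""Paired comparisons of per-breed SNV counts between two assemblies.

A packaged table gives, for each breed, the number of filtered SNVs
called against each of two reference assemblies (a taurine-background
one, ARS_UCD1.2, and an indicine-background one, UOA_Brahman_1).  The
comparisons are paired per breed: per-breed differences in a stated
direction, their mean (reported rounded half away from zero), and a
two-sided paired t-test with df = n - 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
from scipy import stats

ASSEMBLY_COLUMNS = {"ars_ucd12": "ars_ucd12_snvs", "uoa_brahman1": "uoa_brahman1_snvs"}
SUBSPECIES = ("taurus", "indicus")


@dataclass
class SnvCountTable:
    """Rows of (breed, subspecies, snv count per assembly)."""

    table: pd.DataFrame

    def __post_init__(self):
        required = {"breed", "subspecies", *ASSEMBLY_COLUMNS.values()}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if self.table["breed"].duplicated().any():
            raise ValueError("breed names must be unique")
        for col in ASSEMBLY_COLUMNS.values():
            if (self.table[col] <= 0).any():
                raise ValueError(f"{col}: counts must be positive")

    @classmethod
    def packaged(cls) -> "SnvCountTable":
        """The SNV-count table shipped with the package."""
        with resources.as_file(
            resources.files("nfaascan.data").joinpath("snv_counts.tsv")
        ) as path:
            return cls.from_tsv(path)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SnvCountTable":
        return cls(pd.read_csv(path, sep="\t"))

    def breeds_of(self, subspecies: str) -> list[str]:
        if subspecies not in SUBSPECIES:
            raise ValueError(f"unknown subspecies label {subspecies!r}")
        return list(self.table.loc[self.table["subspecies"] == subspecies, "breed"])

    def reassign_breed(self, breed: str, new_label: str) -> "SnvCountTable":
        """A new table with one breed's subspecies label changed."""
        if new_label not in SUBSPECIES:
            raise ValueError(f"unknown subspecies label {new_label!r}")
        if breed not in set(self.table["breed"]):
            raise ValueError(f"unknown breed {breed!r}")
        new = self.table.copy()
        new.loc[new["breed"] == breed, "subspecies"] = new_label
        return SnvCountTable(new)


def paired_differences(
    table: SnvCountTable, breeds: list[str], direction: str = "uoa_minus_ars"
) -> list[int]:
    """Per-breed SNV-count difference in the stated direction, order preserved.

    ``direction`` is ``"uoa_minus_ars"`` or ``"ars_minus_uoa"``.
    """
    if direction not in ("uoa_minus_ars", "ars_minus_uoa"):
        raise ValueError(f"unknown direction {direction!r}")
    if not breeds:
        raise ValueError("empty breed group")
    indexed = table.table.set_index("breed")
    diffs = []
    for breed in breeds:
        if breed not in indexed.index:
            raise ValueError(f"unknown breed {breed!r}")
        row = indexed.loc[breed]
        d = int(row["uoa_brahman1_snvs"]) - int(row["ars_ucd12_snvs"])
        diffs.append(d if direction == "uoa_minus_ars" else -d)
    return diffs


def round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero (not banker's)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def mean_paired_difference(differences: list[int]) -> tuple[int, float]:
    """(rounded mean, unrounded mean) of per-breed differences."""
    if not differences:
        raise ValueError("no differences")
    mean = sum(differences) / len(differences)
    return round_half_away(mean), mean


def paired_t_test(differences: list[int]) -> tuple[float, int, float]:
    """Two-sided one-sample t-test of the differences against zero.

    t = mean(d) / (sd(d)/sqrt(n)) with sample sd; returns (t, df, p).
    """
    n = len(differences)
    if n < 2:
        raise ValueError("need at least 2 differences")
    if len(set(differences)) == 1:
        raise ValueError("zero variance in differences")
    res = stats.ttest_1samp(differences, popmean=0.0)
    return float(res.statistic), n - 1, float(res.pvalue)
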