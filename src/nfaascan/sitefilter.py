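"""Per-breed allele frequencies, retention filters, and NFAA selection.

The retention rules mirror the scan's preconditions: only biallelic,
autosomal sites where every sample has a diploid genotype call (100%
call rate) enter the frequency table.  A nearly fixed alternative
allele (NFAA) site is one whose alternative-allele frequency is >= the
threshold (default 0.95, inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .layout import GenomeLayout
from .vcfio import FreqRecord, SiteRecord

DEFAULT_NFAA_THRESHOLD = 0.95


@dataclass
class AlleleFrequencySet:
    """Retained (biallelic, autosomal, fully called) sites for one breed pool.

    ``table`` columns: chrom, pos, n_chr, alt_freq.  ``drop_counts``
    records how many input sites each filter removed.
    """

    breed: str
    assembly: str
    table: pd.DataFrame
    drop_counts: dict[str, int] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_freq_records(self) -> list[FreqRecord]:
        return [
            FreqRecord(r.chrom, int(r.pos), 2, int(r.n_chr), (1.0 - r.alt_freq, r.alt_freq))
            for r in self.table.itertuples()
        ]


@dataclass
class NfaaSiteSet:
    """NFAA sites for one breed pool: alt frequency >= threshold, sorted."""

    breed: str
    assembly: str
    table: pd.DataFrame  # columns: chrom, pos, alt_freq
    threshold: float

    def __len__(self) -> int:
        return len(self.table)


def compute_alt_frequencies(
    sites: Iterable[SiteRecord],
    layout: GenomeLayout,
    breed: str = "",
    assembly: str = "",
) -> AlleleFrequencySet:
    """Alt-allele frequency per retained site: sum(dosage) / (2 * n_samples).

    Drops (with per-reason counts): multi-allelic sites, sites off the
    autosomes, and sites with any missing/non-diploid genotype.
    """
    rows = []
    drops = {"multiallelic": 0, "non_autosome": 0, "call_rate": 0}
    n_samples = None
    for site in sites:
        if n_samples is None:
            n_samples = len(site.dosages)
            if n_samples == 0:
                raise ValueError("VCF has zero samples")
        if site.is_multiallelic:
            drops["multiallelic"] += 1
            continue
        if not layout.is_autosome(site.chrom):
            drops["non_autosome"] += 1
            continue
        if any(d is None for d in site.dosages):
            drops["call_rate"] += 1
            continue
        n_chr = 2 * len(site.dosages)
        rows.append((site.chrom, site.pos, n_chr, sum(site.dosages) / n_chr))
    table = pd.DataFrame(rows, columns=["chrom", "pos", "n_chr", "alt_freq"])
    return AlleleFrequencySet(
        breed=breed,
        assembly=assembly,
        table=table,
        drop_counts=drops,
        provenance={"call_rate": 1.0, "autosomes": list(layout.autosomes)},
    )


def frequencies_from_table(
    records: Iterable[FreqRecord],
    layout: GenomeLayout,
    breed: str = "",
    assembly: str = "",
) -> AlleleFrequencySet:
    """Build an AlleleFrequencySet from a pre-made freq2 table.

    Applies the same biallelic/autosome filters; call rate is assumed
    already enforced upstream when the table was made (n_chr is taken
    at face value).
    """
    rows = []
    drops = {"multiallelic": 0, "non_autosome": 0}
    for rec in records:
        if rec.n_alleles != 2:
            drops["multiallelic"] += 1
            continue
        if not layout.is_autosome(rec.chrom):
            drops["non_autosome"] += 1
            continue
        rows.append((rec.chrom, rec.pos, rec.n_chr, rec.freqs[1]))
    table = pd.DataFrame(rows, columns=["chrom", "pos", "n_chr", "alt_freq"])
    return AlleleFrequencySet(breed=breed, assembly=assembly, table=table, drop_counts=drops)


def select_nfaa(
    freqs: AlleleFrequencySet, threshold: float = DEFAULT_NFAA_THRESHOLD
) -> NfaaSiteSet:
    """Sites with alternative-allele frequency >= threshold (inclusive)."""
    if not 0 < threshold <= 1:
        raise ValueError(f"NFAA threshold must be in (0, 1], got {threshold}")
    kept = freqs.table[freqs.table["alt_freq"] >= threshold]
    kept = kept.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return NfaaSiteSet(
        breed=freqs.breed,
        assembly=freqs.assembly,
        table=kept[["chrom", "pos", "alt_freq"]],
        threshold=threshold,
    )
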