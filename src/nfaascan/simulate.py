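"""Synthetic multi-breed allele-frequency datasets with ground truth.

The generative model emulates resequencing data from two diverged
subspecies (abstract labels A and B) mapped against a mosaic-ancestry
reference: the reference is subspecies-B everywhere except a set of
planted segments of subspecies-A ancestry (the analogue of taurine
introgression inside an indicine assembly).

Two site classes are placed by homogeneous Poisson processes:

* divergence sites (fixed inter-subspecies differences): the owning
  subspecies carries the non-reference allele at frequency 1 - epsilon
  wherever its ancestry differs from the reference's local ancestry, so
  a pure breed shows alt frequency ~1 - epsilon in ancestry-discordant
  regions and ~epsilon in concordant ones; admixed breeds get the
  q-weighted mixture.
* shared polymorphic sites: one Beta(0.5, 0.5) population frequency per
  site, common to all breeds (a folded, U-shaped frequency spectrum that
  yields a realistic low-but-nonzero NFAA background).

Sites are unlinked; individual dosages are Binomial(2, freq) draws.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import betabinom, binom

from .layout import GenomeLayout, WindowGrid
from .vcfio import FreqRecord, SiteRecord, write_bed, write_freq2_table, write_vcf

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class BreedSpec:
    """One breed pool: nominal subspecies label, A-ancestry fraction q, size."""

    name: str
    subspecies: str  # 'A' or 'B'
    q: float  # fraction of subspecies-A ancestry
    n_individuals: int


@dataclass
class SimulationConfig:
    chrom_lengths: dict[str, int]
    planted_segments: list[tuple[str, int, int]]  # 0-based half-open bp
    breeds: list[BreedSpec]
    divergence_density: float  # fixed-difference sites per Mb
    polymorphism_density: float  # shared segregating sites per Mb
    epsilon: float = 0.02  # residual minor-allele frequency at divergence sites
    seed: int = 0

    def validate(self) -> None:
        if self.divergence_density <= 0 or self.polymorphism_density <= 0:
            raise ValueError("site densities must be positive")
        if not 0 <= self.epsilon < 0.05:
            raise ValueError(f"epsilon must be in [0, 0.05), got {self.epsilon}")
        for b in self.breeds:
            if b.n_individuals < 1:
                raise ValueError(f"breed {b.name!r} has n_individuals < 1")
            if b.subspecies not in ("A", "B"):
                raise ValueError(f"breed {b.name!r}: subspecies must be 'A' or 'B'")
            if not 0 <= b.q <= 1:
                raise ValueError(f"breed {b.name!r}: q must be in [0, 1]")
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.planted_segments:
            if chrom not in self.chrom_lengths:
                raise ValueError(f"planted segment on unknown chromosome {chrom!r}")
            if not 0 <= start < end <= self.chrom_lengths[chrom]:
                raise ValueError(
                    f"planted segment ({chrom}, {start}, {end}) outside chromosome bounds"
                )
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, segs in by_chrom.items():
            segs.sort()
            for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"planted segments ({chrom}, {s1}, {e1}) and "
                        f"({chrom}, {s2}, {e2}) overlap"
                    )

    def layout(self) -> GenomeLayout:
        return GenomeLayout(dict(self.chrom_lengths))

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["breeds"] = [list(asdict(b).values()) for b in self.breeds]
        data["planted_segments"] = [list(s) for s in self.planted_segments]
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text())
        data["breeds"] = [BreedSpec(n, s, float(q), int(ni)) for n, s, q, ni in data["breeds"]]
        data["planted_segments"] = [(c, int(s), int(e)) for c, s, e in data["planted_segments"]]
        return cls(**data)


@dataclass
class AncestryMap:
    """Per-base-resolvable local ancestry of the reference (B except plants)."""

    chrom_lengths: dict[str, int]
    planted: dict[str, list[tuple[int, int]]]  # sorted, 0-based half-open

    def ancestry_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Boolean array: True where the reference ancestry is A (planted).

        ``positions`` are 1-based.
        """
        zero_based = np.asarray(positions) - 1
        out = np.zeros(len(zero_based), dtype=bool)
        for start, end in self.planted.get(chrom, []):
            out |= (zero_based >= start) & (zero_based < end)
        return out

    @property
    def planted_fraction(self) -> float:
        total = sum(self.chrom_lengths.values())
        planted = sum(e - s for segs in self.planted.values() for s, e in segs)
        return planted / total


@dataclass
class TruthSet:
    """Ground truth: planted segments plus per-site class and ancestry labels."""

    planted_segments: list[tuple[str, int, int]]
    sites: pd.DataFrame  # chrom, pos, category, ref_ancestry

    def planted_windows(self, grid: WindowGrid) -> set[tuple[str, int]]:
        """Windows overlapping any planted segment."""
        out: set[tuple[str, int]] = set()
        for chrom, start, end in self.planted_segments:
            first = start // grid.width
            last = (end - 1) // grid.width
            for k in range(first, last + 1):
                out.add((chrom, k))
        return out


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    sites: pd.DataFrame  # chrom, pos, ref, alt, category, ref_ancestry
    pop_freqs: dict[str, np.ndarray]  # breed -> population alt frequency per site
    genotypes: dict[str, np.ndarray]  # breed -> (n_individuals, n_sites) dosages
    allele_counts: dict[str, np.ndarray]  # breed -> pooled alt-allele count per site
    n_chr: dict[str, int]  # breed -> 2 * n_individuals
    truth: TruthSet

    def sample_alt_freq(self, breed: str) -> np.ndarray:
        """Alt frequencies observed in the sampled breed pool."""
        return self.allele_counts[breed] / self.n_chr[breed]

    def breed_freq_records(self, breed: str) -> list[FreqRecord]:
        freqs = self.sample_alt_freq(breed)
        n_chr = self.n_chr[breed]
        return [
            FreqRecord(r.chrom, int(r.pos), 2, n_chr, (1.0 - f, f))
            for r, f in zip(self.sites.itertuples(), freqs)
        ]

    def breed_frequency_table(self, breed: str) -> pd.DataFrame:
        """Sampled-frequency table (chrom, pos, n_chr, alt_freq) for one breed."""
        return pd.DataFrame(
            {
                "chrom": self.sites["chrom"].astype(str),
                "pos": self.sites["pos"],
                "n_chr": self.n_chr[breed],
                "alt_freq": self.sample_alt_freq(breed),
            }
        )

    def breed_site_records(self, breed: str) -> list[SiteRecord]:
        g = self.genotypes[breed]
        return [
            SiteRecord(r.chrom, int(r.pos), r.ref, (r.alt,), tuple(int(d) for d in g[:, i]))
            for i, r in enumerate(self.sites.itertuples())
        ]


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------


def build_mosaic(config: SimulationConfig) -> AncestryMap:
    """Reference local-ancestry map: B everywhere except planted A segments."""
    config.validate()
    planted: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in config.planted_segments:
        planted.setdefault(chrom, []).append((start, end))
    for segs in planted.values():
        segs.sort()
    return AncestryMap(chrom_lengths=dict(config.chrom_lengths), planted=planted)


def simulate_site_frequencies(
    config: SimulationConfig, ancestry_map: AncestryMap, rng: np.random.Generator
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Place sites and compute per-breed population alt frequencies.

    Returns (sites table, breed -> alt-frequency array).  Divergence and
    polymorphic sites are placed by independent Poisson processes at the
    configured per-Mb densities; coinciding positions are dropped.
    """
    chrom_col, pos_col, cat_col, anc_col = [], [], [], []
    for chrom, length in config.chrom_lengths.items():
        mb = length / 1e6
        n_div = rng.poisson(config.divergence_density * mb)
        n_poly = rng.poisson(config.polymorphism_density * mb)
        pos = np.concatenate(
            [rng.integers(1, length + 1, size=n_div), rng.integers(1, length + 1, size=n_poly)]
        )
        codes = np.concatenate(
            [np.zeros(n_div, dtype=np.int8), np.ones(n_poly, dtype=np.int8)]
        )
        # drop coinciding positions, keeping the first (divergence-class) hit
        uniq_pos, first_idx = np.unique(pos, return_index=True)
        chrom_col.append(np.full(len(uniq_pos), chrom, dtype=object))
        pos_col.append(uniq_pos)
        cat_col.append(codes[first_idx])
        anc_col.append(ancestry_map.ancestry_at(chrom, uniq_pos))
    sites = pd.DataFrame(
        {
            "chrom": np.concatenate(chrom_col),
            "pos": np.concatenate(pos_col),
            "category": pd.Categorical.from_codes(
                np.concatenate(cat_col), categories=["divergence", "polymorphic"]
            ),
            "ref_ancestry": pd.Categorical.from_codes(
                np.where(np.concatenate(anc_col), 0, 1), categories=["A", "B"]
            ),
        }
    )

    n_sites = len(sites)
    base_idx = rng.integers(0, 4, size=n_sites)
    alt_offset = rng.integers(1, 4, size=n_sites)
    sites["ref"] = _BASES[base_idx]
    sites["alt"] = _BASES[(base_idx + alt_offset) % 4]

    is_div = (sites["category"] == "divergence").to_numpy()
    ref_is_a = (sites["ref_ancestry"] == "A").to_numpy()
    eps = config.epsilon
    # pure-subspecies alt frequencies at divergence sites
    f_pure_a = np.where(ref_is_a, eps, 1.0 - eps)
    f_pure_b = np.where(ref_is_a, 1.0 - eps, eps)
    shared_poly = rng.beta(0.5, 0.5, size=n_sites)

    freqs: dict[str, np.ndarray] = {}
    for breed in config.breeds:
        f_div = breed.q * f_pure_a + (1.0 - breed.q) * f_pure_b
        freqs[breed.name] = np.clip(np.where(is_div, f_div, shared_poly), 0.0, 1.0)
    return sites, freqs


def sample_genotypes(freqs: np.ndarray, n_individuals: int, rng: np.random.Generator) -> np.ndarray:
    """Diploid dosages: Binomial(2, freq) per individual and site, no missingness."""
    freqs = np.asarray(freqs, dtype=float)
    if ((freqs < 0) | (freqs > 1)).any():
        raise ValueError("frequencies must lie in [0, 1]")
    # Binomial(2, f) as two Bernoulli layers: much faster than rng.binomial
    # when f varies per site, and distributionally identical.
    shape = (n_individuals, len(freqs))
    f32 = freqs.astype(np.float32)
    dosage = (rng.random(shape, dtype=np.float32) < f32).view(np.int8) + (
        rng.random(shape, dtype=np.float32) < f32
    ).view(np.int8)
    return dosage


def sample_allele_counts(
    freqs: np.ndarray, n_individuals: int, rng: np.random.Generator
) -> np.ndarray:
    """Pooled alt-allele counts per site: Binomial(2 * n_individuals, freq).

    Marginally identical to summing :func:`sample_genotypes` dosages, but
    without materializing individuals.
    """
    freqs = np.asarray(freqs, dtype=float)
    if ((freqs < 0) | (freqs > 1)).any():
        raise ValueError("frequencies must lie in [0, 1]")
    return rng.binomial(2 * n_individuals, freqs)


def simulate_dataset(config: SimulationConfig, with_genotypes: bool = True) -> SimulatedDataset:
    """Run the full generator: mosaic, site frequencies, genotypes, truth."""
    ancestry = build_mosaic(config)
    rng = np.random.default_rng(config.seed)
    sites, pop_freqs = simulate_site_frequencies(config, ancestry, rng)
    genotypes: dict[str, np.ndarray] = {}
    counts: dict[str, np.ndarray] = {}
    n_chr = {b.name: 2 * b.n_individuals for b in config.breeds}
    for breed in config.breeds:
        if with_genotypes:
            g = sample_genotypes(pop_freqs[breed.name], breed.n_individuals, rng)
            genotypes[breed.name] = g
            counts[breed.name] = g.sum(axis=0, dtype=np.int64)
        else:
            counts[breed.name] = sample_allele_counts(
                pop_freqs[breed.name], breed.n_individuals, rng
            )
    truth = TruthSet(
        planted_segments=sorted(config.planted_segments),
        sites=sites[["chrom", "pos", "category", "ref_ancestry"]].copy(),
    )
    return SimulatedDataset(config, sites, pop_freqs, genotypes, counts, n_chr, truth)


def emit_dataset(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Write per-breed VCF + freq2 tables, chromosome table, truth BED, config echo.

    Byte-identical outputs for identical (config, seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = simulate_dataset(config, with_genotypes=True)
    paths: dict[str, Path] = {}

    for breed in config.breeds:
        sample_names = [f"{breed.name}_{i + 1}" for i in range(breed.n_individuals)]
        vcf_path = outdir / f"{breed.name}.vcf"
        write_vcf(vcf_path, sample_names, ds.breed_site_records(breed.name), config.chrom_lengths)
        frq_path = outdir / f"{breed.name}.frq"
        write_freq2_table(ds.breed_freq_records(breed.name), frq_path)
        paths[f"{breed.name}.vcf"] = vcf_path
        paths[f"{breed.name}.frq"] = frq_path

    layout_path = outdir / "chrom_lengths.tsv"
    config.layout().to_tsv(layout_path)
    paths["chrom_lengths.tsv"] = layout_path

    bed_path = outdir / "truth_segments.bed"
    write_bed(sorted(config.planted_segments), bed_path)
    paths["truth_segments.bed"] = bed_path

    cfg_path = outdir / "config.yaml"
    config.to_yaml(cfg_path)
    paths["config.yaml"] = cfg_path
    return paths


def dataset_checksums(paths: dict[str, Path]) -> dict[str, str]:
    return {
        name: hashlib.sha256(path.read_bytes()).hexdigest() for name, path in sorted(paths.items())
    }


# ---------------------------------------------------------------------------
# Cattle-like preset
# ---------------------------------------------------------------------------

#: Group-mean NFAA densities (sites/Mb) the preset is calibrated to: the
#: values observed for a taurine group against an indicine-background
#: reference (discordant) and inside taurine-introgressed regions
#: (concordant).
TARGET_DISCORDANT_NFAA_PER_MB = 1162.0
TARGET_CONCORDANT_NFAA_PER_MB = 95.0

_FULL_CHROMS = {f"chr{i}": 25_000_000 for i in range(1, 11)}
_FULL_PLANTED_MB = [
    ("chr1", 3, 5),
    ("chr1", 10, 11),
    ("chr2", 7, 12),
    ("chr3", 20, 21),
    ("chr4", 0, 8),
    ("chr5", 14, 17),
    ("chr6", 22, 25),
    ("chr7", 5, 6),
    ("chr7", 12, 16),
    ("chr8", 18, 20),
    ("chr9", 1, 4),
    ("chr10", 9, 10),
]  # 34 Mb of 250 Mb ~ 0.137 planted

_SMALL_CHROMS = {"chr1": 25_000_000, "chr2": 25_000_000}
_SMALL_PLANTED_MB = [
    ("chr1", 3, 5),
    ("chr1", 10, 11),
    ("chr2", 7, 11),
]  # 7 Mb of 50 Mb

_A_BREED_SIZES = [9, 8, 9, 7, 5, 16]
_B_BREED_SIZES = [10, 7, 9, 5, 6, 7, 6, 5]
_ADMIXED_Q = 0.8
_ADMIXED_N = 3


def nfaa_probability_fixed(n_individuals: int, pop_freq: float, threshold: float = 0.95) -> float:
    """P(sampled alt frequency >= threshold) for a fixed population frequency."""
    n_chr = 2 * n_individuals
    c = int(np.ceil(threshold * n_chr - 1e-9))
    return float(binom.sf(c - 1, n_chr, pop_freq))


def nfaa_probability_beta(
    n_individuals: int, a: float = 0.5, b: float = 0.5, threshold: float = 0.95
) -> float:
    """P(sampled alt frequency >= threshold) for Beta(a, b) population frequencies."""
    n_chr = 2 * n_individuals
    c = int(np.ceil(threshold * n_chr - 1e-9))
    return float(betabinom.sf(c - 1, n_chr, a, b))


def calibrate_densities(
    scan_group_sizes: list[int],
    epsilon: float = 0.02,
    target_discordant: float = TARGET_DISCORDANT_NFAA_PER_MB,
    target_concordant: float = TARGET_CONCORDANT_NFAA_PER_MB,
) -> tuple[float, float]:
    """Solve (divergence_density, polymorphism_density) per Mb in closed form.

    The expected group-mean NFAA count per Mb is
    ``d * mean_b P_div(n_b) + p * mean_b P_poly(n_b)`` in discordant
    windows and ``p * mean_b P_poly(n_b)`` in concordant windows, where
    the probabilities are exact binomial / beta-binomial tails for each
    breed's chromosome count.
    """
    p_div = float(np.mean([nfaa_probability_fixed(n, 1.0 - epsilon) for n in scan_group_sizes]))
    p_poly = float(np.mean([nfaa_probability_beta(n) for n in scan_group_sizes]))
    polymorphism_density = target_concordant / p_poly
    divergence_density = (target_discordant - target_concordant) / p_div
    return divergence_density, polymorphism_density


def cattle_like_config(
    seed: int = 0, small: bool = False, scan_group_only: bool = False
) -> SimulationConfig:
    """The calibrated default preset.

    Six pure subspecies-A breeds (the scan group), eight pure
    subspecies-B breeds and one admixed breed (q = 0.8, n = 3), with
    per-breed diploid sample sizes of 3-16.  Site densities are solved so
    the expected A-group NFAA means match the calibration targets
    (~1162/Mb discordant, ~95/Mb concordant).  ``small`` selects a 50-Mb
    two-chromosome genome instead of the 250-Mb ten-chromosome one; the
    planted fraction is ~0.14 in both.
    """
    breeds = [BreedSpec(f"A{i + 1}", "A", 1.0, n) for i, n in enumerate(_A_BREED_SIZES)]
    if not scan_group_only:
        breeds += [BreedSpec(f"B{i + 1}", "B", 0.0, n) for i, n in enumerate(_B_BREED_SIZES)]
        breeds.append(BreedSpec("ADMIX1", "B", _ADMIXED_Q, _ADMIXED_N))
    epsilon = 0.02
    d, p = calibrate_densities(_A_BREED_SIZES, epsilon=epsilon)
    chroms = _SMALL_CHROMS if small else _FULL_CHROMS
    planted_mb = _SMALL_PLANTED_MB if small else _FULL_PLANTED_MB
    planted = [(c, s * 1_000_000, e * 1_000_000) for c, s, e in planted_mb]
    return SimulationConfig(
        chrom_lengths=dict(chroms),
        planted_segments=planted,
        breeds=breeds,
        divergence_density=d,
        polymorphism_density=p,
        epsilon=epsilon,
        seed=seed,
    )
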