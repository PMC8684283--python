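# Methods

## The depletion scan

The scan assumes that aligning samples against a lineage-divergent reference
produces, at every fixed inter-lineage difference, a variant call that is
(nearly) homozygous for the alternative allele in the whole pool.  Counting
such nearly-fixed-alternative-allele (NFAA) sites per window turns local
reference ancestry into a step function: windows where the reference locally
shares the samples' ancestry lose the fixed-difference signal and retain only
a polymorphism background.

Definitions, in order of computation:

1. **Site retention.** Only biallelic, autosomal sites where every sample has
   a diploid genotype call (100% call rate) are kept.  The autosome set is an
   explicit input (a chromosome-length table); sites on contigs outside it
   are dropped and counted.  GATK-style hard filters are available as a site
   predicate: a site fails iff any of `QD < 2.0`, `QUAL < 30.0`, `MQ < 40.0`,
   `SOR > 3.0`, `FS > 60.0`, `MQRankSum < −12.5`, `ReadPosRankSum < −8.0`
   holds *strictly*; values exactly at a threshold pass, and metrics absent
   from a record are not evaluated (mirroring GATK VariantFiltration).
2. **NFAA selection.** Alternative-allele frequency = Σ dosage / (2·n);
   a site is NFAA when the frequency is ≥ the threshold (default 0.95,
   inclusive).
3. **Window counts.** Non-overlapping windows of width W (default 1 Mb) tile
   each autosome; window k covers 1-based positions [kW+1, (k+1)W], the last
   window truncated at the chromosome end.  A_i is the NFAA count of window
   i; for a breed group, A_i is the arithmetic mean of the per-breed counts.
   Terminal partial windows keep raw counts — the statistic sums counts, not
   densities — and a density option exists but is off by default.
4. **Delta.** Δ_i = μ(A) − A_i with μ(A) the mean over *all* grid windows
   (zero-count and truncated windows included).  Consequently ΣΔ = 0 and
   μ(Δ) = 0 up to rounding; both are asserted in tests.  The sign convention
   makes NFAA-depleted windows large-positive.
5. **Flagging.** T = {i : Δ_i > μ(Δ) + k·sd(Δ)}, strict inequality, default
   k = 1.5.  All standard deviations are sample sds (n−1); the choice is
   recorded in provenance output.  Under an i.i.d. normal null the rule flags
   the upper one-sided tail, ≈ 6.7% of windows, which the test suite checks
   by Monte Carlo.  On real two-population mixtures the Δ density is
   bimodal; a two-component Gaussian-mixture fit with Ashman's
   D = |μ₁−μ₂| / √((σ₁²+σ₂²)/2) > 2 is used as the bimodality diagnostic.
6. **Segments.** Maximal runs of consecutive flagged windows are merged;
   each segment reports start (inclusive) and end (exclusive) in window
   units, size = end − start, and total Δ summed over member windows.  BED
   export converts to bp, 0-based half-open.

Whether to average NFAA counts across breeds before flagging or to flag each
breed separately is genuinely open; the group mean is the default because it
suppresses breed-specific sampling noise, and per-breed tracks remain
available.

## Reference-haplotype validation

The assembly is represented as a pseudo-individual with dosage 0 (homozygous
reference) at every variant site.  Per-breed genotype matrices are merged on
(chrom, pos); sites whose allele union exceeds two alleles are removed
(plink-style biallelic restriction), and ref/alt swaps between inputs are
reconciled by flipping dosages (2 − d).  PCA uses mean-centered,
variance-standardized dosages (zero-variance sites dropped), computed exactly
via the sample-sample Gram matrix — with tens of samples and up to ~10⁵
sites this is orders of magnitude faster than a full SVD and numerically
identical up to component sign.  Variance standardization was chosen to match
the common genotype-PCA default; LD pruning is not applied.  Cluster
membership on PC1 is decided by nearest pure-subspecies centroid.

Admixture model fitting is delegated to the external ADMIXTURE tool: the
package only exports transposed text genotypes (rows = sites, columns =
samples) and ingests/validates K-column Q tables (rows must sum to 1 ± 1e-4).

## Gene annotation

A gene is assigned to a segment when at least one of its transcripts lies
entirely within the segment (`contained`, the default — the literal reading
of "transcripts located within the window") or intersects it (`overlap`);
both modes are exposed because the phrasing is ambiguous, and the mode is
recorded in the report.  Gene symbols are matched case-insensitively with no
alias resolution.  The expected-by-chance gene count in flagged regions is
total genes × flagged genome fraction, rounded half away from zero.

## Paired SNV-count comparisons

The packaged table lists, per breed, the filtered SNV count against each of
two assemblies.  Comparisons are paired per breed: differences in a stated
direction, their mean (reported rounded half away from zero — required to
reproduce half-integer means such as 30,092,547/6 = 5,015,424.5 → 5,015,425;
banker's rounding would differ), and a two-sided one-sample t-test of the
differences with df = n − 1.

## The synthetic-data generator

The generator emulates per-breed per-site alternative-allele frequencies
arising from two diverged subspecies backgrounds (abstract labels A and B)
mapped against a mosaic reference: ancestry B everywhere except planted
segments of ancestry A.  What it models, and what it does not:

- **Divergence sites** (fixed inter-subspecies differences) are placed by a
  homogeneous Poisson process per chromosome at `divergence_density` per Mb.
  The reference base equals the allele of its local ancestry, so a pure
  breed's alternative-allele frequency is 1 − ε where its subspecies differs
  from the local reference ancestry and ε where it matches; an admixed breed
  with A-fraction q gets the q-weighted mixture.  ε defaults to 0.02 so that
  discordant sites pass the ≥ 0.95 NFAA filter with high probability at
  realistic pool sizes while still allowing sampling noise ("nearly fixed");
  ε must stay below 0.05 for the signal to exist at all.
- **Polymorphic sites** are placed at `polymorphism_density` per Mb with one
  Beta(0.5, 0.5) population frequency per site shared across breeds — a
  U-shaped folded frequency spectrum that produces a realistic
  low-but-nonzero NFAA background and no population structure of its own.
- **Genotypes** are Binomial(2, f) dosages per individual with no
  missingness (matching the 100% call-rate filter downstream); for scan-only
  uses, pooled allele counts are drawn directly as Binomial(2n, f), which is
  marginally identical and much cheaper.
- **Not modeled:** linkage disequilibrium (the scan statistic uses only
  marginal frequencies), recombination maps, read-level error, alignment
  artifacts, or demographic history.  Passing recovery tests therefore show
  that the statistic recovers ancestry-discordant windows under its own
  assumptions — not that those assumptions hold in any particular real
  dataset, where LD, assembly gaps and uneven divergence will blur segment
  boundaries.

### Cattle-like preset and calibration

The default preset mimics the data regime of a two-subspecies cattle
analysis: six pure-A breeds (the scan group; diploid sizes 9, 8, 9, 7, 5,
16), eight pure-B breeds (10, 7, 9, 5, 6, 7, 6, 5), one admixed breed
(q = 0.8, n = 3), a 250-Mb genome of ten 25-Mb chromosomes (a deliberate
~10× scale-down of a 2.5-Gb genome to keep simulation tractable), and twelve
planted segments of 1–8 Mb totalling 34 Mb (13.6% of the genome).  A 50-Mb
variant (`small=True`) with 7 Mb planted serves the genotype-level
validation runs.

Site densities are not hand-tuned: they are solved in closed form so that the
*expected* A-group NFAA means equal the calibration targets of 1162/Mb in
discordant windows and 95/Mb in concordant ones.  For a breed of n
individuals the NFAA probability of a divergence site is the exact binomial
tail P(Binom(2n, 1−ε) ≥ ⌈0.95·2n⌉) and that of a polymorphic site is the
beta-binomial tail P(BetaBinom(2n, ½, ½) ≥ ⌈0.95·2n⌉); averaging these over
the scan-group sizes and inverting the two linear equations gives
divergence_density ≈ 1407/Mb and polymorphism_density ≈ 648/Mb.  Simulated
group means land within ~1 site/Mb of the targets.

## Numerical choices and edge cases

- Frequencies in the freq2-dialect tables are serialized with the shortest
  exact decimal representation, so write∘read is the identity on arbitrary
  k/(2n) frequencies; rows whose frequencies do not sum to 1 within 1e-6 are
  rejected with the line number.
- Coordinates are 1-based inclusive internally (VCF/GFF convention); BED
  output is 0-based half-open.  Segment bp intervals are half-open in window
  units: position p is inside [start, end) iff start·W < p ≤ end·W.
- Constant tracks (zero sd) are errors for z-scoring and flagging rather
  than silently producing NaN; empty flag sets compact to empty segment
  sets; an empty NFAA set yields an all-zero track.
- A PCA request for more components than samples−1 truncates with a warning;
  sites with zero variance are dropped before standardization.
- Simulation determinism: one `numpy` Generator seeded from the config drives
  site placement, frequencies and genotypes in a fixed order, so identical
  config + seed reproduce byte-identical emitted files.

## Problem sizes used in the checks

The automated checks run the recovery analysis on 20 seeds of the 250-Mb
scan-group preset (~0.5 M sites each), the PCA placement on 20 seeds of the
50-Mb full-breed preset (~0.1 M sites, 113 samples, PCA thinned to ≤ 30,000
sites by deterministic striding), the null calibration on 10,000 windows,
and the scan oracle comparisons on 20 small two-chromosome datasets.  These
sizes were chosen so the full suite completes in a few minutes on one core
while keeping Monte-Carlo error well inside the asserted tolerances.

## Known limitations

- Window-resolution output: sub-window introgression boundaries cannot be
  localized, and planted segments in the generator are Mb-aligned, which
  makes recovery scoring exact rather than boundary-blurred.
- The scan requires the scanned group to be ancestry-discordant with the
  *bulk* of the reference; if discordant and concordant fractions approach
  50/50 the genome-wide mean no longer separates the modes cleanly.
- The threshold k = 1.5 is a fixed convention chosen for a bimodal Δ
  density; it is not a calibrated false-discovery control, and on unimodal
  data it simply flags the ~6.7% upper tail.
- Symbol-based gene cross-referencing resolves no aliases or orthologs.
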