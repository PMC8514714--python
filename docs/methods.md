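# Methods

## Data model and locus conventions

A haplotype is a map from *allelic series* to repeat counts (floats; one
fractional digit of nomenclature precision; intermediate alleles such as
13.2 are legal and compared exactly under the infinite-allele model).
Two conventions turn raw genotype tables into analysis-ready series:

- **DYS389b.** DYS389II is amplified as a compound repeat containing
  DYS389I, so the independent series is DYS389b = DYS389II − DYS389I.
  Missing input propagates; a non-positive difference is logged as an
  inconsistency and set missing.
- **Multi-copy markers.** DYS385 and DYF387S1 amplify two loci each and
  are split into "a" (smaller allele) and "b" (larger allele) series. A
  single observed allele is treated as homoallelic — the same value on
  both series — which is the standard reporting convention; the
  alternative reading (second copy missing) can be obtained by leaving
  the cell empty for one series.
- **Duplications.** Two peaks at a single-copy locus are recorded (both
  alleles kept in `duplication_flags`) but the locus is missing for all
  downstream statistics. No published comparison rule exists for such
  calls, and exclusion is the conservative forensic choice.

Missingness filtering keeps individuals with at most `max_missing`
(default 3) untyped series; the operation is order-preserving, idempotent
and monotone in the threshold. The qPCR degradation index is the
small-target/large-target concentration ratio, kept at full precision
internally and rounded to integer for reports; it is undefined when the
large target is not detected.

## Diversity indexes

Per-locus gene diversity uses the unbiased estimator
GD = n(1 − Σx²ᵢ)/(n − 1) with pairwise deletion of missing calls (n is
locus-specific). Haplotype-level indexes come from the occurrence
spectrum of distinct haplotypes: HMP = Σp²ᵢ, HD = n(1 − HMP)/(n − 1),
DC = k/n. Results below n = 2 are undefined and logged.

**Compatibility clustering.** Partial profiles cannot be counted as
distinct merely for being partial. Profiles are processed in descending
order of typed-series count; each joins the existing cluster with which
it is *compatible* (equal at every series typed in both) that shares the
most typed-and-equal series, ties going to the earliest cluster, else it
founds a new cluster. The cluster consensus is the union of its members'
typed calls, so a partial profile can never bridge two clusters that
disagree anywhere. A profile compatible with several mutually
incompatible clusters joins only its best match, and the ambiguity is
logged. One consequence worth noting: a one-step mismatch at any shared
series keeps profiles distinct no matter how many other series agree.

Report rounding is 4 decimals for HD/HMP/DC and 6 for GD group means;
full precision is retained internally. Group averages of per-locus GD
computed from *rounded* per-locus inputs can differ from averages of
unrounded values in the 6th decimal; the package never asserts equality
beyond the inputs' precision.

## Pairwise comparison

For each pair the comparison runs over the intersection of typed series,
yielding a 0/1 mismatch vector (IAM view) and a signed repeat-difference
vector (SMM view). Copy-2 markers are compared a-vs-a, b-vs-b after the
per-haplotype ascending sort; minimum-cost assignment across copies was
considered and rejected as non-standard. Non-integer differences under
SMM are rounded to the repeat lattice with a warning. A pair with zero
shared typed series is unusable and raises.

## Bayesian TMRCA

With t generations from each sampled man back to the common ancestor,
each locus has experienced 2t independent meioses. Likelihoods:

- IAM: P(match) = (1 − μᵢ)^2t, P(mismatch) = 1 − (1 − μᵢ)^2t.
- SMM: P(d) = Σₘ Binom(m; 2t, μᵢ) · C(m, (m+d)/2)/2ᵐ over m ≥ |d| with
  m ≡ d (mod 2); the binomial sum is truncated where its tail falls
  below 1e-12 (bounded compute, bounded error).

The prior on t is geometric with mean λ, P(t) = (1/(λ+1))(λ/(λ+1))ᵗ —
the discrete analogue of the exponential pairwise coalescence prior.
λ defaults to 1000 generations and is always configurable; the posterior
grid is 0..grid_max with grid_max = max(10λ, 5000), covering >99.99% of
the prior mass, and a warning fires if posterior mass accumulates within
5 points of the boundary. All computation is in log space; IAM is
vectorized over the whole grid.

Summaries: posterior mean; discrete median (smallest t with CDF ≥ ½);
mode with smallest-t tie-breaking (determinism); central equal-tailed
credible intervals with bounds snapped *outward* to grid points, so an
interval at level L always carries at least L posterior mass and
intervals at nested levels are nested. The doubling to *total*
generations separating the pair (2t) and the conversion to years
(default 33 years/generation, a genealogy-based regional estimate) are
pure rescalings of the support; the mass vector is untouched.

Calibration (checked by the test suite): on 500 pairs simulated at
t = 12 under the default 27-series rates, the 50% CI covers the truth at
0.40–0.60 empirical rate and the median absolute mode error is ≤ 5
generations. With ~0.13 expected mutations per meiosis across the panel
the likelihood, not the λ = 1000 prior, dominates the posterior at this
depth.

## Continuity test

A pair is flagged when its decisive credible interval (default the 50%
interval — stricter than 95% for this purpose because it is narrower) on
the years-separating scale overlaps the burial window (default 300–500
years before present). Overlap uses closed intervals: endpoint contact
counts, the weaker and reproducible reading. An ancient individual shows
continuity when at least one modern partner is flagged (OR over
partners); the summary reports the flagged-partner count per ancient
individual.

## Population structure

Two-level AMOVA on a squared-distance matrix: SSD_total = Σ_{i<j}d²ᵢⱼ/N,
SSD_within = Σ_pop Σ_{i<j∈pop} d²ᵢⱼ/n_pop, σ²_w = SSD_within/(N − P),
σ²_a = (SSD_among/(P − 1) − σ²_w)/n′ with n′ = (N − Σn²_p/N)/(P − 1),
Φ_ST = σ²_a/(σ²_a + σ²_w). With the 0/1 label distance this is a
frequency-based F_ST (labels are normally externally predicted
haplogroups; haplotype-cluster identity is used when no labels are
supplied); with squared repeat differences it is R_ST. Missing loci are
dropped pairwise and the distance rescaled by panel size / shared size to
keep pairs with unequal missingness comparable (configurable off).
Negative variance components are reported as computed. Permutation
p-values shuffle individuals across the two populations, 10,000
permutations by default, with the observed statistic included:
p = (b + 1)/(m + 1), never exactly zero. Ties within 1e-12 of the
observed statistic count as ≥, so fully differentiated toy data yield
the smallest p the tie structure allows rather than 1/(m + 1) exactly.

## Synthetic village generator

The generator emulates the study design the analysis targets:

- **Founders.** 4 founding lineages; founder haplotypes are drawn from
  plausible bounded integer repeat ranges per series (no external
  frequency database), and each founder is offset by +2·k at six series,
  guaranteeing ≥ 8 mutation steps over ≥ 6 series between lineages —
  distinct haplogroup-like backgrounds.
- **Growth.** Each male leaves Poisson(1.2) sons per generation over 15
  generations (~500 years at 33 years/generation); a lineage's last line
  is kept alive rather than allowed to die out, since the analysis needs
  extant lineages.
- **Mutation.** Per meiosis, per series, Bernoulli(μᵢ) with a ±1 step.
  The bundled default rate table is synthetic (core series 2×10⁻³,
  added non-RM series 4×10⁻³, RM series 1.2×10⁻²), reproducing the
  order-of-magnitude structure of published panels without shipping any
  published table; real rate tables load from YAML.
- **Sampling.** 13 "ancient" individuals from generations 0–6 (hence
  9–15 generations, ~300–500 years, before the 14 "modern" individuals
  sampled at the final generation), with stratum labels SU28/SU26/SU23
  from oldest to youngest third of the ancient window.
- **Dropout.** Series are dropped missing-completely-at-random per
  stratum (defaults SU28 0.45, SU26 0.12, SU23 0.06, modern 0.0),
  mirroring the age-graded typing success of stratified crypt burials.
  Real aDNA dropout is amplicon-length-dependent; that refinement is
  deliberately not modelled, so passing tests say nothing about
  locus-specific dropout structure.

Every dataset carries a truth table of pairwise total generations to the
pedigree MRCA (NaN for cross-lineage pairs, which share no ancestor in
the simulation). Identical seeds give byte-identical tables.

What the simulator does *not* emulate: real allele-frequency spectra,
length-dependent dropout, mutation-rate heterogeneity within the RM
class, back-migration into the village, or contamination. Tests passing
on synthetic data therefore validate the estimators' internal
consistency and calibration under the stated model, not their behaviour
on any particular empirical dataset.

## Problem sizes

Default analysis sizes were chosen to keep the statistical checks sharp
while remaining desk-scale: Monte-Carlo likelihood oracles use 10⁶
replicates (3-standard-error agreement), calibration uses 500 simulated
pairs, lineage-discrimination checks use the full 13 × 14 ancient ×
modern pair grid of one seed-locked village, and permutation tests in
the test suite use 10²–2×10³ permutations (the library default is 10⁴).

## Known limitations

- The greedy compatibility clustering is order-dependent by design
  (descending typed count); a globally optimal partition would need a
  set-cover solver and has no forensic precedent.
- The SMM posterior loops over the grid per locus and is an order of
  magnitude slower than the vectorized IAM posterior; IAM is the default
  model throughout.
- AMOVA supports exactly two populations (the analysis's design); no
  hierarchical multi-group variant is provided.
- The geometric prior is one defensible discretization of the pairwise
  coalescence prior; other priors would shift posteriors for
  near-uninformative pairs (many missing loci).
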