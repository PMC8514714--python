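# ylineage

Y-chromosome STR analysis for diachronic male samples: forensic diversity
indexes, partial-profile haplotype matching, Bayesian pairwise TMRCA
estimation, chronological continuity testing, and two-population AMOVA —
plus a forward genealogy simulator that generates fully known test data.

## The problem

Y-STR haplotypes (vectors of repeat counts at 17 or 27 loci of the male
specific Y chromosome) are inherited intact down paternal lines, barring
stepwise mutation. When ancient male remains from a small community can be
genotyped alongside the community's present-day men, three questions arise:

1. **How discriminating is the panel?** Per-locus gene diversity
   GD = n(1 − Σx²ᵢ)/(n − 1), haplotype diversity HD = n(1 − Σp²ᵢ)/(n − 1),
   haplotype match probability HMP = Σp²ᵢ, and discrimination capacity
   DC = k/n (k distinct haplotypes among n men). Ancient profiles are often
   partial, so distinct-haplotype counting uses *compatibility clustering*:
   profiles equal at every locus typed in both are pooled.
2. **How long ago did an ancient–modern pair share a paternal ancestor?**
   A Bayesian estimator puts a geometric prior (mean λ) on the per-branch
   TMRCA t and multiplies per-locus likelihoods: under the infinite-allele
   model a locus matches with probability (1 − μᵢ)^2t after the 2t meioses
   separating the pair; under the stepwise model the observed repeat
   difference d follows a ±1 random walk over Binomial(2t, μᵢ) mutations.
   The posterior over t is summarized by mean/median/mode and central
   credible intervals; the total generations separating the two men is 2t
   and converts to years at 33 years per generation.
3. **Did the paternal gene pool change?** A pair passes the *continuity*
   test when its 50% credible interval (in years separating the pair)
   overlaps the chronological window of the burials (default 300–500 years
   before present); ancient individuals are flagged when any modern partner
   passes. Population-level differentiation is measured by two-level AMOVA:
   frequency-based F_ST on lineage labels and R_ST on squared repeat-count
   distances, with permutation p-values.

Because raw diachronic Y-STR datasets are rarely redistributable, the
`simulate` module grows a village forward in time — a few well-separated
founding paternal lineages, per-locus stepwise mutation with a rapidly
mutating (RM) subset, ancient sampling 9–15 generations before the modern
generation, and stratum-graded locus dropout — and emits a truth table of
pairwise generational separations for calibration.

## Worked example

```python
from ylineage import (SimulationConfig, simulate_village,
                      write_haplotype_table, RunConfig, run_all)

cfg = SimulationConfig(seed=7)          # 4 lineages, 15 generations
village = simulate_village(cfg)
write_haplotype_table(village.haplotypes, cfg.panel, "genotypes.csv")

rc = RunConfig(genotype_table="genotypes.csv", output_dir="out", seed=7)
run_all(rc)                             # 7 stages, outputs as CSV
```

`out/diversity.csv` then holds (for this seed):

```
dataset panel  n  n_distinct     HD    HMP     DC
  Total  full 25          10 0.8367 0.1968 0.4000
  Total  core 25           6 0.7633 0.2672 0.2400
   RP_A  full 11           5 0.7818 0.2893 0.4545
   RP_M  full 14           8 0.8901 0.1735 0.5714
```

Reading: among the 25 individuals surviving the ≤3-missing-loci filter, the
27-locus panel resolves 10 distinct haplotypes (HD 0.8367); projecting the
same men onto the 17-locus core panel collapses them to 6 (HD 0.7633) — the
added RM loci carry most of the discriminating power. `structure.csv` shows
no ancient/modern differentiation (FST −0.0149, p 0.567; RST −0.0341,
p 0.553), and `continuity_summary.csv` flags 10 of 11 ancient individuals
as having at least one modern pair whose 50% CI overlaps the 300–500-year
window — the simulated village is, by construction, paternally continuous.

The same analyses are available as CLI subcommands
(`ylineage simulate | convert | diversity | compare | tmrca | continuity |
structure | run-all`).

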