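# coimpute

Simulation pipeline for studying how **genotype-imputation error** affects the
validity and statistical power of **case-only (CO) studies of
gene–environment (G×E) interaction**.

## The problem

The case-only design estimates G×E interaction from the genotype–exposure
association *within cases only*: for a rare disease with gene–environment
independence in the population, the odds ratio of exposure between carriers
and non-carriers of a risk allele equals the interaction odds ratio
OR<sub>G×E</sub>. In practice the genotype is often not typed but *imputed*
from a reference panel of population haplotypes. At loci with a genetic main
effect on disease risk, case haplotype frequencies deviate systematically
from any population panel, so imputation silently pulls case genotypes toward
the panel — and with them the interaction estimate toward the null.

`coimpute` makes that mechanism reproducible at desk scale:

* **synthetic data** (`coimpute.panel`) — phased reference panels with exact
  control of the r² between each tag SNP and a target SNP (a tag copies the
  target allele with probability √r²); case samples ascertained from the
  panel by rejection sampling under a logistic disease model
  `odds(D=1|G,E) = baseline_odds · OR_G^G · OR_E^E · OR_{G×E}^{G·E}` with
  dominant coding; genotype-specific exposure assignment. VCF v4.2 I/O.
* **exposure & power** (`coimpute.power`) — exact Bayes derivation of the
  exposure probabilities among carrier/non-carrier cases, analytic two-group
  Wald power of the CO test, and a solver for the interaction OR detectable
  at a target power (e.g. 80%).
* **imputation** (`coimpute.impute`) — mask the target, LD-thin the base in
  ten rounds (`none, r²<0.9, …, r²<0.1`), impute each case haplotype with a
  haploid Li–Stephens copying model (forward–backward over reference
  haplotypes), convolve to diploid posteriors, score quality with the
  minimac-style R² = Var(dosage)/2p(1−p), hard-call at posterior ≥ 0.8, and
  apply the exclusion filters (imputed MAF < 0.005, missing rate > 0.2).
* **case-only analysis** (`coimpute.caseonly`) — closed-form fit of
  `logit P(E=1) = β₀ + β₁·G` (the 2×2-table MLE, Haldane–Anscombe corrected
  under separation), Wald test, and a vectorized replicate engine yielding
  power, type-I error and bias = true-based β₁ − imputation-based β₁.
* **metrics** (`coimpute.metrics`) — Cohen's kappa on the 3×3 genotype
  confusion table, MAF categories, pair-pruning and null-SNP matching rules.
* **pipeline & CLI** (`coimpute.pipeline`, `coimpute` command) — scenario
  grids from a YAML/JSON config, deterministic per seed, CSV outputs.

## Worked example

Solve the interaction OR detectable with 80% power in 719 cases
(MAF 0.25, OR<sub>G</sub> 1.5, OR<sub>E</sub> 1.5, exposure frequency 30%):

```bash
$ coimpute power --maf 0.25 --or-g 1.5 --p-exposure 0.3 --n-cases 719 --solve-or
n_cases,maf,or_g,or_e,or_ge,p_exposure,alpha,power,p_exposed_carrier_case,p_exposed_noncarrier_case,small_group_warning
719,0.25,1.5,1.5,1.5399238836011147,0.3,0.05,0.8000000000000008,0.49698510473155927,0.39118541033434656,False
```

An interaction OR of 1.54 is detectable; it manifests in cases as exposure
probabilities 0.497 (carriers) vs 0.391 (non-carriers). Now run the two-tier
pipeline for a main-effect SNP (OR<sub>G</sub> = 2) with the config

```yaml
# demo.yaml
seed: 11
n_cases: 719
n_reps: 2000
exposure_frequencies: [0.3]
prune_thresholds: [none, 0.5, 0.2]
scenarios:
  - {id: nod2_like, maf: 0.25, or_g: 2.0, or_e: 1.5, baseline_odds: 0.001, p_exposure: 0.3}
```

```bash
$ coimpute tier2 --config demo.yaml --out demo_out
$ cat demo_out/power.csv
scenario,maf_category,exposure_freq,threshold,or_ge,power
nod2_like,high,0.3,true,1.566407553,0.824
nod2_like,high,0.3,none,1.566407553,0.8155
nod2_like,high,0.3,0.5,1.566407553,0.6405
nod2_like,high,0.3,0.2,1.566407553,
```

With true genotypes the test reaches the designed ~80% power; imputation
without pruning barely hurts (0.816), pruning the base at r² < 0.5 drops
power to 0.64, and at r² < 0.2 every hard call falls below the 0.8 posterior
threshold (power undefined). `quality.csv` shows why: the imputed case MAF
shrinks from 0.355 (true case MAF 0.360) through 0.336 to 0.281, converging
toward the panel MAF 0.257, while kappa falls from 1.0 to 0.89 and the
dosage-R² from 0.76 to 0.24. `bias.csv` shows the matching attenuation of
the interaction estimate (mean true-minus-imputed β₁: 0.0004 → 0.0495).

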