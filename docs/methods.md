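# Methods

## Disease model and case ascertainment

Disease risk follows a logistic model in dominant carrier status
G ∈ {0, 1} (≥ 1 minor allele) and binary exposure E:

    odds(D = 1 | G, E) = baseline_odds · OR_G^G · OR_E^E · OR_GxE^{G·E}

`baseline_odds` (default 0.001) is the disease odds of an unexposed
non-carrier; small values encode the rare-disease assumption under which the
case-only (CO) design identifies OR_GxE. The exposure main-effect OR
defaults to 1.5 throughout the pipeline, and the two study exposure
frequencies are 10% and 30%.

Cases are drawn by rejection sampling: a diplotype is sampled uniformly
with replacement from the panel, E ~ Bernoulli(p_exposure), and the draw is
accepted with probability P(D=1|G,E). This is exact for any parameter
combination (no analytic inversion, no approximation) at the cost of ~1/P(D)
draws per case; with baseline odds 0.001 and n = 719 that is a few hundred
thousand vectorized draws, well under a second. The optional `flip_prob`
argument perturbs accepted diplotypes with independent allele flips to model
study/panel divergence beyond ascertainment; its default is 0 and flips are
applied after acceptance (the recorded genotype is the flipped one).

## Exposure probabilities among cases and analytic power

All case-conditional quantities are exact Bayes computations over the four
(G, E) population cells:

    P(E=1 | G=g, D=1) = p_E·P(D|g,1) / [p_E·P(D|g,1) + (1−p_E)·P(D|g,0)]
    P(G=1 | D=1)      = Σ_e w(1,e) / Σ_{g,e} w(g,e),   w(g,e) = P(g)P(e)P(D|g,e)

As baseline odds → 0 the odds ratio between the two exposure probabilities
converges to OR_GxE (the CO principle); the test suite asserts the
convergence to within 1e−3 in log-odds at baseline odds 1e−5.

Analytic power treats the cases as two groups of *expected* (fractional)
sizes n·P(G=1|D=1) and n·(1−P(G=1|D=1)) with exposure probabilities p₁, p₀;
the effect is β = log[p₁(1−p₀)/(p₀(1−p₁))], SE² = 1/(n₁p₁q₁) + 1/(n₀p₀q₀),
and two-sided power Φ(|β|/SE − z_{1−α/2}) + Φ(−|β|/SE − z_{1−α/2}).
Fractional group sizes keep the function smooth for root finding. The
detectable interaction OR at a target power is the unique root > 1 of this
formula, found by Brent's method on log OR over [0, log 50]; the solver
verifies the achieved power to 1e−6 and reports the binding parameters when
the target is unattainable. When the expected carrier group falls below one
case the result carries a `small_group_warning`: the large-sample formula is
not trustworthy there, which is precisely the low-MAF regime where the
sparsity diagnostic n·(1−(1−MAF)²)·p_exposure (≈ 7 exposed carriers at
n = 719, MAF 0.05, 10% exposure) explains the breakdown.

**Known accuracy limits.** Against 20,000-replicate simulation at n = 719
the analytic formula agrees within Monte-Carlo noise at exposure frequency
0.30, but is mildly conservative at exposure 0.10: the simulated power at
the solved OR reaches 0.814 (MAF 0.25) and 0.836 (MAF 0.4) instead of 0.80.
The tests assert two-sided agreement at 0.30 and a one-sided bound
(no shortfall, overshoot ≤ 4 percentage points) at 0.10.

## Synthetic panels with controlled LD

A panel is generated column-wise: the target column is i.i.d.
Bernoulli(MAF); each tag column copies the target allele with probability
c = √r² and otherwise draws an independent Bernoulli(MAF) allele. Then
corr(tag, target) = c exactly in expectation, so the realized r² converges
to the requested value (verified at ±0.02 with 10⁵ haplotypes). The
construction requires tags to share the target's MAF whenever r² > 0;
mismatched MAFs cap the attainable r² and are rejected rather than clipped.
Positions are synthetic 1-based coordinates on one contig; the minor allele
is the ALT allele by convention.

What this generator does **not** emulate: genome-wide haplotype-block
structure, recombination-distance decay, allele-frequency spectra, or
multi-locus LD beyond the star-shaped tag–target dependence. Because tags
are conditionally independent given the target, a moderately rich tag set
identifies the copied reference haplotype almost uniquely, so imputation
stays near-perfect until pruning leaves only a handful of weak tags and then
degrades sharply — real data degrade more gradually. Passing tests therefore
demonstrate the *mechanism* (ascertainment-induced panel mismatch, monotone
quality loss, attenuation bias) and the *calibration* of the statistics, not
quantitative agreement with any real cohort.

Cases are drawn from the same panel that later serves as imputation base;
the case–panel mismatch is induced purely by disease ascertainment. This
isolates the main-effect mechanism and is the reason imputed case MAFs
converge to the panel MAF (not the population MAF) under pruning.

## Imputation engine

A deliberately small haploid Li–Stephens copying model stands in for
production software (minimac4 + Eagle behind an imputation server); it is a
stand-in, not a reimplementation. States are the reference haplotypes;
transitions between consecutive typed sites keep the current haplotype with
probability 1 − `switch_prob` (default 0.01) and otherwise switch uniformly;
emissions match the observed allele with probability 1 − ε
(ε = `mismatch_prob`, default 0.001). Both defaults are plausible
magnitudes for a dense synthetic neighbourhood and are config-exposed and
swept in tests; there is no recombination map or per-site error estimation.

The masked target receives the copying posterior interpolated between its
flanks: the forward message from the nearest retained site on the left and
the backward message from the nearest on the right, each advanced by one
transition step, multiplied and normalized. The probability that a case
haplotype carries the minor allele is the posterior-weighted panel allele at
the target (read without ε-correction — ε models miscopying at *typed*
sites; the prior fallback with an empty retained set then yields exactly
dosage = 2 · panel MAF). The two haploid posteriors of a case are convolved
into the diploid posterior over {0, 1, 2}.

Numerical choices: messages are renormalized per site (no log-space needed
at these sizes); posterior rows are asserted to sum to 1 within 1e−9 and
dosages to equal the posterior mean. Hard calls take the argmax genotype
when its posterior is ≥ 0.8 (boundary inclusive; ties resolve to the
smaller genotype), else missing. This posterior rule is adopted for the
"hard-call threshold 0.8" even though PLINK2's native semantics differ
slightly, because it reproduces the intended missing-rate behaviour and is
fully deterministic. The quality score is Var(dosage)/(2p̂(1−p̂)) with
p̂ = mean(dosage)/2 and population-variance denominator; it is defined as 0
for constant dosages or p̂ ∈ {0, 1}.

LD pruning for round n retains sites with r² *strictly* below (11−n)/10,
computed on the reference panel haplotypes (the quantity the generator
controls); round 1 applies no pruning. Monomorphic sites carry no LD
information and are always retained (pairwise `ld_r2` on a monomorphic site
is an explicit error). An empty retained set is legal and triggers the
prior fallback.

## Case-only fit and replicate engine

With one binary covariate the logistic MLE equals the 2×2-table closed form
β₁ = log(ad/bc), SE = √(1/a+1/b+1/c+1/d); the closed form is used so that
behaviour under separation is deterministic: any zero cell adds 0.5 to all
four cells (Haldane–Anscombe) and flags the fit. The Wald p-value is
two-sided normal (equivalent to the 1-df chi-square). Agreement with an
iteratively fitted GLM is cross-checked in the tests.

Per scenario the imputation is computed once (it does not depend on
exposure) and 10,000 exposure replicates are drawn from the *true*
genotypes via the genotype-specific case probabilities; each replicate is
fitted with the true and with each pruning round's hard-called genotypes.
Missing hard calls are dropped per fit (complete case); a fit whose carrier
group is empty is recorded as missing, and missing fits count as
non-rejections in power/type-I estimates (conservative, with the total
replicate count as denominator). Power uses the strict inequality p < α.
Bias is mean(true-based β₁ − imputation-based β₁) over complete pairs, with
median and IQR alongside.

At n = 719 the closed-form Wald test is itself mildly conservative
(empirical null level ≈ 0.046–0.049), a property of Wald tests on 2×2
tables at these cell counts; the calibration test bounds the level above by
0.05 + 2·MC-SE and below by 0.04.

## Headline calibration computations

`coimpute.studies` fixes the two desk-scale experiments that
`scripts/acceptance.py` reruns:

* **Design-power check** — n = 719, MAF 0.25, OR_G 1.5, OR_E 1.5, exposure
  30%, α 0.05: solve the 80%-power interaction OR, then estimate power from
  10,000 replicates that redraw both carrier counts (from P(G=1|D=1)) and
  exposures. Redrawing genotypes per replicate matches the expected group
  sizes the analytic formula uses; conditioning on a single fixed sample of
  719 cases would add ±0.7pp of carrier-sampling noise to the comparison.
* **Low-MAF null validity** — 10 scenarios with target MAF uniform in
  [0.01, 0.05), panels of 1,000 haplotypes with 50 tags spanning r²
  0.1–0.9, OR_G 2, 719 cases; impute after pruning at r² < 0.5, hard-call
  at 0.8, run 2,000 null replicates (exposure 10% for all genotypes) and
  report the median empirical type-I error. 2,000 replicates per scenario
  (rather than 10,000 over a 56-SNP panel) keep the computation at desk
  scale; a scenario whose hard calls contain no carriers at all is scored
  0 (the test can never reject).

## Pipeline determinism and scale

One root seed drives everything; child generators are derived per
(seed, stage-label, scenario) via hashed `SeedSequence` keys, so scenario
execution order is irrelevant and reruns are byte-identical. Default
problem sizes (719 cases, 1,000-haplotype panels, 10,000 replicates) run in
seconds per scenario; the replicate engine is vectorized over replicates in
blocks bounded to ~8 M matrix elements.

## Known limitations

* Single-block star-shaped LD (see above); whether the sharp late
  degradation can reproduce the real-data kink between r² thresholds 0.6
  and 0.5 in the high-MAF category is left exploratory.
* Phasing is assumed known (synthetic truth is phased); unphased input is
  rejected rather than phased.
* Dominant coding only; no covariates, no population-stratification
  correction, no case–control tier.
* Pruning r² is computed in the reference panel, not in the study sample;
  with main effects the two differ slightly.
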