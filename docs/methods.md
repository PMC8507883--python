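# Methods

This note documents the statistical machinery, the synthetic data-generating
process, the numerical conventions, and the design choices where the design
was genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Quality control

The chain runs in a fixed order — sample call rate → heterozygosity →
variant call rate → HWE exact test → IBD — with each rule applied to the
survivors of the previous one, so every excluded id appears under exactly
one rule and the report's counts conserve (`input = retained + Σ excluded`,
checked by `QCReport.counts_conserve`).

* **Call rates.** A sample or variant is excluded when its missing fraction
  strictly exceeds 5% (defaults in `QCThresholds`).
* **Heterozygosity.** Per sample, het = (N−O)/N with N non-missing and O
  homozygous calls. Mean and SD are taken over samples that passed the
  call-rate filter (outlier statistics should not include failed samples);
  samples beyond ±3 SD are excluded. A sample with zero evaluable calls is
  flagged and excluded rather than silently kept; if the SD is zero nothing
  is excluded. Because this is a tail trim, a clean cohort still loses
  ~0.3% of samples by chance — that is a property of the rule, not a bug.
* **HWE exact test.** The conditional exact test on the heterozygote count
  given the allele counts: all attainable heterozygote configurations share
  the parity of the rare-allele count; each gets the multinomial probability
  ∝ 2^h·n!/(n_rr!·h!·n_cc!), evaluated in log space (gammaln + logsumexp)
  and the p-value sums configurations whose probability does not exceed the
  observed one (classic two-sided test, no mid-p correction, all samples
  treated as founders). Monomorphic variants get p = 1 and can never be
  excluded by this rule. Tests verify agreement with an exact-rational
  enumeration oracle to 1e-12 for every count triple with n ≤ 25.
* **IBD.** Method-of-moments P(IBD=0/1/2) from genome-wide IBS counts and
  in-sample allele frequencies; probabilities are clamped to [0,1] and
  renormalised, PI_HAT = P2 + P1/2. For a pair with missing calls the
  expected IBS sums are scaled by the pair's valid-call fraction (a global
  approximation rather than per-pair frequency recomputation). Monomorphic
  variants are uninformative and skipped; below 50 informative variants the
  report carries an instability warning. Pairs with PI_HAT > 0.1875 lose
  the member with the lower call rate (tie → the higher sample index).
  An optional LD-pruning flag (`ibd_ld_prune`, off by default) estimates
  PI_HAT on a greedy window-pruned marker subset (r² ≤ 0.2, window 50).
  Note the trade-off: pruning removes redundant markers but also shrinks
  the panel, and the estimator's variance scales with the inverse effective
  marker count — with this generator's dense blocks the full unpruned panel
  actually has the smaller tail noise, which is why the worked example uses
  6000 markers rather than pruning. Y-chromosome variants are excluded from
  heterozygosity and HWE by a chromosome filter and from the scan by
  default; X is treated autosomally.

## Phenotypes

eGFR uses the 4-variable MDRD study equation with the printed coefficients
(175, −1.154, −0.203, 0.742 female, 1.21 African-American; the cohort is
non-African-American so the last factor is inert by default). The mediator
is the natural log (not log₁₀) of plasma aluminum; non-positive
concentrations are domain errors, never silently offset. Additive coding
determines the minor allele from the post-QC analysis sample (no external
reference panel); a coded-allele frequency above 0.5 flips the coding,
an exact 0.5 tie is broken toward the lexicographically smaller allele
character, and the per-variant record (minor/major allele, MAF, flip flag)
makes genotype labels such as CC/CT/TT → 0/1/2 reproducible. The operation
is idempotent.

## Association scan

Per SNP: OLS with intercept, complete cases per SNP, two-sided p from the
t distribution with residual degrees of freedom. A constant genotype or
singular design yields an unestimable record (NaN statistics, counted and
reported) rather than a dropped row. The default model adjusts for sex,
age, smoking and drinking; `model="crude"` drops them — both are provided
because the source workflow describes a crude scan while its genome-wide
figure is captioned as adjusted, and the package does not adjudicate.
Significance tiers use the exact α/m value with strict inequality
(p < threshold); the one-significant-figure rendering (e.g. 0.05/645918 =
7.74e−8 shown as 8e−8) is display only. λ = median χ²/0.4549 is reported,
never used to adjust p-values. The OLS engine is a lean numpy
implementation (rank-revealing least squares + classical t inference)
because the mediation bootstrap refits ~10⁶ small models; it is validated
against an explicit normal-equations solver on random instances (1e-8
relative) and against statsmodels.

## Mediation

Three models on joint complete cases (rows complete for x, m, y and all
covariates, so the decomposition identity holds exactly). Covariates enter
all three models by default, including the mediator model — the displayed
mediator equation is often written bare, but adjusted path estimates are
what the workflow reports; `covariates_in_mediator=False` restores the
literal bare form. The indirect effect is the product a₁·rₘ.

The bootstrap resamples individuals (rows) with replacement — case
resampling, not residual resampling, since percentile CIs for indirect
effects are motivated by their skewed sampling distribution. Each replicate
refits the mediator and outcome models; coefficients for all replicates in
a chunk are solved in one batched normal-equations call. Replicates with a
constant resampled regressor or singular cross-product are counted in
`n_failed_reps` and excluded; more than 5% failures is a hard error (the
CI would be meaningless). Percentiles use linear interpolation between
order statistics at (1−level)/2 and 1−(1−level)/2; defaults are 3000
replications at the 95% level. Each SNP draws from an independent RNG
substream keyed by its variant column index, so results are invariant to
processing order. Baron–Kenny flags come from each model's own residual-df
t-test at α = 0.05; the narrative code distinguishes `full_baron` (all
three criteria), `mackinnon_only` (no significant total effect but
significant a- and b-paths) and `no_mediation_evidence`.

Calibration, measured by the test suite over 500 simulated datasets
(n = 500, 500 replications each): coverage of the true indirect effect
within a 3-SE binomial band of 95%, and when the a-path is zero the CI
excludes zero at no more than 5% + 3 SE (the percentile bootstrap is
conservative-to-nominal in that corner).

## Synthetic cohort generator

The generator emulates the study conditions, not any particular dataset:

* **Genotypes.** Per variant, calls are Binomial(2, q) — Hardy–Weinberg
  proportions — with q either fixed or drawn uniformly from (0.05, 0.5).
  LD is modelled by a per-sample copy-previous-variant process inside
  blocks of `block_size` (probability `ld_copy_prob`), which is sufficient
  to test that the scan flags neighbours of a causal variant without a
  coalescent simulation. All variants in a block share the block's allele
  frequency: copying between variants drawn at different frequencies would
  itself be a Wahlund-style HWE violation and poison the HWE stage.
  Planted HWE violators occupy the tail variant positions and are drawn
  with inbreeding coefficient F = 0.8 at MAF 0.3 (strong homozygote
  excess, detectable by the exact test at a few hundred samples).
* **Covariates.** Age uniform on [30, 70]; male/smoking/drinking Bernoulli
  at 0.557/0.342/0.079 — the study population's marginals.
* **Structural model.** ln(Al) = a₀ + a·G + covariates + N(0, σ_m);
  eGFR = r₀ + b·ln(Al) + direct·G + covariates + N(0, σ_y), redrawn while
  non-positive (no point mass at zero). σ_m = 0.62 reproduces the reported
  aluminum distribution (mean 1.13, SD 0.80 μg/L ⇒ lognormal σ ≈ 0.64);
  σ_y = 20 makes the total eGFR SD ≈ 22 once the age effect (−0.45/yr,
  centred at 50) and the mediator contribution are added. Covariate effect
  sizes are free parameters (the study reports none); the defaults are
  modest plausible values. Intercepts are solved analytically: a₀ from the
  lognormal mean identity corrected by the realized mean of exp(linear
  predictor) so E[Al] hits 1.13 μg/L; r₀ from the realized means so E[eGFR]
  hits 99.5. Serum creatinine is back-computed by inverting the MDRD
  equation (noise lives on the eGFR scale), so the pipeline ingests
  creatinine exactly as real data would and the round trip is exact to
  machine precision.
* **Planted violations.** Contamination redraws a sample with heterozygote
  probability 0.8 (mimicking DNA mixture, matching the excess-heterozygosity
  exclusion rationale); duplicates copy genotypes; first-degree relatives
  share exactly one transmitted allele per variant. Planted low-call-rate
  variants receive an exact ceil(0.2·n) missing calls — deterministic, so
  planted-truth validation can demand exact recovery — while global
  missingness is Bernoulli per call (default 0.2%, giving a total
  genotyping rate near the study's 99.76%). Every planted violation is
  listed in a truth record for the validator tests.
* **Determinism.** Every stage draws from its own crc32-keyed substream of
  the config seed, so identical config + seed gives bit-identical cohorts
  and the truth record is reproducible from the config alone.

What the generator does **not** emulate: population structure or admixture,
coalescent LD with recombination, X/Y dosage, assay noise in creatinine or
aluminum, and any real genotype–phenotype architecture. Passing tests
therefore demonstrate correctness of the estimators under the assumed
structural model, not robustness to the confounding real cohorts carry.

## Problem sizes

The test suite and acceptance script run at desk scale by design: cohorts
of 300–2000 samples and 1000–6000 markers, 500-replicate bootstraps in the
calibration loops and the full 3000 replications for single-SNP analyses;
the analysis scripts use 1000 × 6000. These sizes keep every Monte-Carlo
band (3-SE binomial) meaningful while the whole suite completes in minutes.

## Known limitations

* The per-pair missingness adjustment in IBD scales global expected-IBS
  sums instead of recomputing allele frequencies per pair; with extreme
  differential missingness the estimates shift slightly.
* The batched bootstrap detects singular replicates via exact column-
  variance checks and solver failure; a pathologically near-singular but
  numerically invertible replicate would pass through.
* λ's median-based estimator has substantial sampling noise below ~5000
  markers (SD ≈ 0.05 at 2000), so calibration bands at that scale are wide.
* The MDRD equation is the only eGFR model (no CKD-EPI), and only aluminum
  is log-transformed.
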