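# Methods

## The problem

The intersexual genetic correlation for fitness, r_mf, is estimated by
measuring male and female fitness across a panel of genotypes (here,
isofemale lines treated as single genotypes) and correlating the
line-level means. Negative r_mf is read as intralocus sexual conflict.
Unidirectional cytoplasmic incompatibility (CI) confounds this: a genotype
that is *uninfected* with *Wolbachia* has females that fail when mated to
infected males, while its males — free of infection costs — may be
unusually competitive. The uninfected genotypes then contribute
(low-female, high-male) points that pull the correlation negative with no
shared-locus antagonism involved. `cibias` quantifies that artifact two
ways: by direct Monte-Carlo simulation at the genotype level, and by an
isoline analysis pipeline exercised on synthetic individual-level data
with known ground truth.

## Scenario simulator (`cibias.scenarios`)

Per replicate, each of `n_genotypes` (default 10) genotypes gets one male
and one female fitness value, independent draws from
Normal(`baseline_mean`=60, `baseline_sd`=15) in arbitrary reproductive
success units. `round(ci_fraction * n_genotypes)` genotypes, chosen
uniformly without replacement per replicate, are uninfected: their female
value is redrawn from Normal(`ci_female_mean`=5, `ci_female_sd`=2), and in
`male_mode="high"` their male value from Normal(`high_male_mean`=85,
`high_male_sd`=15). Draws are *not* truncated at zero: the generator
mirrors raw normal sampling, and negative values (probability ~0.6% for
N(5,2)) are a property of that model, not a bug. Which genotypes are
uninfected is irrelevant to the correlation (it is exchangeable over
genotype labels), so random selection per replicate is observationally
equivalent to a fixed assignment.

A battery computes each replicate's Pearson r across genotypes and tallies
sign and two-tailed significance at `alpha` (0.05). Significance of the
correlation and of the regression slope coincide for simple regression
(identical t), so a single test serves both phrasings. Tie-break: r
exactly 0 counts as positive. A zero-variance replicate would make r
undefined; such replicates are recorded as `None`, excluded from both
tallies and warned about, rather than crashing a battery (they cannot
occur with valid configs, which require positive SDs, but the guard keeps
batch runs robust to pathological inputs).

Randomness: one `numpy` `SeedSequence` per battery, spawning an
independent child stream per replicate, so results are reproducible and
independent of execution order. The 3 × 2 grid runner spawns one child per
cell the same way.

## Statistics (`cibias.stats`)

- `pearson_rmf`: product-moment r; t = r sqrt(n−2)/sqrt(1−r²) on n−2 df;
  two-tailed p from Student's t (scipy). Also returns the OLS slope of
  female on male fitness and its SE (these feed the slope comparison).
- `compare_slopes`: t = (b1 − b2)/sqrt(se1² + se2²), df = n1 + n2 − 4
  (two slopes and two intercepts estimated). For 27- and 25-line
  regressions this gives df = 48. If both SEs are zero the statistic is
  degenerate and is reported explicitly as t = 0 (equal slopes) or signed
  infinity with p = 0, rather than raising.
- `chi_square_independence`: Pearson Σ(O−E)²/E with margin-based expected
  counts and no Yates correction (`scipy.stats.chi2_contingency`,
  `correction=False`); zero margins are reported as errors naming the
  empty row/column.
- `binomial_sign_test`: z = (k − n·p0)/sqrt(n·p0·(1−p0)) with no
  continuity correction, plus the exact two-sided p that sums all binomial
  point masses not exceeding the mass at k (`scipy.stats.binomtest`).

## Isoline pipeline (`cibias.pipeline`)

Raw records (one row per assayed individual) are Z-standardized within
each sex-by-block cell using the sample (n−1) SD, putting offspring counts
and paternity shares on one scale and absorbing block location/scale.
Line means of z are pooled across blocks unweighted — standardization has
already removed block effects, and the intended balanced design makes
weighting moot. r_mf is the Pearson correlation of male vs female line
means (df = n_lines − 2).

Suspect-line exclusion **re-standardizes from scratch** on the remaining
records before re-aggregating; subsetting previously computed z-scores is
wrong because cell means and SDs change, and a regression test pins the
difference. Outlier handling is flag-only (`flag_outliers`, default
|z| > 3): removal requires an explicit caller decision so it is visible in
the analysis record.

The sex-by-line interaction test is an OLS F test: fitness_z on sex, line,
block and sex:line, all categorical fixed effects, comparing residual sums
of squares of the full and interaction-free models (df1 = rank difference,
df2 = N − full rank). Treating block as *fixed* is a deliberate
simplification of the random-block mixed model a field analyst might fit:
with ~3 blocks the distinction is minor, and REML machinery is out of
scope here. The reported df are the honest OLS ones. Null calibration of
this test is verified by simulation (type-I error ≈ 0.05); the test is run
on standardized data, whose per-cell constraints make it very mildly
conservative.

`ci_bias_report` bundles the with/without-suspects estimates, the slope
comparison between them, leave-one-line-out r values (per-line leverage),
and sex-specific line ranks (whose crossings the interaction test detects).

## Synthetic isoline generator (`cibias.synthetic`)

The generator emulates the standard assay: `n_lines`=27 ×
`n_blocks`=3 × `n_per_sex_per_block`=10 per sex. Latent effects live on a
common unit scale (one unit = one log-odds unit for males; for females,
`female_scale` offspring per unit):

- line effects (g_m, g_f): bivariate normal, SD `sigma_line`,
  correlation `rho_mf` — the ground-truth intersex correlation;
- block effects β_b ~ N(0, `sigma_block`), shared by the sexes;
- residuals ε ~ N(0, `sigma_resid`) per record.

Female record: `round(max(0, mean + female_scale*(g_f + β_b + ε)))`, an
offspring count; `mean` is `female_mean`=60 normally and
`ci_female_mean`=5 for CI lines. Male record: the focal male's paternity
share wt/(wt+ebony) in a vial with 4 marker testers, generated as
Binomial(`n_offspring_assay`=100, logistic(`male_baseline_logit` + g_m +
β_b + ε (+ `ci_male_boost` for CI lines)))/`n_offspring_assay`. The share
parametrization avoids the division-by-zero of a literal wild-type:marker
ratio. The baseline logit is logit(0.2): one focal male against four
equivalent testers.

Variance defaults (`sigma_line`=0.7, `sigma_block`=0.3, `sigma_resid`=0.8,
`female_scale`=15) were chosen on variance-component grounds: female
counts get an SD of ≈ 17 around 60, comparable to the scenario simulator's
N(60,15); line means over 30 individuals/sex then carry reliabilities of
≈ 0.95, so the estimated r_mf recovers the generating ρ with modest
attenuation (within ±0.15 over seed batteries). `ci_male_boost`=2 logits
lifts a CI male's expected share from ≈ 0.2 to ≈ 0.65, making CI lines the
lowest-female, among-the-highest-male lines, the configuration that drives
the bias.

All random draws are made unconditionally in a fixed order depending only
on the design dimensions, so datasets differing only in `ci_lines` or
`cured` are paired by common random numbers (male counts use inverse-CDF
binomial draws from shared uniforms). `cure()` flips `cured=True`:
CI effects are switched off, emulating antibiotic elimination of the
infection, while all non-CI structure is bit-identical under the same
seed — enabling low-variance paired comparisons of the infected and cured
worlds.

Deliberate asymmetry with the scenario simulator: female counts here are
rounded and floored at zero (real assays yield non-negative integers),
whereas the scenario simulator keeps raw normal draws; the two modules
model different levels of the experiment.

What the generator does **not** emulate: infection-frequency dynamics,
partial CI penetrance, mate choice, larval competition, tester-male
infection status, or real *Drosophila* overdispersion in offspring counts.
Passing tests therefore show the pipeline's statistical behaviour under a
clean variance-component model, not that real fly data meet these
assumptions.

## Problem sizes and numerical choices

Monte-Carlo checks use 50 batteries × 100 replicates for the scenario
tallies, 200 datasets per condition for parameter recovery and the
bias/cure pattern, and 800 null simulations (8 lines × 2 blocks × 5/cell)
for F-test calibration — sizes at which the sampling error of each check
is several times smaller than its acceptance band. Cell standardization
requires ≥ 2 records and nonzero SD per cell and fails loudly naming the
cell. p-values are clamped to [0, 1] by construction; |r| is clipped to 1
before the t transform to avoid NaNs at machine-precision overshoot.

## Known limitations

- The mixed-model (random block, Satterthwaite df) analysis is
  approximated by fixed-effect OLS; df and p differ from a REML fit,
  though conclusions on balanced 3-block data agree closely.
- The exact contingency tables behind grid-level independence tests depend
  on how scenario outcomes are cross-classified; the package provides the
  generic chi-square test rather than one blessed table construction.
- Isoline variance components for real populations are unknown; the
  generator's defaults are plausible, tunable, and not asserted as
  estimates of any real population.
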