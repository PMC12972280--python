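# Methods

## The problem

Gene-expression biomarkers are often reported as "high vs low" survival
contrasts, but the dichotomisation threshold is rarely given a priori. A
common practice is to scan every achievable cutoff within the interquartile
range of the biomarker, test each split with a Cox model, and report the
cutoff with the smallest p-value. Taking a minimum over many correlated
tests inflates the type-I error badly, so the scan must be paired with an
explicit multiplicity correction. `survscan` implements this procedure for
one gene and one cohort at a time — normalization of the input expression
matrix, the quartile-band scan, FDR control, Kaplan–Meier reporting at the
selected cutoff, subgroup scans within clinical strata, and a
tumor-vs-normal expression contrast — together with a synthetic-cohort
generator that makes every stage testable without any external data.

## Normalization

RNA-seq counts are depth-corrected with median-of-ratios size factors:
`s_j = median_g ( c_gj / (prod_k c_gk)^(1/n) )`, with geometric means
computed in log space over genes whose counts are strictly positive in
every sample (genes touching zero are skipped; this is the strict
convention of the reference count-normalization method). A second scaling
step multiplies each sample so that its mean expression over genes equals a
fixed target, 1000 by default. The composition of the two steps is exactly
invariant to multiplying any sample by a positive depth factor, which is
the property the tests assert.

Array-style inputs skip the size factors and receive only the mean-1000
scaling. Two further sample-level QC steps are provided:

- **Duplicate removal.** Samples whose full expression vectors are exactly
  equal are duplicates; only the first in column order is kept. Equality is
  exact by default (a relative-tolerance option exists but defaults off,
  since measured replicates are never exactly equal by accident).
- **Outlier filter.** Given a per-sample table of continuous QC metrics
  (array background, noise, present-call fraction, housekeeping 3'/5'
  ratios — computed upstream, since they need probe-level data), a sample
  is kept iff each metric lies within mean ± z·SD of that metric over all
  samples, z = 1.95996 for the default 95% central band. Bounds are
  computed in a single pass (no iterative re-estimation) so the result does
  not depend on processing order; a zero-variance metric cannot exclude
  anyone.

## Survival core

All four primitives are implemented in the package rather than delegated,
because the scan needs thousands of two-group Cox fits per cohort and the
binary-covariate case collapses to risk-set counts:

- **Kaplan–Meier.** Product-limit estimate over distinct event times with
  Greenwood standard errors. Censoring times tied with an event time remain
  in that risk set (events first). When a risk set is exhausted (S = 0) the
  SE is reported as 0.
- **Log-rank.** Observed − expected over pooled event times with the
  hypergeometric variance; p from chi-square with 1 df via the regularized
  upper incomplete gamma (`scipy.stats.chi2.sf`).
- **Binary Cox.** Newton–Raphson from β = 0 on the partial likelihood with
  Efron tie correction (Breslow selectable); with a single binary covariate
  every Efron term has score μ_l and information μ_l(1−μ_l) for a
  Bernoulli-like mean μ_l, so the whole scan vectorises as a
  (cutoffs × event-times) array iteration. Convergence at |Δβ| < 1e-9 or 50
  iterations, with step-halving whenever the partial log-likelihood
  decreases. A monotone likelihood (all events ordered by group) is flagged
  `converged=False` with β capped at ±15; such fits stay in the scan table
  but cannot be selected as best. The score test is evaluated at β = 0 and
  equals the log-rank chi-square exactly on tie-free data (asserted to
  1e-8 relative); the Wald SE comes from the inverse observed information.
- **Benjamini–Hochberg.** Step-up adjusted values
  q_(i) = min_{j≥i} p_(j)·m/j, capped at 1.

Efron is the default tie rule because day- or month-resolution survival
data produce heavy ties, where Breslow's approximation is visibly biased.
Cross-checks against an established survival library (coefficient and SE to
1e-6 relative on 100 random cohorts) live in the test suite only; the
library is never on the analysis path. For that comparison the reference
fitter is run at much tighter convergence settings than its defaults,
otherwise the comparison measures its stopping rule rather than either
estimate (our root satisfies U(β̂) = 0 to machine precision).

## The cutpoint scan

Candidates are the distinct observed expression values v with
Q1 ≤ v < Q3 (quartiles by the linear-interpolation convention,
configurable); the split is high = expression > v, which guarantees both
groups non-empty for every candidate. This grid reproduces every achievable
split in the band, so "all possible cutoffs" is finite and exhaustive. Each
candidate gets one Cox fit; the ranking p is the score (log-rank) p, and
HR with its Wald 95% CI is reported from the same fit, for the high group
relative to the low group. q-values are BH-adjusted across the scan (one
gene, one cohort — the only multiplicity scope computable from the inputs).
The best cutoff is the minimum p among converged fits, ties resolved to the
smaller cutoff (deterministic and order-independent). The significance call
requires, concurrently, best raw p < α (default 0.05) and best q ≤ fdr_max
(default 0.20).

Subgroup scans filter the cohort to one stratum level first and recompute
the quartile band inside the subgroup. Missing stratum values form an
explicit "missing" category: excluded when that stratum is analysed,
retained in the overall scan.

## Synthetic cohorts

`simulate_cohort` draws expression as log-normal (default log-mean
log 1000, log-SD 1 — the scale the mean-1000 normalization produces),
assigns the latent "high" label above the quantile at `true_cutoff_pct`,
and draws survival under proportional hazards: cumulative hazard
H(t) = rate·t^shape with shape 1 (exponential) by default, rate
`baseline_hazard` for the low group and `baseline_hazard·hr` for the high
group. Censoring is an independent exponential clock capped at an
administrative horizon. Defaults model a solid-tumor cohort with time in
months: baseline hazard 0.015/month (median OS ≈ 46 months), censoring
0.01/month, 120-month cap — about two thirds of subjects have observed
events, and without the cap the event fraction is exactly
rate/(rate + censor_rate), which the tests verify. The sharp threshold
makes cutoff recovery well-posed; a `linear` effect option (log-hazard
proportional to standardised log-expression) is provided to study the scan
under misspecification. All draws come from a seeded `numpy` generator and
are bit-reproducible; the package default seed is 20250627.

What the generator does **not** emulate: real tumor cohorts have
non-log-normal expression mixtures, covariate-dependent censoring,
cure fractions and non-proportional hazards. Passing tests therefore
demonstrate the procedure's internal correctness and its operating
characteristics under the proportional-hazards world it assumes — not that
any particular real-data finding is right.

## Operating-characteristic experiments

- `type1_error_experiment` (null, hr = 1): fraction of replicates whose
  scan minimum raw p is below 0.05, versus the fraction called by the joint
  p/FDR rule. At n = 200 with 1000 replicates the raw rate is ≈ 26–29%
  (minimum-p inflation), while the single fixed median cutoff's log-rank p
  is uniform (KS test); the joint rule calls ≈ 10%. The corrected rate can
  only be ≤ the raw rate, since the joint rule adds a condition.
- `recovery_experiment` (hr ≠ 1): median absolute error of the recovered
  cutoff percentile, the fraction of replicates with the HR direction
  correct, and the median fitted HR. At hr = 2, true percentile 0.6,
  n = 500, 200 replicates: percentile error ≈ 0.01, direction 100%, median
  HR ≈ 2.04 — slightly above the truth, the expected selection bias of
  minimum-p optimised cutpoints (more visible at smaller n).

Problem sizes used by the test suite and the acceptance script — 1000 null
replicates at n = 200, 200 recovery replicates at n = 500, 100 oracle
cohorts — were chosen so each experiment's Monte-Carlo error is well below
the asserted margins while the whole suite runs in well under a minute of
compute per experiment.

## Tumor-vs-normal contrast

A two-sided Mann–Whitney U test of tumor vs normal expression: the exact
null distribution of U when the data are tie-free and n1·n2 ≤ 400,
otherwise the normal approximation with tie-corrected variance and
continuity correction. The reported direction ("up"/"down") compares group
medians and is only asserted when p < 0.01 (configurable), since a rank
test can reach significance with negligible location shift. Violin
summaries use a Gaussian KDE with Silverman bandwidth; constant samples are
flagged degenerate instead of smoothed.

## Numerical and formatting choices

- Quartiles and all quantiles: linear interpolation unless overridden.
- Chi-square tail probabilities: regularized upper incomplete gamma; no
  continuity correction.
- p-value formatting in figures: scientific notation below 1e-4, otherwise
  3 significant figures.
- File I/O: delimiter chosen by extension (.csv = comma, otherwise tab),
  '.' radix, no locale handling; expression matrices are written with 17
  significant digits so read → write → read round trips are bit-exact.
  Sample IDs match by exact string equality.
- Reruns of any subcommand with the same inputs and configuration are
  byte-identical for JSON/TSV outputs (figures excluded; their underlying
  TSVs are covered).

## Known limitations

Single binary covariate only — no multivariable or stratified Cox, no
time-varying effects, no proportionality diagnostics. FDR scope is a single
scan; cross-gene or cross-cohort multiplicity is out of scope, as are
meta-analysis, restricted-mean-survival and landmark analyses. The reported
HR at the best cutoff inherits the optimism of minimum-p selection; the
recovery experiment quantifies that bias but the package does not attempt
shrinkage or cross-validation corrections.
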