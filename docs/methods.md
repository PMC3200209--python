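# Methods

## The modelling problem

Length of stay (LOS) after elective PCI is recorded as whole days from
admission to discharge with a floor of one day. Treating it as a count
conditioned on being positive leads to the zero-truncated NB2 model used
throughout: untruncated mean μ = exp(xᵀβ), dispersion α ≥ 0
(Var = μ + αμ² before truncation), and conditional mean
E[Y | Y ≥ 1] = μ / (1 − (1 + αμ)^(−1/α)). The α → 0 limit is the
truncated Poisson and is handled explicitly (dispersions below 1e−10 use
the Poisson forms; the likelihood optimiser works on log α with bounds
[−12, 4], and an active lower bound is accepted as a Poisson-limit fit via
the KKT condition rather than reported as non-convergence).

Patients cluster within providers. Clustering is handled through the
variance only: the sandwich estimator sums score contributions within
provider before forming the meat, with an optional G/(G−1) small-sample
factor (off by default; the basic estimator is the conventional one when
the correction choice is unspecified). Both the model-based covariance
(inverse observed information, with the Hessian obtained by central
differences of the analytic gradient) and the robust covariance are
stored on the (β, log α) scale; Wald 95% CIs are formed on the log scale
and exponentiated, matching the symmetric-in-log intervals conventional
for rate ratios. No frailty is *estimated* — random intercepts exist only
in the data generator, as the truth the robust variance must absorb.

Fitting is maximum likelihood: L-BFGS-B on the analytic log-likelihood
and score (the score with respect to log α uses digamma terms plus the
truncation correction), polished by damped Newton steps on the
finite-difference Hessian until the gradient max-norm is below 1e−6.
Starting values are the Poisson-regression coefficients and α = 0.5.

## Stratifiers

The MCRS and Wu scores are fixed additive lookup rules. Decisions the
sources leave open, resolved here and configurable where sensible:

* MCRS age term: `floor(max(0, age − 30) / 10)` — one point per
  *completed* decade past 30 (no rounding rule is published; floor keeps
  the score integer and monotone).
* MCRS renal failure (creatinine >2.5 mg/dL or dialysis) is one +3
  criterion, never doubled. Elective mode zeroes the shock and
  urgent/emergent terms.
* Wu mutually exclusive groups are enforced by precedence: dialysis over
  creatinine-only, current over past heart failure; a missing ejection
  fraction scores the reference (≥30%) level. Missing optional covariates
  default to reference levels.
* The TSPC "heart failure present" question uses the combined
  current-or-past flag by default (the published rule does not
  distinguish), with a current-only switch. Renal failure is
  creatinine >2.5 or dialysis; ties at age 70 go to the older branch
  (the question is `age ≥ 70`).

The Wu cutpoint search maximises an additive objective over ordered
partitions of the observed score range into five contiguous categories:
by default the profile ZTNB log-likelihood with category-specific means
and a shared dispersion (estimated once from an intercept-only fit), with
a fast between-category log-LOS sum-of-squares surrogate. Because both
objectives are additive over score intervals, dynamic programming over
precomputed interval values returns the exact optimum of the same search
space an exhaustive enumeration of cutpoint 4-tuples would scan. Each
category must hold at least 0.5% of records (configurable); infeasible
constraints raise a dedicated error.

## Tree growing, pruning and selection

The grower is standard greedy binary recursive partitioning for a binary
endpoint: Gini impurity decrease, thresholds at midpoints between sorted
distinct values, stopping at node purity, `min_leaf`, or `max_depth`;
ties break to the lower covariate index then the lower threshold, so
growth is deterministic.

Pruning is weakest-link cost-complexity pruning. The resubstitution risk
is the **binomial deviance** by default rather than misclassification or
Gini, for two reasons specific to rare endpoints (complication rates here
are 0.5–8%): with every leaf rate below 0.5, misclassification risk is
identical across all subtrees and cannot rank them at all; and the Gini
risk of a split scales with p(1 − p), so chance splits inside a
high-rate branch outrank genuinely predictive splits in low-rate
branches (empirically, a noise split among heart-failure patients can
carry a larger Gini improvement than the true sex split among the
elderly, whose likelihood-ratio statistic is four times larger). The
deviance split statistic is scale-free in the leaf rate. Both
alternatives remain implemented and tested; the hand-checkable
weakest-link arithmetic example uses misclassification risk.

Cross-validated selection follows the standard recipe: the full-data
prune sequence is evaluated at geometric-midpoint α values; each fold
grows and prunes its own tree and scores held-out records with the loss
matched to the risk measure (log loss for deviance, with fold-leaf rates
clipped to [1e−6, 1 − 1e−6]). Fold assignment is stratified by outcome
and made invariant to record order by ranking records on their full
covariate/outcome tuple before the seeded shuffle; `folds = n` is
treated as leave-one-out (stratification is vacuous there). Two
selection rules are exposed: `min_risk`, and the default `one_se` whose
band uses the standard error of the **paired** per-record loss
difference against the CV minimiser. The unpaired SE of the CV risk
itself is an order of magnitude wider than any real subtree contrast
under rare events (subtrees share most of their predictions) and would
always select the root.

Leaves of a selected tree are ordered into risk classes by event rate,
highest rate = highest risk. Partition identity between trees is judged
on induced record partitions, never on node order or labels.

## The synthetic registry

The generator emulates the published testing-years cohort, not the real
registry's joint distribution:

* **Covariates** are independent draws from the published marginals
  (heart failure 5.5%, women 32.6%, renal failure 2.8%, left main 2.9%,
  multivessel 47%, vascular disease 9.4%, prior MI 6.9%; age truncated
  normal mean 64.7, SD 11.8 on [18, 100]). A Gaussian-copula hook accepts
  pairwise correlations for sensitivity runs. Variables the published
  tables omit carry documented defaults: heart failure splits 60/40
  current/past, renal failure 70/30 creatinine-only/dialysis, prior MI
  40/60 recent (1–14 d)/older, NYHA III/IV 4%, thrombus 5%, ejection
  fraction N(50, 10) with 3% missing. Ages are recorded in completed
  years (the continuous draw is rounded); this matches registry practice
  and keeps the `age ≥ 70` rule exactly representable by midpoint
  thresholds, so grown trees can agree with the fixed rule record-for-
  record rather than only approximately.
* **LOS** is ZTNB with log-mean = log μ_base + log rr(class) + provider
  intercept. Providers (40 by default) get N(0, 0.1²) log-scale
  intercepts. Three calibration modes: `rate_ratio` (explicit μ_base, α),
  `truncated_mean` (per-class target conditional means inverted through
  the truncated-mean function — supported because it is not stated
  whether published "conditional means" are model-based or raw
  averages), and the default `joint`, which solves the two-equation
  system {truncated_mean(μ_base, α) = 3.2, truncated_mean(rr·μ_base, α)
  = 8.7} with rr = 3.20, giving μ_base ≈ 2.634 and α ≈ 0.454. Sampling is
  by rejection of zeros from untruncated NB draws; acceptance probability
  is 1 − P₀, close to 1 at LOS-scale means, which is why the tabulated
  inverse-CDF alternative was not needed.
* **Complications** are Bernoulli per TSPC leaf with default
  probabilities (0.005, 0.015, 0.025, 0.045, 0.08), monotone in risk
  class and realistic for an in-hospital death/stroke/CABG composite
  after elective PCI. The spacing is deliberate: with closer values
  (e.g. low 0.01 vs moderate 0.015) the impurity gains of the age-first
  and renal-first orderings at the no-heart-failure node come within
  ~10% of each other and the greedy grower's split order flips across
  seeds — and only the age-first order can represent the published
  partition — while the sex split falls into the range of
  threshold-optimised noise splits. The chosen values keep every true
  split's gain clearly above both hazards, so planted-tree recovery is a
  property of the method rather than of a lucky seed.
* Acute-MI, shock, unstable and urgent/emergent prevalences default to
  zero (the emulated cohort is already elective); they are configurable,
  and the elective filter is exercised on constructed records in tests.

What passing tests on this generator do **not** show: performance under
correlated covariates (the real registry's joint distribution is
unknown), secular trends across years, non-multiplicative provider
effects, or stratifier comparisons as they fell in the real data — in
the synthetic truth LOS depends only on the TSPC class, so the Wu and
MCRS fits are necessarily weaker there, the reverse of the published
ordering. Parameter-recovery results validate the estimators, not the
registry findings.

## Model comparison and discrimination

The nonnested test is the basic Vuong z on per-record log-likelihood
differences (sample SD, n − 1), two-sided normal p; AIC/BIC dimension
corrections exist but are off by default, and cluster-level aggregation
(summing contributions within provider first) is available and reported
alongside the unclustered test, since the published analysis does not say
which was used. Zero-variance differences are flagged degenerate rather
than dividing by zero.

The c-statistic uses midranks (O(n log n)) with the DeLong
placement-value variance; categorical classifiers enter by ordered
category index, which is sufficient because the AUC is invariant to
strictly increasing recodings. For the IDI, categorical classifiers are
mapped to probabilities by their category event proportions (same-cohort
estimation by default; a train/evaluate split is supported). The IDI SE
combines the within-events and within-non-events variances of the
per-record probability differences; the CI is normal-based. The
"net-integrated discrimination improvement" wording in the source
analysis is treated as the IDI.

## Study pipeline

`run_study` draws independent learning and testing cohorts with identical
parameters (the original temporal split has no synthetic analogue but the
derive-then-validate discipline is kept): cutpoints and the grown tree
come from the learning cohort, all reported fits from the testing cohort.
Default sizes are the published 67,766 / 79,545; `--reduced` uses
20,000/20,000 and completes in a few seconds on one CPU. All randomness
flows from the study seed through named substreams (generation, fold
assignment), outputs carry no timestamps, and repeated runs are
byte-identical. Reports round to the precision conventional for such
tables (rate ratios to 2 dp, AUC to 3 dp).

The acceptance script fits at the published testing scale (n = 79,545)
and checks generator calibration at n = 200,000; the test suite's
heavier simulations use 100–200 replicates at n = 2,000–5,000 and
tree-recovery runs at n = 200,000 over five seeds, sizes chosen to keep
Monte-Carlo error well inside the asserted tolerances.

## Known limitations

* Covariate independence is a simplification; real age/sex/comorbidity
  correlation would change category frequencies (e.g. the moderate TSPC
  share is ~10% here vs 14.4% published) though not the estimators.
* The robust-variance validation plants a cluster-level regressor; for
  within-cluster contrasts the model-based and robust variances nearly
  coincide and the test would be uninformative.
* The cutpoint search assumes the objective is additive over score
  intervals; objectives with cross-category terms would need the
  exhaustive scan.
* Wu cutpoints derived on synthetic learning data differ from the
  published set because the synthetic LOS truth is TSPC-structured; the
  pipeline reports both.
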