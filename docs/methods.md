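# Methods

## The model

mindcpm implements connectome-based predictive modeling (CPM) of trait
mindfulness. The unit of analysis is the *edge*: the Fisher
z-transformed Pearson correlation between the BOLD timeseries of two
atlas nodes, `z_ij = atanh(r_ij)`. For `p` nodes there are
`E = p(p-1)/2` unique edges, stored in a fixed canonical order (0-based
upper triangle, row-major, `i < j`). Everything downstream — masks,
exports, oracles — uses that one ordering.

Training proceeds in three steps inside every cross-validation fold:

1. **Edge screening.** Each edge is correlated with the behavioral
   score across training subjects. Edges pass at a two-tailed
   `p < 0.01` (strict), with p from the exact t transform
   `t = r sqrt((n-2)/(1-r^2))` on `n-2` df rather than a normal
   approximation, so the threshold is reproducible at small n. Passing
   edges with `r > 0` form the positive mask, `r < 0` the negative
   mask; the two masks are disjoint by construction. Zero-variance
   edges are ineligible and counted, not fatal.
2. **Network strength.** For each subject the edge values (the
   subject's Fisher-z values, not the screening r's — the screening-r
   reading would make strength constant across subjects and unable to
   predict) are summed over each mask. The combined strength is the
   positive sum minus the negative sum.
3. **Linear model.** Ordinary least squares of score on strength,
   `score = beta * strength + c`, fitted separately for the combined,
   positive-only and negative-only variants. Held-out prediction uses
   the combined variant by convention; the sign-specific variants are
   always recorded alongside.

Cross-validation is leave-one-out by default; k-fold (default k=10)
assigns subjects by a seeded uniform shuffle into near-equal folds. A
fold whose strength predictor is constant (e.g., both masks empty)
predicts the training mean and is logged. Group-level inference
re-runs the *entire* cross-validation — screening included — on scores
randomly permuted across subjects (default 1000 iterations) and
reports `p = #(null r >= observed r)/n_perm`; the `(count+1)/(n+1)`
variant exists behind a flag but is off by default, matching the plain
counting definition. Models with permutation `p < 0.05` (strict,
uncorrected) are selected for external testing. The exported model is
the *single fold*: screening and fits on all training subjects.

## Evaluation

A frozen model is applied to new data without re-screening: mask, sum,
predict through the stored coefficients, then compare predicted and
observed scores by Pearson r (p via the t transform, df = n-2), mean
squared error, and partial correlations. Partial correlation
residualizes both variables on the covariates (with intercept) by OLS
and correlates the residuals, p on `n-2-q` df. Covariate control (head
motion, clinical status, site means) happens at evaluation, never
inside screening.

Cross-model operations:

- **Strength correlation** — Pearson r between two models' combined
  strengths over pooled subjects.
- **Mask overlap** — shared edges as a percentage of the *sum* of the
  two mask sizes (the only denominator consistent with both worked
  examples used in the tests: 20/(328+664) = 2.02%, 58/(758+628) =
  4.18%). The null shuffles the edges, i.e., draws two uniformly random
  masks of the observed sizes; the shared count is then exactly
  Hypergeometric(E, m_A, m_B) and is sampled directly from that
  distribution instead of materializing masks.
- **Split-half stability** — across-subject correlation of combined
  strength computed from the first half of the runs vs the second half,
  compared with the split correlations of 1000 uniformly sampled single
  edges; `p = P(single-edge r >= strength r)`, one-sided by default
  (a two-sided flag exists).
- **Combined shuffle-split** — pool all sites, shuffle with a seed,
  split 80–20, train (CV + permutation + single-fold) on the 80%, apply
  frozen to the 20%; optional partial correlation with per-site mean
  observed score as the covariate to absorb between-site score offsets.

## Motion QC

Subjects (or, for multi-run data, runs first and then subjects) are
excluded when mean framewise displacement exceeds 0.15 mm; the
comparison is strict (`> 0.15` excludes, 0.15 exactly is retained). In
run-level mode the subject decision defaults to the mean of mean-FD
over *retained* runs — under which subject-level exclusion can only
trigger when no runs survive, since a mean of values each ≤ threshold
cannot exceed it — with the "all runs" alternative available as a
config switch and every exclusion logged with its reason and value.

## The synthetic cohort generator

The generator exists so every stage is testable without restricted
data. It emulates:

- **Sites.** Three sites by default, 200 subjects each, with distinct
  total-score means/SDs (134.8/17.8, 126.8/17.4, 107.2/11.3) matching
  the kind of multi-site heterogeneity seen across a university
  community sample, a student sample and an overseas sample.
- **Facets.** Five questionnaire facets drawn multivariate normal with
  inter-facet correlation 0.4; facet SDs are set so the facet sum
  reproduces the configured total mean/SD. An item-level mode samples
  39 ordinal responses approximately consistent with target facet sums
  for exercising the scoring engine.
- **Signal.** 30 positive and 30 negative planted edges (≈1.2% of the
  default 4950-edge space, the same order as real CPM masks). A planted
  positive edge is `baseline + site shift + sd*(r z(score) +
  sqrt(1-r^2) noise)` with `z` the within-site standardized target
  score and `r = effect_r = 0.3` by default; negative edges flip the
  sign. Using within-site standardization plus per-site edge shifts
  makes the effect portable across sites, which is what frozen-model
  external validation measures. Generation self-checks that the mean
  realized planted-edge correlation is within ±0.1 of the target at
  n ≥ 200. The default effect (0.3) is deliberately stronger than the
  weak per-edge effects implied by real prediction r's near 0.2, to
  keep recovery tests stable; a weak-effect configuration is a matter
  of setting `effect_r` lower.
- **Motion confounds.** Mean FD ~ N(0.12, 0.05) mm, clipped positive.
  With `confound_strength > 0`, FD is coupled to the score
  (`fd_score_corr`, default −0.3) and a separate set of confound edges
  couples to standardized FD, so that naive evaluation r exceeds the
  FD-partialled r — the property that partial correlation is meant to
  remove.
- **Multi-run structure.** Four-run mode decomposes edge noise into a
  stable subject component and run noise with the stable fraction
  `lam = rel/(2-rel)` so a single edge's two-run-average split-half
  correlation equals `edge_reliability` (default 0.4). The planted
  signal is scaled by `sqrt(lam + (1-lam)/n_runs)` so the run-averaged
  edge still correlates with the score at `effect_r`.
  `shared_run_noise` mixes an all-edge common factor into both noise
  components: without coherent signal, summing edges preserves the
  stable:run variance ratio, so aggregate strength is exactly as stable
  as a single edge — the construction behind the negative stability
  result. (At `shared_run_noise = 1` with equal-size masks the combined
  strength cancels identically; the tests use partial sharing and
  unequal masks.)
- **Timeseries mode.** Node-disjoint planted pairs share a latent
  factor per pair, with the subject-level loading set so the expected
  empirical Fisher-z (including estimation noise of variance
  ≈ 1/(T-3)) tracks the score at `effect_r`; null pairs are
  uncorrelated. This exercises the full
  timeseries → connectome → CPM path at reduced power.

What the generator does **not** emulate: temporal autocorrelation of
BOLD, scanner-specific artifacts, atlas geometry, realistic
whole-matrix covariance (null edges are independent), or heavy-tailed
score distributions. Passing tests therefore demonstrate the
correctness and calibration of the procedure, not effect sizes
attainable on real data.

## Numerical choices

- Perfect correlations (|r| ≥ 1 − 1e-12) in connectome construction are
  errors, not clipped values: planted-data bugs should surface.
- Degenerate predictors are detected at variance ≤ 1e-24 (absolute);
  edge screening treats such edges as ineligible, model fitting raises.
- The LOOCV fast path computes all folds at once from leave-one-out
  downdates of the screening sufficient statistics
  (`sum x`, `sum x^2`, `sum xy`, …) and per-fold strengths via one
  mask-by-subject matrix product. It is algebraically identical to the
  explicit per-fold loop (tested for equality to 1e-8) and makes the
  nested permutation scheme (every iteration re-runs the full CV)
  tractable: one 60-subject, 300-edge cohort with 200 permutations
  runs in under a second.
- Fisher-z averaging across runs happens on the stored Fisher-z
  matrices (the representation), not raw r.
- Ties at any p threshold are excluded (strict `<`) everywhere.
- Problem sizes in the test suite: the null-calibration property uses
  200 cohorts of n=60 subjects, E=300 edges and 200-iteration
  permutation nulls; recovery uses 20 two-site cohorts of 200 subjects
  per site over 4950 edges; these sizes give tight Monte-Carlo error on
  the checked proportions while keeping the default suite in the
  minutes range.

## Design choices that were genuinely open

- **Scoring map.** The FFMQ-39 item→facet assignment and reverse-item
  list ship as a packaged, editable YAML (the standard published
  assignment: O 1,6,11,15,20,26,31,36; D 2,7,12R,16R,22R,27,32,37;
  AA 5R,8R,13R,18R,23R,28R,34R,38R; NJ 3R,10R,14R,17R,25R,30R,35R,39R;
  NR 4,9,19,21,24,29,33), validated at load against the structural
  invariants (partition, reverse items present in AA/NJ/D). Scoring
  stays auditable and swappable.
- **Cohen's d** uses the pooled-SD formula
  `d = (m_a - m_b)/s_p`, `s_p^2 = ((n_a-1)s_a^2+(n_b-1)s_b^2)/(n_a+n_b-2)`.
- **Welch df** is reported to 2 decimals from the Welch–Satterthwaite
  formula applied to whatever summaries are given; summaries rounded to
  one decimal can shift the df by ~1 even when t is stable.
- **Overlap null** shuffles both masks; shuffling one against a fixed
  other yields the same hypergeometric null, so the choice is moot and
  the distribution is sampled directly.
- **Node→network labels** are an input file. The packaged
  100-node labelling (`synthetic_network_labels_100.csv`) is a
  synthetic illustration for demos, not a real atlas assignment.

## Known limitations

- No volumetric/NIfTI handling, no FD computation from realignment
  parameters, no denoising: the package consumes node timeseries or
  connectivity matrices.
- No elastic-net, basis-set or tangent-space predictive variants; the
  interchange format accepts any externally trained mask/coefficient
  set for comparison instead.
- The permutation test is CPU-bound for k-fold schemes (no fast path);
  LOOCV is the intended default.
- Item-level synthetic responses approximate target facet sums rather
  than matching them exactly.
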