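# Methods

This note documents the statistical machinery, the synthetic-data design,
the numerical choices, and the known limitations of `riskbn`.

## Study design being modelled

A hospital case-control comparison: three case groups — type 2 diabetes
(T2DM, n = 1163), coronary heart disease (CAD, n = 982) and their
comorbidity (n = 504) — each contrasted against one shared healthy control
group (n = 1175), with 27 variables per subject: six demographic
characteristics, two family-history indicators, nine lifestyle/diet
variables, anthropometry and blood pressure, heart rate, and five fasting
labs.  Each disease is analysed independently on the two-group subset
(cases + controls).

## Screening

* **Categorical variables**: Pearson χ² on the 2×C control-vs-case table,
  no continuity correction.  The no-correction choice is deliberate: on the
  sex table (726/449 vs 635/528) it yields 12.411 where the Yates-corrected
  statistic would give ≈12.12, and 12.411 is the value the source analysis
  reports.
* **Symmetric continuous variables**: Welch's unequal-variance *t*
  (a pooled option exists).  Both flavours agree with the reported age
  statistic within the rounding of the summary inputs; Welch is the default
  because it stays valid under variance heterogeneity between a healthy
  control group and a diseased case group.
* **Skewed labs (FBG, TG)**: Mann–Whitney rank-sum via the tie-corrected
  normal approximation, reported as *Z*.  These two variables are exactly
  the ones summarized as median (P25, P75) rather than mean ± SD.
* Gate: two-sided *P* < α with α = 0.05.  No multiplicity adjustment by
  default (matching the original analysis); Bonferroni and
  Benjamini–Hochberg options are available.
* FBG is excluded outright from any screen against the diabetic outcome:
  it is part of the diagnostic criterion, so its "association" would be
  circular.

## Logistic selection

Binary logistic regression fitted by damped Newton/IRLS; convergence when
max |score| < 1e-8 or the relative log-likelihood change < 1e-10; the
covariance is the inverse observed information.  Separation is flagged at
|β| > 15 or 50 iterations without convergence; rank-deficient designs
raise an error naming a collinear column (via pivoted QR).

Forward stepwise with likelihood-ratio entry/removal ("Forward: LR"):
entry threshold 0.05, removal 0.10 (classic defaults; the method is named
in the source but its thresholds are not).  Categorical predictors enter
and leave as whole reference-coded indicator blocks, tested by a block LR
χ² — which is why the reported tables carry a single χ² line per
categorical variable.  Continuous predictors stay on their raw scale at
this stage (per-unit odds ratios); discretization applies only to the
network stage.  The 95% CI uses z = 1.959964, which reproduces the
published CI bounds to the printed precision.  Ambiguities in the printed
coefficient signs (some β are printed unsigned while OR < 1) are resolved
by always reporting signed β consistent with OR = exp(β).

## Discretization

Continuous variables are mapped to clinical bins before structure
learning.  Bins are half-open intervals [lo, hi) on the next bin's lower
edge, so the real line is covered without gaps: BMI 23.995 falls in the
18.5–23.99 band, 24.0 starts the next.  Heart rate is recorded as integer
beats/min, so the "too fast (> 100)" bin opens at 101 (59 → too slow,
100 → normal, 101 → too fast).  Two printed rules are clinically atypical
— HDL-C flagged abnormal at ≥ 2.3 mmol/L and LDL-C flagged abnormal *below*
1.0 mmol/L — and are implemented exactly as printed, with a YAML config
override for users who want conventional thresholds.  Ages under 18 are
accepted into the lowest band with a warning rather than an error, so
generator edge cases cannot crash the pipeline.  `discretize` is
idempotent: a column whose values already all lie in its bin-code set is
left untouched (raw clinical measurements can never satisfy that).

## Structure learning

Score-based search over DAGs with the decomposable BIC (log marginal
counts likelihood minus (ln N)/2 per free parameter; 0·ln 0 ≡ 0).  The
scoring criterion is not named in the source; BIC is the de-facto default
of score-based tabu implementations, and a likelihood-only option exists.

Tabu search details: start from the whitelist-only graph; neighborhood =
all single-edge additions, deletions and reversals that keep the graph
acyclic and respect the constraints; each iteration takes the best-scoring
move whose inverse is not tabu (aspiration: tabu moves pass if they beat
the best score seen); the inverse move is pushed with tenure 10; stop at
1000 iterations or 50 consecutive non-improving moves; return the best DAG
encountered.  Ties are broken lexicographically by (move type, source,
target), so the search is fully deterministic for fixed data — the seed
only affects the train/test split and data generation.

Expert constraints default to the standard epidemiological encoding:
no edges *into* age, sex, region or family-history nodes (immutable
characteristics cannot be effects).  The constraints actually used in the
original analysis are unstated, so structural output is validated by
recovery tests against declared ground truths rather than by matching the
published figures: on a fixed 8-node truth with all conditional
probabilities in {0.1, 0.9} and n = 10⁴ samples, the learned CPDAG
(skeleton + v-structures + Meek closure, rules R1–R3) matches the truth's
CPDAG in ≥ 18 of 20 seeds, and on three-node instances the search attains
the global optimum found by exhaustively scoring all 25 DAGs.

Split: stratified by group, train fraction 0.7, per-stratum train size
⌊0.7 n⌋, seeded.

## Parameter learning and inference

CPTs are pure maximum likelihood (θ̂ = N_ijk/N_ij) with no smoothing —
exact-zero rows are a documented feature of the source tables.  Unseen
parent configurations receive a uniform row plus a warning so inference
stays defined; a `smooth` pseudo-count option gives strictly positive
tables.

Inference is exact variable elimination with a min-degree elimination
heuristic; networks here are ≤ ~18 nodes, so no junction tree is needed.
It is verified against brute-force joint enumeration (≤ 1e-10) on
randomized small networks, and any elimination order gives identical
posteriors.  Zero-probability evidence raises an error at the API level
(surfacing MLE sparsity) — except in the hold-out evaluation loop, where a
test record whose configuration the training data assigns zero mass falls
back to the disease prior and is counted in the report
(`impossible_evidence_fallbacks`).

Classification threshold: 0.5 (the source's cut-off for its confusion
matrix is unstated; the threshold is exposed, and the ROC makes results
threshold-transparent).  Records with absent values are scored by
marginalization, no imputation.

## Sensitivity

Variance reduction with the binary target valued {0, 1}:
100·(V − Σ_f P(f)·V_f)/V with V = p(1−p).  For a binary finding this
equals 100·corr²(target, finding) under the network joint, which the tests
exploit as a cross-check.  Mutual information ("entropy reduction", bits)
is available as a secondary column.  Rankings break ties by name.

## Synthetic cohort generator

Marginal-matching mode emulates the published cohort description: exact
group sizes (1175/1163/982/504), categorical draws from each group's
published marginal, continuous draws from normals truncated at 0 with the
published mean/SD, and log-normal draws for FBG and TG with μ = ln(median)
and σ = ln(P75/P25)/(2·z₀.₇₅) so the published quantiles are preserved.
Randomness comes from one master seed with fixed per-group/per-variable
substreams, so adding a variable does not perturb the others.

Corrections to the published summary table (all overridable via
`reference_profiles(overrides=...)`):

* comorbidity heart rate "6.55 ± 11.64" → 76.55 (physiologic
  plausibility);
* T2DM FBG upper quartile "1.40" → 11.40 (must exceed the median 7.80);
* truncated quartile digits restored: control TG P75 ".72" → 1.72, T2DM TG
  "(1.00, .21)" → 2.21, CAD TG ".81" → 1.81, comorbidity TG ".02" → 2.02,
  comorbidity FBG ".73" → 9.73 (single leading digit restored keeping
  P25 < median < P75);
* control staple-food count 626 → 622 and central-obesity count 897 → 894
  (the printed counts contradict both the group size and the printed
  percentages; the percentages are trusted).

**What this generator does not emulate**: within a group, variables are
drawn independently — all dependence between risk factors enters through
group membership only, because the published description provides
marginals, not joints.  Consequences: (i) end-to-end structure learning on
marginal-matching cohorts produces disease-centred graphs rather than the
richer factor-to-factor topology a real cohort yields, so learned
structures are validated in forward-sampling (recovery) mode instead;
(ii) hold-out discrimination is *easier* than on real data — the strongly
separated group marginals (e.g. mean age 40.8 vs 60.0) yield synthetic
AUCs near 0.99, a qualitative analogue of, not a match to, the reported
0.84–0.86.  Passing the end-to-end test therefore shows the pipeline is
wired correctly and discriminates when signal exists, not that real-data
performance is reproduced.

Forward-sampling mode draws records ancestrally from a declared
DAG + CPT ground truth and underpins all recovery tests.

## Problem sizes used in tests and the acceptance script

Worked-example checks run directly on published-table inputs (instant).
Recovery and calibration use: n = 10⁴ × 20 seeds (structure), n = 5·10⁴
(CPT recovery), 200 replicates of n = 5000 (logistic coefficients), 1000
null replicates at n = 200/arm (test calibration), and the full 3824-row
cohort for the three end-to-end replications.  These sizes keep the whole
suite and the acceptance script each under a minute or two on one CPU
while leaving Monte-Carlo noise well below the asserted tolerances.

## Known limitations

* No missing-data handling at the learning stage (the source used complete
  data only); incomplete records are supported at inference time only.
* No Markov-equivalence averaging or bootstrap confidence on edges: one
  DAG is reported, and undirected-equivalent orientations are possible.
* Hanley–McNeil AUC intervals are approximate for small test sets; a
  seeded bootstrap alternative is provided.
* The published figures' exact networks, worked posteriors (57.6%, 65.8%,
  …) and sensitivity magnitudes depend on the unavailable hospital data
  and are treated as qualitative direction checks on synthetic
  replications, not as numeric targets.
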