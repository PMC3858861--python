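# Methods

## The statistical model

Each probe's normalized log2 expression is modeled as

    y_ij = mu + T_i + S_j + e_ij

with a fixed two-level group effect `T_i` (case/control), a random sample
effect `S_j ~ N(0, sigma1^2)`, and residual noise `e_ij ~ N(0, sigma^2)`.
With a single observation per sample and probe, `S_j` is unidentifiable
from `e_ij`, so the per-probe test is the one-way fixed-effect ANOVA of the
group effect — for two groups exactly the squared pooled t test — and the
fit reports `sigma1^2 = 0`. The `AnovaFit` type keeps the slot so a
multi-observation design could populate it without an API break.

Group effects are reported under the unweighted sum-to-zero constraint
(`mu` is the mean of the two group means), so they sum to zero exactly even
in unbalanced designs. Probes with identical values in both groups get
F = 0, p = 1 rather than NaN; probes with zero within-group variance but
different group means get p = 0.

## Multiplicity control

Three quantities per probe: the raw p-value, the Benjamini–Hochberg
step-up adjusted p-value (via statsmodels), and the Storey–Tibshirani
q-value

    q_(i) = min_{j>=i} pi0 * m * p_(j) / j

on the ascending-sorted p-values, capped at 1. `pi0` is estimated from
`pi0(lambda) = #{p > lambda} / (m (1 - lambda))` on the grid
lambda = 0, 0.05, ..., 0.90, smoothed with a least-squares cubic
polynomial evaluated at lambda = 0.90. The cubic is a 4-parameter smoother
playing the same role as a df=3 smoothing spline, with no tuning
parameter and deterministic output. Guard rails: `pi0` falls back to 1
(with a warning) when fewer than 100 p-values are supplied or when the
smoothed estimate leaves (0, 1]; with `pi0 = 1` the q-values equal the BH
adjustment exactly, which the test suite asserts elementwise.

Markers are screened with a strict `q < q_threshold` filter (default
0.01), ordered by ascending q, then p, then probe id for determinism, and
optionally capped at the `max_markers` best-ranked probes (default 100 —
beyond that an exhaustive 5-panel search stops being tractable, and probes
ranked past 100 rarely add diagnostic value).

## Splitting protocol

One stratified random split divides the cohort into training group A
(fraction 0.5 by default) and testing group B; each class contributes
round(fraction * n_class) samples to A (round half up), which reproduces
the 34/32 + 33/31 allocation of a 67-case/63-control cohort. Group-A
samples are dealt into k = 5 folds class by class; a greedy allocation
gives every fold class counts within one of each other and total sizes
within one overall. Both assignments are pure functions of
(sample ids, labels, seed, fraction, k) and serialize to a two-column
text table for audit and replay.

## Panel search

All C(M, N) combinations of the M screened markers are enumerated in
lexicographic order (hard error above a configurable cap, default 1e8).
Every combination is scored with the same fold assignment: features are
standardized on the training folds (zero-variance features pass through
centered but unscaled), an RBF-kernel C-SVC is fit on the training folds,
and held-out decision values give a fold AUC. The validation AUC is the
unweighted mean of the k fold AUCs (a pooled-decision-value variant is
available via `aggregation="pooled"`). Ties are broken by the higher
minimum fold AUC, then by the lexicographically smallest panel, and all
candidates tied with the last returned rank are reported.

Hyperparameters default to C = 1 and gamma = 1 / (N * var), i.e. 1/N
after standardization — the scale-free default used across kernel
methods; the pipeline deliberately fits a single model per combination
rather than tuning per panel, so AUC differences reflect panels, not
hyperparameter luck. AUC is the Mann–Whitney statistic (ties counted
half), identical to the trapezoidal ROC area; the search loop uses a
rank-based implementation of the same statistic, asserted equal to the
public ROC-based one to 1e-12. SVM fits go through scikit-learn's
low-level libsvm binding (bit-identical decision values to
`SVC.decision_function`, asserted by the test suite, with a fallback to
the public estimator), which removes estimator overhead that would
otherwise dominate at ~50-sample fold sizes.

The final model is refit on all of group A with scaling learned there,
serializes to JSON (the raw training block plus hyperparameters) and
reloads to a bit-identical decision function. Hard labels use the
score > 0 threshold; a Youden-optimal threshold is deliberately not the
default so confusion matrices stay comparable across runs.

## Leakage discipline

Marker screening and panel search receive a view holding only group-A
columns; per-probe centering medians are learned on group A and applied
to group B at evaluation time. This is the one deliberate deviation from
normalizing the whole matrix before splitting: centering learned on all
samples would let testing data leak into training-stage statistics. The
choice is numerically inert for the pipeline itself — a per-probe location
shift changes neither F statistics nor fold-standardized SVM features —
and it makes the poisoning audit hold exactly: overwriting every group-B
value with NaN changes neither the differential-expression table nor the
panel ranking, bit for bit (a permanent test).

## Synthetic data

The generator emulates a two-class peripheral-blood microarray study:
n_cases = 67 / n_controls = 63 by default, 2,000 probes (a study-scale
array shrunk ~16x so exhaustive searches run in minutes on one CPU),
Gaussian log2-scale noise (residual SD 1.0 around a baseline of 8.0), and
a planted panel (default 5 probes) shifted by `effect_size` residual SDs
in cases. Planted probes share a per-sample latent factor with weight
sqrt(rho), rho = 0.2 by default — a modest co-regulation level chosen
once as typical for a functionally related marker set; marginal variance
is preserved. The generator does not model probe-level artifacts (dye
bias, spatial effects, batch), heavy-tailed noise, or class imbalance
beyond the configured counts, so passing tests demonstrate correctness of
the machinery under the assumed Gaussian model, not robustness to real
microarray pathology.

## Operating characteristics on simulated data

Two results from the seeded simulation suite are worth stating plainly,
because they characterize the method rather than the code:

- **Null calibration holds.** On effect-free data the q < 0.01 screen
  passes ~0% of 2,000 probes (10 replicates), and the full pipeline —
  relaxed to search over its 10 best-looking null probes so the search
  stage actually runs — yields testing-group AUCs within [0.41, 0.59]
  over 20 seeds. The machinery manufactures no signal.
- **The within-training-group argmax overfits marker luck.** With a
  5-probe panel planted at 2 SD among 15 null markers (n_A = 66, k = 5),
  the rank-1 panel contains on average ~2.6 of the 5 planted probes:
  null probes carry chance group-A separation (~0.25–0.45 SD) that
  cross-validation inside group A validates, and the fold-mean AUC
  objective saturates at 1.0 (fold granularity 1/42), leaving large tie
  sets. The winner's CV AUC is never below the pure planted panel's — the
  argmax is correct — while the pure panel is reliably better on group B,
  the signature of wrapper-selection overfitting at this sample size.
  Optimizer-chosen panels still beat randomly drawn marker panels on mean
  CV AUC in 10/10 seeded runs, and the discovered panels average ~0.94
  testing-group AUC. These numbers are recomputed, not asserted, by
  `scripts/acceptance.py`.

## Numerical choices

- Medians use midpoint interpolation for even counts; both median
  normalizations are idempotent (property-tested).
- Nonpositive values before log2: hard error by default; optional floor
  at 2^-20.
- Missing cells at ingestion: hard error by default; optional row-drop
  policy. In-memory matrices may carry non-finite sentinels (the leakage
  audit depends on it); ingestion always enforces finiteness.
- Matrix values are written with 17 significant digits so text round
  trips are exact; the final model forces a C-contiguous training block
  so a reloaded model reproduces decision values bit for bit.
- Candidate scoring is order- and worker-count-independent; an
  append-only checkpoint file allows resuming interrupted searches with
  identical output.

## Known limitations

- Exhaustive search cost grows as C(M, N); with the default cap the
  practical limit is on the order of 1e8 combinations (M near 100 for
  N = 5), consistent with the marker cap.
- No per-panel hyperparameter tuning, confidence intervals on AUC, or
  multi-class support.
- The q-value smoother is a global cubic rather than a spline with
  chosen knots; for very non-uniform p-value histograms the two can
  differ slightly, with the clamp to (0, 1] bounding the damage.
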