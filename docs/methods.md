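# Methods

This note documents the modeling choices in `dynograph`: the data model,
the procedures each module implements, the defaults and why they were
chosen, what the synthetic generator does and does not emulate, and the
numerical details a user reproducing results should know.

## Panel model and targets

Time is the integer visit index t ∈ {0, …, T−1} (default T = 5, annual
visits). A panel has at most one row per (subject, visit). Two target
constructions are provided:

* **Continuous.** The lag y_{t−1} and change score Δy_t = y_t − y_{t−1}
  are defined only when visit t−1 was itself observed; across an
  observation gap both are flagged invalid rather than computed over the
  gap, because the definitions are tied to consecutive indices.
* **Discrete-time event.** Per-period labels are 1 once an event subject's
  event time has passed (δ=1, T_i ≤ t), 0 while any subject is still at
  risk (T_i > t), and missing from a censored subject's end of follow-up
  onward. At equality (δ=0, t = T_i) the still-at-risk branch fails and
  the cell is missing — censoring at a visit yields no label for that
  visit. Post-event cells keep the label 1 by default; the classical
  person-period convention of dropping post-event rows is available via
  `drop_post_event` since the literature uses both.

Sequences are padded to fixed length with an observation mask m_{i,t};
padded feature cells hold 0, the post-standardization mean, so they are
neutral under any masked computation (and the mask-gated recurrence makes
them unreachable anyway, see below).

## Preprocessing

Order: median imputation → standardization → covariate residualization.
All three are fitted on training subjects only and applied to held-out
rows with the stored statistics; pooling across time points is the default
(the alternative of per-visit fitting halves the effective n per statistic
and is rarely warranted at these cohort sizes). Standardization uses the
population SD (divisor n); zero-variance features are dropped with a
warning rather than silently producing NaN. Residualization appends an
intercept column, one-hot encodes categorical covariates with a dropped
reference level, verifies full column rank (naming collinear columns on
failure), and solves least squares by QR — mathematically equivalent to
the projection X − C(CᵀC)⁻¹CᵀX but without forming the inverse.

## Graph construction

Features map to domain nodes by their `<domain>__` name prefix; node
summaries are the unweighted mean of each node's standardized features
(a first principal component would be sign-ambiguous across refits).
The default adjacency is |Pearson r| between node summaries across
training rows, zeroed below τ = 0.1, unit self-loops, symmetrized, then
row-normalized to sum 1. Row normalization makes one message-passing step
x_graph = A x a weighted averaging operator: every entry of Ax lies in
[min x, max x]. `identity` and `full` (uniform) baselines are available. A is a single
static matrix by default; a per-visit variant (one adjacency per time
index, fitted from that visit's training rows) exists for analyses that
allow edge strength to drift, but learned or directed edge dynamics are
out of scope.

Note a subtlety that matters for energy summaries: row normalization does
**not** guarantee that mean-square energy is non-increasing under message
passing. Jensen's inequality bounds each coordinate,
(Ax)_j² ≤ Σ_k a_jk x_k², but summing over j weights x_k² by the *column*
sums of A, which row normalization leaves unconstrained; random
row-stochastic matrices violate E(Ax) ≤ E(x) in a small fraction of draws.
The contraction does hold exactly for doubly stochastic A, and the
entrywise convexity bound always holds; the test suite asserts exactly
these true statements (one intentionally failing test records the false
general claim).

## Temporal models

Both architectures are implemented in numpy with hand-written
backpropagation through time and Adam, verified against central finite
differences (agreement to ~1e-10 relative) in the test suite.

* `graph_lstm` — standard LSTM (forget-gate bias initialized to 1, Glorot
  uniform weights) over raw feature sequences, with a linear or logistic
  scalar head applied to every hidden state.
* `graph_gtrnn` — GRU over node-summary sequences whose step-t input is
  A x_t. With A = I it reduces bitwise to a plain GRU, which is tested.

**Mask gating.** At an unobserved visit the hidden (and cell) state is
carried forward unchanged: h_t = m_t ⊙ h_new + (1 − m_t) ⊙ h_{t−1}. This
makes masking exact rather than approximate — values stored at padded
positions cannot influence any prediction, loss, or metric, which the
suite verifies by writing garbage into masked cells.

**Losses.** Masked MSE for continuous heads; masked binary cross-entropy
on logits (numerically stable softplus form) for event heads, computed
only at cells that are both observed and labeled — censored discrete-time
cells are excluded by construction. No class re-weighting by default; a
`pos_weight` option exists.

**Optimization defaults.** Hidden width 32, learning rate 1e-3, batch
size 64, at most 200 epochs, early stopping on validation loss with
patience 10 and best-epoch weight restoration. These are conventional
small-tabular-sequence settings; nothing in the method depends on them
finely, and all are configurable. Training is deterministic given the
config seed (single-threaded numpy).

## Evaluation

Continuous: RMSE, MAE, R² = 1 − SS_res/SS_tot, Pearson r. Binary: AUROC
(Mann–Whitney convention, ties count ½), AUPRC in the average-precision
step convention — trapezoidal interpolation is avoided because it is
optimistic for rare events — and the Brier score. Binary metrics are
computed over all valid subject-period cells by default (a per-subject
mode exists). Undefined cases (constant truth for r, single-class truth
for AUROC/AUPRC) return NaN with a warning instead of raising, so
multi-seed sweeps survive degenerate splits. The implementations are
scikit-learn/scipy calls behind this module's interface; the test suite
checks them against independent brute-force oracles (all-pairs counting
for AUROC, step-sum for AUPRC, textbook formulas for regression).

## System energy and collapse states

E_t is the mean squared entry of a subject's state vector at visit t; N in
the formula is the vector's length. The default state vector is the
trained graph-GRU's hidden state h_t, with the node-summary vector x_t as
an alternative; for hidden states (whose width differs from the node
count) graph-propagated energy is reported as the plain energy since
message passing is defined on the node dimension. ΔE_t is the difference
between consecutive *observed* visits, undefined at the first. The
collapse detector flags visits where ΔE_t strictly exceeds μ_ΔE + σ_ΔE of
a reference population of energy changes; the default reference pools all
subjects' ΔE values at the cohort level so flags are comparable across
subjects (a per-subject reference exists). For standard-normal energy
changes self-referencing flags ≈ P(Z > 1) ≈ 15.9 % of visits, which the
suite checks by Monte Carlo.

Group contrasts average, per group, each member's time-mean energy, energy
at the last observed visit, and mean ΔE, and report high-minus-comparison
differences. For continuous outcomes the high-symptom group is the top
quartile of the last observed outcome (configurable — a quartile split
matches typical high/low symptom-group proportions in cohort analyses);
for event outcomes the groups are event versus no-event subjects.

## Synthetic cohort generator

The generator defines the study conditions for every test and for
`scripts/acceptance.py`; its defaults are fixed, not tuned per experiment.

* **Latent dynamics.** Each of the 11 domain nodes carries an AR(1) state
  z_t = φ z_{t−1} + ε_t (φ = 0.6), started from the innovation
  distribution rather than the stationary law, so latent variance grows
  toward its stationary level over follow-up. A high-risk subgroup
  (25 % of subjects) has innovation SD multiplied by `volatility_ratio`;
  because variance accrues over time, an inflated ratio yields both higher
  energy and a more positive energy trend — the planted dysregulation
  signal.
* **Features.** 5 features per node, loading ~ U(0.7, 1.3) on the node
  state plus N(0, 0.5²) measurement noise; 10 % of feature cells are MCAR
  missing.
* **Continuous outcome.** y_t = u_t + v_t where u_t = κu_{t−1} + wᵀz_t
  over 4 signal nodes (κ = 0.3) and v_t is the same recursion driven by
  unit Gaussian noise, scaled so var(u)/var(y) equals the requested
  generative R² exactly on the realized cohort (both components are linear
  in their innovations, so a single scale factor calibrates it).
* **Events.** Per-period hazard σ(c + 1.5·w_hᵀz_t) at visits 1…last
  observed; the intercept c is found by bisection on pre-drawn uniforms,
  making calibration to any feasible target prevalence exact up to cohort
  granularity and fully deterministic. Censored subjects (15 %) drop out
  uniformly between visit 0 and T−2; a subject seen only at baseline can
  never contribute an event, so extreme prevalence targets under heavy
  censoring are genuinely infeasible and raise a calibration error.
* **Covariates.** Sex (Bernoulli ½), baseline age 9–10 incrementing by 1
  per visit, 10 standard-normal PC-like columns, 4 sites.

What it does *not* emulate: real marginal distributions, linkage
disequilibrium or imaging covariance structure, informative missingness,
measurement invariance drift. Tests passing on this generator demonstrate
that the pipeline recovers structure it is designed for; they say nothing
about effect sizes in any real cohort.

## Splits and reproducibility

Splits are by subject, never by row. Sizes follow the nested held-out
convention — test takes ⌈n·f_test⌉, then validation ⌈n·f_val⌉, training
the remainder — the arithmetic of two nested train/test splits, which at
2,620 subjects and 64/16/20 gives 1,676/420/524. One global seed expands
to stage-specific seeds by fixed offsets so stages are independently
reproducible; rerunning a pipeline config byte-reproduces the metric CSVs.

## Problem sizes used in checks

The recovery experiments run at desk scale, chosen for estimator
stability: n = 1,000 subjects for continuous-signal recovery (generative
R² 0.5; the masked LSTM reaches test R² ≈ 0.42–0.48), n = 600 for the
volatility contrast, and n = 2,000 for the rare-event experiment at 5 %
prevalence — at a 20 % test split this leaves ~20 event subjects, the
minimum at which even a ground-truth oracle's AUROC is stable across
cohort realizations. The graph-GRU is the architecture used for the
rare-event check: its 11-dimensional node-summary input resists the
overfitting that the 55-feature LSTM shows when only ~60 positive training
subjects exist, consistent with the broader observation that
graph-recurrent models hold up better on sparse event outcomes.

## Known limitations

* Energy values are model-derived latent summaries; their scale depends on
  hidden width and training, so only within-cohort contrasts are
  meaningful.
* The adjacency is static and correlation-based; directed, lagged, or
  learned edges are out of scope.
* Calendar-time irregularity is not modeled; time is the visit index.
* No hyperparameter search utilities; the defaults above are the supported
  configuration surface.
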