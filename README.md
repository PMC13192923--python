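# dynograph

Graph-based temporal modeling of longitudinal multi-domain cohort panels.

Developmental and epidemiological cohorts (genetics, environment, brain,
behavior) are usually analyzed predictor-by-predictor or with static
summaries. `dynograph` instead treats each subject as a small dynamic
system: domain-level nodes whose states evolve over discrete visits,
connected by a data-driven adjacency matrix. The package turns long-format
panel data into masked sequences, trains recurrent temporal models for
continuous symptom trajectories and rare initiation events, and summarizes
each subject's latent dynamics with system-energy statistics that can be
contrasted between risk groups. It is aimed at biostatisticians and
computational psychiatry / epidemiology researchers working with panel
designs of a few thousand subjects and a handful of annual visits.

## The model

**Panel and targets.** Visits are integer time indices t ∈ {0, …, T}. For a
continuous outcome y_{i,t} the temporal features are the lag y_{i,t−1} and
the change score Δy_{i,t} = y_{i,t} − y_{i,t−1}, defined only over
consecutive observed visits. A time-to-event outcome (event time T_i,
indicator δ_i) is coded as a discrete-time survival sequence

    y_{i,t} = 1   if δ_i = 1 and T_i ≤ t
            = 0   if T_i > t
            = missing otherwise  (censored at or before t)

so a longitudinal classifier models the per-period hazard.

**Preprocessing.** Median imputation, standardization
x′ = (x − μ_x)/σ_x, and covariate residualization
X_res = X − C(CᵀC)⁻¹CᵀX (sex, age, genetic PCs, site; solved by QR), all
fitted on training subjects only.

**Graph.** Features map to N domain nodes by name prefix; each node's state
is the mean of its standardized features. Edges are the thresholded
absolute Pearson correlations between node summaries on training rows, with
unit self-loops, row-normalized. One message-passing step is
x_graph,t = A x_t.

**Temporal models.** Two architectures, both with mask-gated recurrence
(an unobserved visit leaves the hidden state untouched and contributes
nothing to any loss or metric):

* `graph_lstm`: h_t = LSTM(h_{t−1}, x_t) on the raw feature sequence,
  ŷ_t = f(h_t) with a linear head (MSE loss) or logistic head
  (cross-entropy).
* `graph_gtrnn`: a GRU whose input at each step is the message-passed node
  vector A x_t.

Training uses minibatch Adam with validation-based early stopping; the
recurrent cells, backpropagation through time, and the optimizer are
implemented directly in numpy and gradient-checked against finite
differences in the test suite.

**System energy.** For a state vector x_t (node summaries or the trained
model's hidden state h_t), E_t = (1/N) Σ_j x_{j,t}², and
E_graph,t is the same after one message-passing step. The energy change
ΔE_t = E_t − E_{t−1} feeds a collapse-like-state detector:
collapse_t = 1 iff ΔE_t > μ_ΔE + σ_ΔE of a reference population of energy
changes. Group contrasts report mean energy, final energy, and mean energy
change for a high-risk group versus its comparison group.

A synthetic-cohort generator (`dynograph.cohort`) produces panels with this
exact structure — AR(1) latent node states, planted linear outcome signal
with a chosen generative R², logistic per-period hazards calibrated by
bisection to a target prevalence, censoring-driven dropout, MCAR feature
holes, and a high-volatility subgroup — so every stage is testable without
access-restricted cohort data.

## Worked example

```python
import pandas as pd
from dynograph.pipeline import RunConfig, run_pipeline

cfg = RunConfig(
    out_dir="demo_run",
    simulate={"n_subjects": 400, "seed": 7},
    outcomes=[{"name": "symptoms", "task": "continuous", "column": "y"}],
    seeds=(0, 1, 2),
)
out = run_pipeline(cfg)
m = pd.read_csv(out / "metrics.csv")
print(m.groupby("model")[["r2", "rmse", "pearson_r"]].agg(["mean", "std"]).round(3))
```

prints

```
                r2          rmse        pearson_r
              mean    std   mean    std      mean    std
model
graph_gtrnn  0.416  0.004  1.609  0.005     0.648  0.003
graph_lstm   0.356  0.014  1.690  0.018     0.598  0.011
```

Both models recover most of the planted signal (the generator's default
effect size puts the ceiling at a generative R² of 0.5); the across-seed SD
shows run-to-run stability. The run directory also contains per-seed energy
traces and `group_summary.csv` with the high-symptom (top quartile of the
last observed outcome) versus lower-symptom contrast:

```
 seed  n_high  n_comparison  diff_mean_energy  diff_final_energy  diff_mean_delta
    0      20            60            0.0035             0.0128           0.0042
    1      20            60            0.0093             0.0243           0.0070
    2      20            60            0.0076             0.0168           0.0046
```

Positive differences mean the high-symptom group carries more latent
hidden-state energy, ends follow-up at higher energy, and accumulates
energy faster.

The same pipeline is available from the shell:

```bash
dynograph simulate --out panel.parquet --n-subjects 400 --seed 7
dynograph train --panel panel.parquet --arch graph_gtrnn --outcome y \
    --task continuous --seeds 3 --out demo_run
dynograph evaluate --run-dir demo_run
dynograph energy   --run-dir demo_run
```

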