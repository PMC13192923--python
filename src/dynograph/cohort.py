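"""Synthetic longitudinal cohort generator.

Emulates the statistical structure of a multi-domain developmental panel:
~thousands of subjects followed over up to five annual visits, tens of
features grouped into domain-level nodes, continuous symptom trajectories
driven by latent autoregressive node states, and rare binary initiation
events generated from a per-period logistic hazard.  A planted "high-risk"
subgroup carries inflated latent-state volatility so that downstream
system-energy contrasts have a known ground truth.

The generator is fully deterministic given a seed: identical
``CohortSpec`` values produce byte-identical panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_NODE_NAMES",
    "CohortSpec",
    "GroundTruth",
    "CalibrationError",
    "generate_cohort",
    "planted_truth",
]

#: Eleven domain-level nodes of the default system graph.
DEFAULT_NODE_NAMES: tuple[str, ...] = (
    "genetics",
    "environment",
    "family",
    "school",
    "peer",
    "physical_health",
    "technology",
    "neurocognition",
    "brain_structure",
    "brain_function",
    "behavior",
)


class CalibrationError(ValueError):
    """Raised when the hazard intercept cannot be calibrated to the target rate."""


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic cohort.

    Parameters
    ----------
    n_subjects:
        Number of subjects in the cohort.
    n_timepoints:
        Number of integer-indexed visits t = 0..n_timepoints-1 (>= 2).
    n_nodes:
        Number of domain-level nodes (default 11).
    features_per_node:
        Observed features loading on each latent node state.
    continuous_effect_size:
        Fraction of continuous-outcome variance explained by the planted
        latent-state signal (the generative R-squared), in [0, 1].
    ar_coefficient:
        AR(1) coefficient of the latent node states, in [0, 1).
    event_rate:
        Target marginal prevalence of the binary initiation event, in [0, 1].
    censor_rate:
        Fraction of subjects whose follow-up ends before the final visit.
    volatility_ratio:
        Multiplier on latent-state innovation SD for the high-risk subgroup.
    high_risk_fraction:
        Fraction of subjects in the planted high-risk subgroup.
    feature_noise_sd:
        SD of measurement noise added on top of node loadings.
    outcome_lag_coefficient:
        Autoregressive carry-over of the continuous outcome between visits.
    n_signal_nodes:
        Number of leading nodes whose states carry outcome/hazard signal.
    hazard_scale:
        Scale of the latent-state effect on the per-period logit hazard.
    cell_missing_rate:
        Missing-completely-at-random rate applied per feature cell.
    visit_missing_rate:
        MCAR rate of whole-visit dropout for visits after baseline.
    n_pcs:
        Number of principal-component-like covariate columns.
    n_sites:
        Number of site factor levels.
    baseline_age:
        Age at t=0; age increases by one per time index.
    seed:
        RNG seed; identical spec + seed gives byte-identical output.
    """

    n_subjects: int
    n_timepoints: int = 5
    n_nodes: int = 11
    features_per_node: int = 5
    continuous_effect_size: float = 0.5
    ar_coefficient: float = 0.6
    event_rate: float = 0.05
    censor_rate: float = 0.15
    volatility_ratio: float = 1.0
    high_risk_fraction: float = 0.25
    feature_noise_sd: float = 0.5
    outcome_lag_coefficient: float = 0.3
    n_signal_nodes: int = 4
    hazard_scale: float = 1.5
    cell_missing_rate: float = 0.10
    visit_missing_rate: float = 0.0
    n_pcs: int = 10
    n_sites: int = 4
    baseline_age: float = 9.0
    node_names: Sequence[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be >= 2")
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        if not 0.0 <= self.event_rate <= 1.0:
            raise ValueError("event_rate must be in [0, 1]")
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise ValueError("ar_coefficient must be in [0, 1)")
        if not 0.0 <= self.continuous_effect_size <= 1.0:
            raise ValueError("continuous_effect_size must be in [0, 1]")
        if self.n_signal_nodes > self.n_nodes:
            raise ValueError("n_signal_nodes cannot exceed n_nodes")
        names = self.node_names
        if names is not None and len(names) != self.n_nodes:
            raise ValueError("node_names length must equal n_nodes")

    @property
    def resolved_node_names(self) -> tuple[str, ...]:
        if self.node_names is not None:
            return tuple(self.node_names)
        if self.n_nodes <= len(DEFAULT_NODE_NAMES):
            return DEFAULT_NODE_NAMES[: self.n_nodes]
        extra = tuple(
            f"node{k:02d}" for k in range(len(DEFAULT_NODE_NAMES), self.n_nodes)
        )
        return DEFAULT_NODE_NAMES + extra


@dataclass(frozen=True)
class GroundTruth:
    """Generative parameters planted in a synthetic cohort.

    ``effect_vector`` holds the weights on the signal-bearing node states in
    the continuous outcome (all zeros when ``continuous_effect_size`` is 0);
    ``hazard_coefficients`` the weights in the per-period logit hazard;
    ``generative_r2`` the fraction of outcome variance carried by the
    latent-state signal, as calibrated on this cohort.
    """

    node_names: tuple[str, ...]
    signal_nodes: tuple[str, ...]
    effect_vector: np.ndarray
    outcome_lag_coefficient: float
    hazard_coefficients: np.ndarray
    hazard_intercept: float
    generative_r2: float
    ar_coefficient: float
    loadings: np.ndarray  # (n_nodes, features_per_node)
    subject_ids: tuple[str, ...]
    high_risk: np.ndarray  # bool per subject
    event_time: np.ndarray  # int per subject (event or censor time)
    event_indicator: np.ndarray  # 0/1 per subject
    noise_sd: float = field(default=float("nan"))


def _subject_ids(n: int) -> list[str]:
    return [f"S{i:05d}" for i in range(n)]


def _simulate_latents(spec: CohortSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """AR(1) latent node states, started from the innovation distribution.

    States start at t=0 from the innovation noise (not the stationary law),
    so latent variance grows toward its stationary level over follow-up —
    the high-volatility subgroup accumulates energy faster, giving the
    planted dysregulation signal a positive mean energy change.
    """
    n, T, N = spec.n_subjects, spec.n_timepoints, spec.n_nodes
    n_high = int(round(spec.high_risk_fraction * n))
    order = rng.permutation(n)
    high_risk = np.zeros(n, dtype=bool)
    high_risk[order[:n_high]] = True
    scale = np.where(high_risk, spec.volatility_ratio, 1.0)[:, None]

    z = np.empty((n, T, N))
    eps = rng.standard_normal((n, T, N))
    z[:, 0, :] = scale * eps[:, 0, :]
    for t in range(1, T):
        z[:, t, :] = spec.ar_coefficient * z[:, t - 1, :] + scale * eps[:, t, :]
    return z, high_risk


def _continuous_outcome(
    spec: CohortSpec, z: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Outcome = latent signal component + AR-carried noise component.

    The signal component u follows u_t = kappa*u_{t-1} + w'z_t over the
    signal nodes; the noise component v follows the same recursion driven by
    unit Gaussian innovations.  Scaling v so that var(u)/(var(u)+var(v))
    equals the target effect size makes the generative R-squared exact on
    the realized cohort.
    """
    n, T = spec.n_subjects, spec.n_timepoints
    k = spec.n_signal_nodes
    kappa = spec.outcome_lag_coefficient
    w = rng.uniform(0.8, 1.2, size=k) / np.sqrt(k)
    e = rng.standard_normal((n, T))

    r2 = spec.continuous_effect_size
    if r2 == 0.0:
        w = np.zeros(k)

    g = z[:, :, :k] @ w
    u = np.empty((n, T))
    v = np.empty((n, T))
    u[:, 0] = g[:, 0]
    v[:, 0] = e[:, 0]
    for t in range(1, T):
        u[:, t] = kappa * u[:, t - 1] + g[:, t]
        v[:, t] = kappa * v[:, t - 1] + e[:, t]

    var_u = float(np.var(u))
    var_v = float(np.var(v))
    if r2 == 0.0:
        sd = 1.0
    elif r2 == 1.0:
        sd = 0.0
    else:
        sd = float(np.sqrt(var_u * (1.0 - r2) / (r2 * var_v)))
    y = u + sd * v
    return y, w, sd, r2


def _censor_times(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Last observed visit per subject; censored subjects drop out early."""
    n, T = spec.n_subjects, spec.n_timepoints
    last = np.full(n, T - 1, dtype=int)
    censored = rng.random(n) < spec.censor_rate
    # dropout visit uniform over 0..T-2: some subjects are seen only at
    # baseline, so they can never contribute an event
    last[censored] = rng.integers(0, T - 1, size=censored.sum())
    return last


def _calibrate_events(
    spec: CohortSpec,
    eta: np.ndarray,
    last_visit: np.ndarray,
    rng: np.random.Generator,
    tol: float = 1e-4,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Bisection on the logistic hazard intercept to hit the target prevalence.

    Per-period uniforms are drawn once, so prevalence is a monotone step
    function of the intercept and bisection is exact up to the Monte-Carlo
    granularity of the cohort.
    """
    n, T = eta.shape
    u = rng.random((n, T))

    def realize(c: float) -> tuple[np.ndarray, np.ndarray]:
        with np.errstate(over="ignore"):
            p = 1.0 / (1.0 + np.exp(-(c + eta)))
        hit = u < p
        # events may occur at visits 1..last_visit (baseline is pre-event)
        t_idx = np.arange(T)[None, :]
        eligible = (t_idx >= 1) & (t_idx <= last_visit[:, None])
        hit &= eligible
        any_event = hit.any(axis=1)
        first = np.where(any_event, hit.argmax(axis=1), last_visit)
        delta = any_event.astype(int)
        return first.astype(int), delta

    if spec.event_rate == 0.0:
        return last_visit.copy(), np.zeros(n, dtype=int), -np.inf

    lo, hi = -40.0, 40.0
    _, d_hi = realize(hi)
    if d_hi.mean() + tol < spec.event_rate:
        raise CalibrationError(
            f"target event_rate={spec.event_rate:.4f} exceeds the maximum "
            f"achievable prevalence {d_hi.mean():.4f} under the censoring pattern"
        )
    _, d_lo = realize(lo)
    if d_lo.mean() > spec.event_rate + max(tol, 2.0 / n):
        raise CalibrationError(
            f"target event_rate={spec.event_rate:.4f} is below the minimum "
            f"achievable prevalence {d_lo.mean():.4f}"
        )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        _, d = realize(mid)
        if d.mean() < spec.event_rate:
            lo = mid
        else:
            hi = mid
    c = hi  # smallest intercept reaching >= target prevalence
    t_event, delta = realize(c)
    return t_event, delta, c


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a long-format synthetic panel and its planted ground truth.

    Returns
    -------
    panel:
        One row per subject x observed visit with columns ``subject_id``,
        ``t``, covariates prefixed ``cov_``, features named
        ``<domain>__f<k>``, the continuous outcome ``y``, and per-subject
        ``event_time`` / ``event_indicator``.
    truth:
        :class:`GroundTruth` with the planted parameters.
    """
    rng = np.random.default_rng(spec.seed)
    n, T, N, F = spec.n_subjects, spec.n_timepoints, spec.n_nodes, spec.features_per_node
    names = spec.resolved_node_names
    ids = _subject_ids(n)

    # covariates (subject level)
    sex = rng.integers(0, 2, size=n)
    age_jitter = rng.integers(0, 2, size=n)
    pcs = rng.standard_normal((n, spec.n_pcs))
    site = rng.integers(0, spec.n_sites, size=n)

    z, high_risk = _simulate_latents(spec, rng)

    loadings = rng.uniform(0.7, 1.3, size=(N, F))
    feat_noise = rng.standard_normal((n, T, N, F))
    x = loadings[None, None, :, :] * z[:, :, :, None] + spec.feature_noise_sd * feat_noise

    y, w, noise_sd, r2 = _continuous_outcome(spec, z, rng)

    w_h = rng.uniform(0.8, 1.2, size=spec.n_signal_nodes) / np.sqrt(spec.n_signal_nodes)
    eta = spec.hazard_scale * (z[:, :, : spec.n_signal_nodes] @ w_h)

    last_visit = _censor_times(spec, rng)
    t_event, delta, intercept = _calibrate_events(spec, eta, last_visit, rng)

    # observation pattern: baseline always observed, dropout after last_visit,
    # optional MCAR whole-visit holes in between
    observed = np.arange(T)[None, :] <= last_visit[:, None]
    if spec.visit_missing_rate > 0:
        holes = rng.random((n, T)) < spec.visit_missing_rate
        holes[:, 0] = False
        observed &= ~holes

    if spec.cell_missing_rate > 0:
        cell_holes = rng.random(x.shape) < spec.cell_missing_rate
        x = np.where(cell_holes, np.nan, x)

    feat_cols = [f"{names[j]}__f{k}" for j in range(N) for k in range(F)]
    rows_i, rows_t = np.nonzero(observed)
    data: dict[str, np.ndarray | list] = {
        "subject_id": [ids[i] for i in rows_i],
        "t": rows_t,
        "cov_sex": sex[rows_i],
        "cov_age": spec.baseline_age + age_jitter[rows_i] + rows_t,
    }
    for k in range(spec.n_pcs):
        data[f"cov_pc{k + 1}"] = pcs[rows_i, k]
    data["cov_site"] = [f"site{s}" for s in site[rows_i]]
    flat = x.reshape(n, T, N * F)
    for c, col in enumerate(feat_cols):
        data[col] = flat[rows_i, rows_t, c]
    data["y"] = y[rows_i, rows_t]
    data["event_time"] = t_event[rows_i]
    data["event_indicator"] = delta[rows_i]
    data["high_risk"] = high_risk[rows_i].astype(int)
    panel = pd.DataFrame(data)

    truth = GroundTruth(
        node_names=names,
        signal_nodes=names[: spec.n_signal_nodes],
        effect_vector=w,
        outcome_lag_coefficient=spec.outcome_lag_coefficient,
        hazard_coefficients=spec.hazard_scale * w_h,
        hazard_intercept=intercept,
        generative_r2=r2,
        ar_coefficient=spec.ar_coefficient,
        loadings=loadings,
        subject_ids=tuple(ids),
        high_risk=high_risk,
        event_time=t_event,
        event_indicator=delta,
        noise_sd=noise_sd,
    )
    return panel, truth


def planted_truth(spec: CohortSpec) -> GroundTruth:
    """Return only the planted generative parameters for a spec (deterministic)."""
    _, truth = generate_cohort(spec)
    return truth
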