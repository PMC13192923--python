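"""Latent system-energy and collapse-state analysis.

The state of a subject at time t is a vector x_t — either the node-summary
vector or a trained model's hidden state h_t.  Its energy is the mean
squared entry, E_t = (1/N) sum_j x_{j,t}^2; graph-propagated energy is the
same quantity after one message-passing step, E_graph,t = (1/N) sum_j
(A x_t)_j^2.  The energy change Delta E_t = E_t - E_{t-1} over observed
visits feeds a collapse-like state detector: a visit is flagged when its
energy increase strictly exceeds the reference mean plus one SD of energy
changes.  Group contrasts summarize mean, final, and change-in energy for
a high-risk group versus its comparison group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "energy",
    "graph_energy",
    "delta_energy",
    "detect_collapse",
    "EnergyTrace",
    "trace_from_states",
    "group_contrast",
    "traces_to_frame",
    "plot_group_energy",
]


def energy(x: np.ndarray) -> float | np.ndarray:
    """Mean squared entry of a state vector (or of each row of a stack)."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] == 0:
        raise ValueError("empty state vector")
    return np.mean(x * x, axis=-1)


def graph_energy(A: np.ndarray, x: np.ndarray) -> float | np.ndarray:
    """Energy of the message-passed state A x."""
    A = np.asarray(A, dtype=float)
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != A.shape[1]:
        raise ValueError(
            f"dimension mismatch: A is {A.shape[0]}x{A.shape[1]}, x has {x.shape[-1]} entries"
        )
    return energy(x @ A.T)


def delta_energy(E: np.ndarray, observed: np.ndarray | None = None) -> np.ndarray:
    """Consecutive energy differences over observed visits.

    Returns an array aligned with ``E``; NaN at the first observed visit,
    at unobserved visits, and wherever the previous observed visit is not
    the direct predecessor in the observed subsequence.  Differences are
    taken between consecutive *observed* visits, matching how the energy
    series itself is only defined where the subject was seen.
    """
    E = np.asarray(E, dtype=float)
    if observed is None:
        observed = ~np.isnan(E)
    observed = np.asarray(observed).astype(bool)
    out = np.full(E.shape, np.nan)
    idx = np.nonzero(observed)[0]
    if idx.size < 2:
        # expected for early-dropout subjects; callers summarizing many
        # subjects should report the count once rather than per subject
        logger.debug("fewer than 2 observed visits: empty energy-change series")
        return out
    out[idx[1:]] = E[idx[1:]] - E[idx[:-1]]
    return out


def detect_collapse(
    dE: np.ndarray, reference: np.ndarray | None = None
) -> np.ndarray:
    """Flag visits whose energy increase strictly exceeds mu + sigma.

    ``reference`` is the population of energy changes defining the
    threshold (defaults to ``dE`` itself); mu and sigma are its mean and
    population SD over non-NaN values.  NaN entries of ``dE`` are never
    flagged.
    """
    dE = np.asarray(dE, dtype=float)
    ref = dE if reference is None else np.asarray(reference, dtype=float)
    ref = ref[~np.isnan(ref)]
    if ref.size < 2:
        raise ValueError("reference population needs at least 2 values")
    mu, sigma = float(np.mean(ref)), float(np.std(ref))
    if sigma == 0.0:
        logger.warning("zero-variance reference: collapse threshold equals the mean")
    threshold = mu + sigma
    flags = np.zeros(dE.shape, dtype=int)
    with np.errstate(invalid="ignore"):
        flags[np.nan_to_num(dE, nan=-np.inf) > threshold] = 1
    return flags


@dataclass
class EnergyTrace:
    """Per-subject time series of energies and collapse flags."""

    subject_id: str
    E: np.ndarray
    E_graph: np.ndarray
    dE: np.ndarray
    collapse: np.ndarray
    source: str = "hidden_state"  # or "node_summaries"

    @property
    def mean_energy(self) -> float:
        return float(np.nanmean(self.E))

    @property
    def final_energy(self) -> float:
        obs = np.nonzero(~np.isnan(self.E))[0]
        return float(self.E[obs[-1]]) if obs.size else float("nan")

    @property
    def mean_delta(self) -> float:
        if np.all(np.isnan(self.dE)):
            return float("nan")
        return float(np.nanmean(self.dE))


def trace_from_states(
    subject_id: str,
    states: np.ndarray,
    observed: np.ndarray,
    A: np.ndarray,
    reference_dE: np.ndarray | None = None,
    source: str = "hidden_state",
) -> EnergyTrace:
    """Build an :class:`EnergyTrace` from per-visit state vectors (T, N).

    When the state vector is a model hidden state (width != number of graph
    nodes) the graph-propagated energy is reported as the plain energy of
    the state; message passing applies only to node-dimension states.
    """
    states = np.asarray(states, dtype=float)
    observed = np.asarray(observed).astype(bool)
    E = np.where(observed, energy(states), np.nan)
    if states.shape[-1] == A.shape[1]:
        Eg = np.where(observed, graph_energy(A, states), np.nan)
    else:
        Eg = E.copy()
    dE = delta_energy(E, observed)
    ref = dE if reference_dE is None else np.asarray(reference_dE, dtype=float)
    if np.count_nonzero(~np.isnan(ref)) < 2:
        collapse = np.zeros(dE.shape, dtype=int)
    else:
        collapse = detect_collapse(dE, ref)
    return EnergyTrace(subject_id, E, Eg, dE, collapse, source=source)


def traces_to_frame(traces: list[EnergyTrace]) -> pd.DataFrame:
    """Tidy long CSV-ready frame: subject, t, E, E_graph, dE, collapse."""
    rows = []
    for tr in traces:
        for t in range(len(tr.E)):
            rows.append(
                {
                    "subject_id": tr.subject_id,
                    "t": t,
                    "E": tr.E[t],
                    "E_graph": tr.E_graph[t],
                    "dE": tr.dE[t],
                    "collapse": tr.collapse[t],
                }
            )
    return pd.DataFrame(rows)


def group_contrast(
    traces: list[EnergyTrace], labels: np.ndarray | list, high_label=1
) -> dict:
    """Contrast energy summaries between a high-risk group and its comparison.

    Per group: mean over member subjects of (time-mean energy, energy at
    the last observed visit, mean energy change).  Differences are
    high minus comparison, matching a risk-versus-comparison table layout.
    """
    labels = np.asarray(labels)
    if len(labels) != len(traces):
        raise ValueError("one label per trace required")
    high = [tr for tr, lb in zip(traces, labels) if lb == high_label]
    comp = [tr for tr, lb in zip(traces, labels) if lb != high_label]
    if not high or not comp:
        raise ValueError("both groups must be non-empty")

    def summarize(group: list[EnergyTrace]) -> dict:
        return {
            "n": len(group),
            "mean_energy": float(np.nanmean([tr.mean_energy for tr in group])),
            "final_energy": float(np.nanmean([tr.final_energy for tr in group])),
            "mean_delta": float(np.nanmean([tr.mean_delta for tr in group])),
        }

    hs, cs = summarize(high), summarize(comp)
    return {
        "high": hs,
        "comparison": cs,
        "diff": {
            "mean_energy": hs["mean_energy"] - cs["mean_energy"],
            "final_energy": hs["final_energy"] - cs["final_energy"],
            "mean_delta": hs["mean_delta"] - cs["mean_delta"],
        },
    }


def plot_group_energy(traces, labels, path, high_label=1) -> None:
    """Mean energy by visit for each group, saved to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = np.asarray(labels)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for name, sel in (("high", labels == high_label), ("comparison", labels != high_label)):
        group = [tr for tr, s in zip(traces, sel) if s]
        if not group:
            continue
        E = np.vstack([tr.E for tr in group])
        ax.plot(np.nanmean(E, axis=0), marker="o", label=f"{name} (n={len(group)})")
    ax.set_xlabel("visit index t")
    ax.set_ylabel("mean energy")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
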