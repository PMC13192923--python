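"""Long-format panel to masked model-ready sequences.

Time is the integer visit index t in {0..T_max}.  The module builds the
temporal targets used by the recurrent models — the lagged outcome
y_{t-1}, the change score Delta y_t = y_t - y_{t-1}, and the per-period
discrete-time event labels — and packs per-subject rows into fixed-length,
zero-padded sequences with an observation mask m_{i,t}.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SequenceBatch",
    "build_continuous_targets",
    "encode_discrete_time_event",
    "build_sequences",
    "sequences_to_long",
]


@dataclass
class SequenceBatch:
    """Padded per-subject sequences with an observation mask.

    Attributes
    ----------
    subject_ids:
        Subject identifier per sequence row.
    X:
        Feature array of shape (n_subjects, T, n_features); zeros at
        padded (unobserved) slots.
    mask:
        0/1 observation mask of shape (n_subjects, T); 1 exactly where the
        long panel has a row.
    y, y_valid:
        Per-time target values and validity flags (same shape as mask).
        Positions with ``y_valid == 0`` never enter a loss or a metric.
    feature_names:
        Column order of the last axis of ``X``.
    """

    subject_ids: list[str]
    X: np.ndarray
    mask: np.ndarray
    y: np.ndarray
    y_valid: np.ndarray
    feature_names: list[str]
    extras: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.X.shape[1]

    @property
    def n_features(self) -> int:
        return self.X.shape[2]

    def save(self, path: str | Path) -> None:
        """Write arrays to a compressed ``.npz`` with a JSON sidecar naming dims."""
        path = Path(path)
        np.savez_compressed(
            path,
            X=self.X,
            mask=self.mask,
            y=self.y,
            y_valid=self.y_valid,
            **{f"extra__{k}": v for k, v in self.extras.items()},
        )
        sidecar = {
            "subject_ids": self.subject_ids,
            "feature_names": self.feature_names,
            "shape": {
                "n_subjects": self.n_subjects,
                "n_timepoints": self.n_timepoints,
                "n_features": self.n_features,
            },
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "SequenceBatch":
        path = Path(path)
        arrays = np.load(path if path.suffix else path.with_suffix(".npz"))
        sidecar = json.loads(path.with_suffix(".json").read_text())
        extras = {
            k[len("extra__"):]: arrays[k] for k in arrays.files if k.startswith("extra__")
        }
        return cls(
            subject_ids=sidecar["subject_ids"],
            X=arrays["X"],
            mask=arrays["mask"],
            y=arrays["y"],
            y_valid=arrays["y_valid"],
            feature_names=sidecar["feature_names"],
            extras=extras,
        )


def build_continuous_targets(
    panel: pd.DataFrame, outcome: str = "y"
) -> pd.DataFrame:
    """Add the lagged outcome and change score to a long panel.

    ``<outcome>_lag`` holds y_{t-1} and ``<outcome>_delta`` holds
    y_t - y_{t-1}.  Both are NaN (with ``<outcome>_lag_valid = 0``) at a
    subject's first observed visit and wherever visit t-1 is unobserved:
    lag and change are defined only over consecutive integer time indices,
    never across a gap.
    """
    if outcome not in panel.columns:
        raise KeyError(f"outcome column {outcome!r} not present in panel")
    out = panel.sort_values(["subject_id", "t"]).reset_index(drop=True)
    grp = out.groupby("subject_id", sort=False)
    prev_t = grp["t"].shift(1)
    prev_y = grp[outcome].shift(1)
    consecutive = (out["t"] - prev_t) == 1
    valid = consecutive & prev_y.notna() & out[outcome].notna()
    out[f"{outcome}_lag"] = np.where(valid, prev_y, np.nan)
    out[f"{outcome}_delta"] = np.where(valid, out[outcome] - prev_y, np.nan)
    out[f"{outcome}_lag_valid"] = valid.astype(int)
    return out


def encode_discrete_time_event(
    event_time: int, event_indicator: int, times: np.ndarray | list[int]
) -> np.ndarray:
    """Per-period discrete-time survival labels for one subject.

    For each period t_a the label is 1 if the event occurred by t_a
    (delta=1 and T_i <= t_a), 0 while the subject is still at risk
    (T_i > t_a), and NaN once a censored subject's follow-up has ended
    (delta=0 and T_i <= t_a) — at equality the still-at-risk branch fails
    and the censored cell carries no label.
    """
    if event_indicator not in (0, 1):
        raise ValueError(f"event indicator must be 0 or 1, got {event_indicator}")
    if event_time < 0:
        raise ValueError(f"event time must be non-negative, got {event_time}")
    times = np.asarray(times)
    labels = np.full(times.shape, np.nan)
    labels[times < event_time] = 0.0
    if event_indicator == 1:
        labels[times >= event_time] = 1.0
    return labels


def build_sequences(
    panel: pd.DataFrame,
    feature_cols: list[str],
    t_max: int,
    outcome: str = "y",
    outcome_valid_col: str | None = None,
    drop_post_event: bool = False,
) -> SequenceBatch:
    """Pack a long panel into fixed-length masked sequences.

    Each subject gets ``t_max + 1`` slots; ``mask[i, t] = 1`` iff the panel
    has a row for (subject i, visit t).  Padded slots carry zero features
    (the post-standardization mean) and invalid targets.

    When ``outcome`` names the per-subject event columns implicitly (the
    panel has ``event_time`` / ``event_indicator`` and ``outcome`` is set
    to ``"event"``), targets are the discrete-time labels of
    :func:`encode_discrete_time_event`, restricted to observed visits.
    With ``drop_post_event`` the classical person-period convention is
    used instead: periods after the event carry no label.
    """
    dup = panel.duplicated(subset=["subject_id", "t"])
    if dup.any():
        bad = panel.loc[dup, ["subject_id", "t"]].iloc[0]
        raise ValueError(
            f"duplicate (subject, t) rows, e.g. ({bad['subject_id']}, t={bad['t']})"
        )
    if (panel["t"] < 0).any() or (panel["t"] > t_max).any():
        raise ValueError(f"panel contains t outside 0..{t_max}")

    subjects = list(pd.unique(panel["subject_id"]))
    index = {s: i for i, s in enumerate(subjects)}
    n, T = len(subjects), t_max + 1

    X = np.zeros((n, T, len(feature_cols)))
    mask = np.zeros((n, T), dtype=int)
    y = np.zeros((n, T))
    y_valid = np.zeros((n, T), dtype=int)

    rows = panel["subject_id"].map(index).to_numpy()
    cols = panel["t"].to_numpy()
    mask[rows, cols] = 1
    feats = panel[feature_cols].to_numpy(dtype=float)
    if np.isnan(feats).any():
        raise ValueError("features contain NaN; run imputation before sequencing")
    X[rows, cols, :] = feats

    if outcome == "event":
        times = np.arange(T)
        for s, sub in panel.groupby("subject_id", sort=False):
            i = index[s]
            labels = encode_discrete_time_event(
                int(sub["event_time"].iloc[0]),
                int(sub["event_indicator"].iloc[0]),
                times,
            )
            if drop_post_event:
                labels[times > int(sub["event_time"].iloc[0])] = np.nan
            ok = mask[i].astype(bool) & ~np.isnan(labels)
            y[i, ok] = labels[ok]
            y_valid[i, ok] = 1
    else:
        if outcome not in panel.columns:
            raise KeyError(f"outcome column {outcome!r} not present in panel")
        vals = panel[outcome].to_numpy(dtype=float)
        ok = ~np.isnan(vals)
        if outcome_valid_col is not None:
            ok &= panel[outcome_valid_col].to_numpy(dtype=bool)
        y[rows[ok], cols[ok]] = vals[ok]
        y_valid[rows[ok], cols[ok]] = 1

    extras: dict[str, np.ndarray] = {}
    for name in (f"{outcome}_lag", f"{outcome}_delta"):
        if name in panel.columns:
            arr = np.zeros((n, T))
            ok_arr = np.zeros((n, T), dtype=int)
            vals = panel[name].to_numpy(dtype=float)
            good = ~np.isnan(vals)
            arr[rows[good], cols[good]] = vals[good]
            ok_arr[rows[good], cols[good]] = 1
            extras[name] = arr
            extras[f"{name}_valid"] = ok_arr

    return SequenceBatch(
        subject_ids=subjects,
        X=X,
        mask=mask,
        y=y,
        y_valid=y_valid,
        feature_names=list(feature_cols),
        extras=extras,
    )


def sequences_to_long(batch: SequenceBatch, outcome: str = "y") -> pd.DataFrame:
    """Unpack a sequence batch back to long format, dropping padded slots."""
    records = []
    for i, sid in enumerate(batch.subject_ids):
        for t in range(batch.n_timepoints):
            if batch.mask[i, t]:
                rec = {"subject_id": sid, "t": t}
                rec.update(dict(zip(batch.feature_names, batch.X[i, t])))
                rec[outcome] = batch.y[i, t] if batch.y_valid[i, t] else np.nan
                records.append(rec)
    return pd.DataFrame(records)
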