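"""End-to-end pipeline: simulate -> preprocess -> graph -> train -> evaluate -> energy.

A :class:`RunConfig` (usually loaded from YAML) names the panel (or a
simulation spec), the outcomes with their task type, the subject-level
split fractions, graph settings, model settings, and the seed list.  The
pipeline writes a run directory containing metric CSVs, model
checkpoints, energy traces, group summaries, and a manifest sufficient to
reproduce the run.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortSpec, generate_cohort
from .energy import group_contrast, trace_from_states, traces_to_frame
from .graph import assign_nodes, build_adjacency, node_summaries
from .metrics import MetricReport, reports_to_csv
from .models import ModelConfig, hidden_states, multi_seed_run
from .panel import build_continuous_targets, build_sequences
from .preprocess import apply_preprocess, fit_preprocess

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "split_subjects", "run_pipeline", "prepare_outcome"]

# fixed offsets so each stage draws from an isolated stream under one global seed
_SPLIT_OFFSET = 101
_SIM_OFFSET = 0


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    out_dir: str
    panel_path: str | None = None
    simulate: dict | None = None  # CohortSpec fields
    outcomes: list[dict] = field(
        default_factory=lambda: [{"name": "y", "task": "continuous"}]
    )
    split_fractions: tuple[float, float, float] = (0.64, 0.16, 0.20)
    graph_method: str = "abs_correlation"
    graph_threshold: float = 0.1
    architectures: tuple[str, ...] = ("graph_lstm", "graph_gtrnn")
    hidden_width: int = 32
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 200
    patience: int = 10
    seeds: tuple[int, ...] = (0,)
    seed: int = 0  # global seed for splitting / simulation
    high_symptom_quantile: float = 0.75
    energy_source: str = "hidden_state"
    residualize: bool = True

    def validate(self) -> None:
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError(
                f"split fractions must sum to 1, got {self.split_fractions}"
            )
        if any(f <= 0 for f in self.split_fractions):
            raise ValueError("split fractions must be positive")
        if self.panel_path is None and self.simulate is None:
            raise ValueError("either panel_path or a simulate spec is required")
        for oc in self.outcomes:
            if oc.get("task") not in ("continuous", "binary"):
                raise ValueError(f"outcome {oc} needs task 'continuous' or 'binary'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        payload = yaml.safe_load(Path(path).read_text())
        if "split_fractions" in payload:
            payload["split_fractions"] = tuple(payload["split_fractions"])
        if "architectures" in payload:
            payload["architectures"] = tuple(payload["architectures"])
        if "seeds" in payload:
            payload["seeds"] = tuple(payload["seeds"])
        return cls(**payload)


def split_subjects(
    subject_ids: list[str],
    fractions: tuple[float, float, float],
    seed: int,
) -> tuple[list[str], list[str], list[str]]:
    """Seed-deterministic subject-level train/val/test split.

    Sizes follow the nested held-out convention: the test set takes
    ceil(n * f_test), the validation set ceil(n * f_val), and training the
    remainder — the arithmetic of two nested train/test splits, which maps
    2,620 subjects at 64/16/20 to 1,676/420/524.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    if any(f <= 0 for f in fractions):
        raise ValueError("fractions must be positive")
    ids = list(subject_ids)
    n = len(ids)
    if n < 3:
        raise ValueError("need at least 3 subjects to split")

    def _ceil(x: float) -> int:
        r = round(x)
        return r if abs(x - r) < 1e-9 else math.ceil(x)

    n_test = _ceil(n * fractions[2])
    n_val = _ceil(n * fractions[1])
    n_train = n - n_val - n_test
    if n_train < 1 or n_val < 1 or n_test < 1:
        raise ValueError("each split must receive at least one subject")

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    shuffled = [ids[i] for i in order]
    test = sorted(shuffled[:n_test])
    val = sorted(shuffled[n_test : n_test + n_val])
    train = sorted(shuffled[n_test + n_val :])
    return train, val, test


def _feature_columns(panel: pd.DataFrame) -> list[str]:
    reserved = {"subject_id", "t", "y", "event_time", "event_indicator", "high_risk"}
    return [
        c
        for c in panel.columns
        if "__" in c and not c.startswith("cov_") and c not in reserved
    ]


def _covariate_columns(panel: pd.DataFrame) -> list[str]:
    return [c for c in panel.columns if c.startswith("cov_")]


def prepare_outcome(
    panel: pd.DataFrame,
    task: str,
    config: RunConfig,
    outcome_col: str = "y",
) -> dict:
    """Preprocess, build the graph, and pack masked sequences for one outcome.

    Returns a dict with the subject splits, fitted preprocessing state,
    graph spec, and per-split feature-level and node-level sequence
    batches.
    """
    feature_cols = _feature_columns(panel)
    covariate_cols = _covariate_columns(panel) if config.residualize else []
    subjects = sorted(panel["subject_id"].unique())
    train_ids, val_ids, test_ids = split_subjects(
        subjects, config.split_fractions, config.seed + _SPLIT_OFFSET
    )
    parts = {
        name: panel[panel["subject_id"].isin(ids)].copy()
        for name, ids in (("train", train_ids), ("val", val_ids), ("test", test_ids))
    }

    state = fit_preprocess(parts["train"], feature_cols, covariate_cols)
    processed = {
        name: apply_preprocess(df, state, covariate_cols) for name, df in parts.items()
    }
    retained = state.retained

    node_names, feature_map = assign_nodes(retained)
    graph = build_adjacency(
        node_summaries(processed["train"][retained], node_names, feature_map),
        node_names,
        method=config.graph_method,
        threshold=config.graph_threshold,
    )
    graph.feature_map = feature_map

    t_max = int(panel["t"].max())
    outcome = "event" if task == "binary" else outcome_col
    batches: dict[str, dict] = {"features": {}, "nodes": {}}
    for name, df in processed.items():
        if task == "continuous":
            df = build_continuous_targets(df, outcome_col)
        batches["features"][name] = build_sequences(df, retained, t_max, outcome=outcome)
        summ = node_summaries(df[retained], node_names, feature_map)
        node_df = df[["subject_id", "t"]].copy()
        for j, nn in enumerate(node_names):
            node_df[f"{nn}__summary"] = summ[:, j]
        if task == "continuous":
            node_df[outcome_col] = df[outcome_col].to_numpy()
        else:
            node_df["event_time"] = df["event_time"].to_numpy()
            node_df["event_indicator"] = df["event_indicator"].to_numpy()
        node_batch = build_sequences(
            node_df,
            [f"{nn}__summary" for nn in node_names],
            t_max,
            outcome=outcome,
        )
        node_batch.feature_names = list(node_names)
        batches["nodes"][name] = node_batch

    return {
        "splits": {"train": train_ids, "val": val_ids, "test": test_ids},
        "state": state,
        "graph": graph,
        "batches": batches,
        "t_max": t_max,
    }


def _high_symptom_labels(batch, quantile: float) -> np.ndarray:
    """Top-quantile of the last observed continuous outcome -> label 1."""
    last_y = np.full(batch.n_subjects, np.nan)
    for i in range(batch.n_subjects):
        obs = np.nonzero(batch.mask[i] * batch.y_valid[i])[0]
        if obs.size:
            last_y[i] = batch.y[i, obs[-1]]
    cut = np.nanquantile(last_y, quantile)
    return (last_y > cut).astype(int)


def _event_labels(panel: pd.DataFrame, subject_ids: list[str]) -> np.ndarray:
    per_subject = panel.groupby("subject_id")["event_indicator"].first()
    return per_subject.reindex(subject_ids).to_numpy(dtype=int)


def energy_analysis(
    model,
    graph,
    test_feature_batch,
    test_node_batch,
    labels: np.ndarray,
    source: str = "hidden_state",
) -> tuple[list, dict]:
    """Energy traces and group contrast on the test split.

    With ``source='hidden_state'`` energies come from the trained model's
    hidden trajectories; with ``'node_summaries'`` from the standardized
    node vectors themselves.
    """
    if source == "hidden_state":
        batch = (
            test_node_batch if model.config.architecture == "graph_gtrnn" else test_feature_batch
        )
        states = hidden_states(model, batch, graph=graph)
        mask = batch.mask
        ids = batch.subject_ids
    else:
        states = test_node_batch.X
        mask = test_node_batch.mask
        ids = test_node_batch.subject_ids

    A = graph.adjacency
    # cohort-level reference population of energy changes
    prelim = [
        trace_from_states(ids[i], states[i], mask[i].astype(bool), A, source=source)
        for i in range(len(ids))
    ]
    n_short = sum(1 for tr in prelim if np.all(np.isnan(tr.dE)))
    if n_short:
        logger.warning(
            "%d of %d subjects have <2 observed visits: empty energy-change series",
            n_short, len(prelim),
        )
    ref = np.concatenate([tr.dE for tr in prelim])
    ref = ref[~np.isnan(ref)]
    traces = [
        trace_from_states(
            ids[i], states[i], mask[i].astype(bool), A, reference_dE=ref, source=source
        )
        for i in range(len(ids))
    ]
    contrast = group_contrast(traces, labels)
    return traces, contrast


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline and write the run directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from importlib.metadata import version as _dist_version

    try:
        pkg_version = _dist_version("dynograph")
    except Exception:
        pkg_version = "unknown"
    manifest: dict = {
        "version": pkg_version,
        "config": asdict(config),
        "stages": {},
    }

    try:
        if config.simulate is not None:
            spec = CohortSpec(**{**config.simulate, "seed": config.simulate.get("seed", config.seed + _SIM_OFFSET)})
            panel, _ = generate_cohort(spec)
            panel.to_parquet(out / "panel.parquet")
            manifest["stages"]["simulate"] = {"n_subjects": spec.n_subjects}
        else:
            path = Path(config.panel_path)
            panel = (
                pd.read_parquet(path) if path.suffix == ".parquet" else pd.read_csv(path)
            )
            manifest["stages"]["load"] = {"path": str(path)}

        reports: list[MetricReport] = []
        summaries: list[dict] = []
        for oc in config.outcomes:
            name, task = oc["name"], oc["task"]
            prep = prepare_outcome(panel, task, config, outcome_col=oc.get("column", "y"))
            prep["state"].to_json(out / f"preprocess_{name}.json")
            prep["graph"].to_json(out / f"graph_{name}.json")
            head = "continuous" if task == "continuous" else "binary"

            for arch in config.architectures:
                uses_nodes = arch == "graph_gtrnn"
                bset = prep["batches"]["nodes" if uses_nodes else "features"]
                width = bset["train"].n_features
                mcfg = ModelConfig(
                    architecture=arch,
                    input_width=width,
                    hidden_width=config.hidden_width,
                    head=head,
                    learning_rate=config.learning_rate,
                    batch_size=config.batch_size,
                    max_epochs=config.max_epochs,
                    patience=config.patience,
                )
                graph_arg = prep["graph"] if uses_nodes else None
                result = multi_seed_run(
                    mcfg, bset["train"], bset["val"], bset["test"],
                    config.seeds, graph=graph_arg,
                )
                for r in result["per_seed"]:
                    r["model"].save(out / f"model_{name}_{arch}_seed{r['seed']}")
                    pd.DataFrame(r["model"].history).to_csv(
                        out / f"history_{name}_{arch}_seed{r['seed']}.csv", index=False
                    )
                    reports.append(
                        MetricReport(
                            outcome=name,
                            model=arch,
                            seed=r["seed"],
                            metrics=r["metrics"],
                            n_positions=int(
                                (bset["test"].mask * bset["test"].y_valid).sum()
                            ),
                            event_prevalence=r["metrics"].get("prevalence"),
                        )
                    )
                manifest["stages"][f"train_{name}_{arch}"] = result["summary"]

                if uses_nodes:
                    test_nodes = prep["batches"]["nodes"]["test"]
                    if task == "continuous":
                        labels = _high_symptom_labels(
                            test_nodes, config.high_symptom_quantile
                        )
                    else:
                        labels = _event_labels(panel, test_nodes.subject_ids)
                    for r in result["per_seed"]:
                        try:
                            traces, contrast = energy_analysis(
                                r["model"], prep["graph"],
                                prep["batches"]["features"]["test"], test_nodes,
                                labels, source=config.energy_source,
                            )
                        except ValueError as err:
                            # e.g. no event/case subjects in a small test split
                            logger.warning(
                                "skipping energy contrast for %s seed %s: %s",
                                name, r["seed"], err,
                            )
                            continue
                        traces_to_frame(traces).to_csv(
                            out / f"energy_{name}_seed{r['seed']}.csv", index=False
                        )
                        summaries.append(
                            {
                                "outcome": name,
                                "seed": r["seed"],
                                "n_high": contrast["high"]["n"],
                                "n_comparison": contrast["comparison"]["n"],
                                **{f"high_{k}": v for k, v in contrast["high"].items() if k != "n"},
                                **{f"comp_{k}": v for k, v in contrast["comparison"].items() if k != "n"},
                                **{f"diff_{k}": v for k, v in contrast["diff"].items()},
                            }
                        )

        reports_to_csv(reports, out / "metrics.csv")
        if summaries:
            pd.DataFrame(summaries).to_csv(out / "group_summary.csv", index=False)
        manifest["stages"]["done"] = True
    except Exception as exc:  # record the failure, then re-raise
        manifest["stages"]["error"] = repr(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
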