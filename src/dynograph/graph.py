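"""Domain graph construction and message passing.

Features are grouped into domain-level nodes by name prefix
(``<domain>__<feature>``), each node is summarized as the mean of its
standardized features, and edges are derived from the training data: the
default adjacency is the absolute Pearson correlation between node
summaries, thresholded, given unit self-loops, and row-normalized so that
one message-passing step x_graph = A x is a stable averaging operator.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GraphSpec",
    "assign_nodes",
    "node_summaries",
    "build_adjacency",
    "message_pass",
]


@dataclass
class GraphSpec:
    """Node definitions and adjacency matrix of the system graph."""

    node_names: list[str]
    feature_map: dict[str, str]  # feature -> node
    adjacency: np.ndarray  # (N, N)
    method: str = "abs_correlation"
    threshold: float = 0.1
    metadata: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    def features_of(self, node: str) -> list[str]:
        return [f for f, n in self.feature_map.items() if n == node]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "node_names": self.node_names,
            "feature_map": self.feature_map,
            "adjacency": self.adjacency.tolist(),
            "method": self.method,
            "threshold": self.threshold,
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GraphSpec":
        payload = json.loads(Path(path).read_text())
        payload["adjacency"] = np.asarray(payload["adjacency"])
        return cls(**payload)

    def to_edge_list(self, path: str | Path) -> None:
        """Write nonzero edges as a TSV (node_i, node_j, weight)."""
        with open(path, "w") as fh:
            fh.write("node_i\tnode_j\tweight\n")
            for i, ni in enumerate(self.node_names):
                for j, nj in enumerate(self.node_names):
                    w = self.adjacency[i, j]
                    if w != 0:
                        fh.write(f"{ni}\t{nj}\t{w:.10g}\n")


def assign_nodes(
    feature_names: list[str],
    node_names: list[str] | None = None,
    strict: bool = True,
    other_node: str = "other",
) -> tuple[list[str], dict[str, str]]:
    """Map features to nodes by their ``<domain>__`` prefix.

    With ``strict`` an unknown prefix raises; otherwise unknown features go
    to ``other_node``.  Returns the node list (known order preserved) and
    the feature -> node map.
    """
    if not feature_names:
        raise ValueError("empty feature list")
    mapping: dict[str, str] = {}
    seen: list[str] = []
    known = set(node_names) if node_names is not None else None
    for feat in feature_names:
        prefix = feat.split("__", 1)[0] if "__" in feat else feat
        if known is not None and prefix not in known:
            if strict:
                raise ValueError(f"feature {feat!r} has unknown domain prefix {prefix!r}")
            prefix = other_node
        mapping[feat] = prefix
        if prefix not in seen:
            seen.append(prefix)
    nodes = list(node_names) if node_names is not None else seen
    if not strict and other_node in mapping.values() and other_node not in nodes:
        nodes.append(other_node)
    return nodes, mapping


def node_summaries(
    features: pd.DataFrame | np.ndarray,
    node_names: list[str],
    feature_map: dict[str, str],
    feature_names: list[str] | None = None,
) -> np.ndarray:
    """Per-row node-level vector: mean of each node's standardized features.

    Nodes with no assigned feature get 0.  Accepts a DataFrame of feature
    columns or an array plus ``feature_names`` giving its column order.
    """
    if isinstance(features, pd.DataFrame):
        feature_names = list(features.columns)
        values = features.to_numpy(dtype=float)
    else:
        if feature_names is None:
            raise ValueError("feature_names required with array input")
        values = np.asarray(features, dtype=float)
    out = np.zeros((values.shape[0], len(node_names)))
    for j, node in enumerate(node_names):
        cols = [k for k, f in enumerate(feature_names) if feature_map.get(f) == node]
        if cols:
            out[:, j] = values[:, cols].mean(axis=1)
    return out


def build_adjacency(
    train_summaries: np.ndarray,
    node_names: list[str],
    method: str = "abs_correlation",
    threshold: float = 0.1,
) -> GraphSpec:
    """Build the adjacency matrix from training-row node summaries.

    ``abs_correlation`` (default): a_jk = |pearson r(node_j, node_k)| for
    j != k, zeroed below ``threshold``; unit self-loops; symmetrized, then
    row-normalized to sum 1.  ``identity`` and ``full`` baselines skip the
    data-driven step (``full`` is the uniform row-stochastic matrix).
    """
    N = len(node_names)
    if method == "identity":
        A = np.eye(N)
    elif method == "full":
        A = np.full((N, N), 1.0 / N)
    elif method == "abs_correlation":
        S = np.asarray(train_summaries, dtype=float)
        if S.ndim != 2 or S.shape[0] < 2:
            raise ValueError("need at least 2 training rows of node summaries")
        if S.shape[1] != N:
            raise ValueError(f"summaries have {S.shape[1]} nodes, expected {N}")
        sd = S.std(axis=0)
        dead = sd == 0
        if dead.any():
            logger.warning(
                "nodes with zero variance get no edges: %s",
                [node_names[j] for j in np.nonzero(dead)[0]],
            )
        safe = np.where(dead, 1.0, sd)
        Z = (S - S.mean(axis=0)) / safe
        R = np.abs(Z.T @ Z / S.shape[0])
        R[dead, :] = 0.0
        R[:, dead] = 0.0
        R[R < threshold] = 0.0
        np.fill_diagonal(R, 1.0)
        A = 0.5 * (R + R.T)
        rows = A.sum(axis=1, keepdims=True)
        A = A / np.where(rows == 0, 1.0, rows)
    else:
        raise ValueError(f"unknown adjacency method {method!r}")
    spec = GraphSpec(
        node_names=list(node_names),
        feature_map={},
        adjacency=A,
        method=method,
        threshold=threshold,
    )
    if method == "abs_correlation":
        spec.metadata["pre_normalization"] = (0.5 * (R + R.T)).tolist()
    return spec


def build_adjacency_per_timepoint(
    train_summaries: np.ndarray,
    t_index: np.ndarray,
    node_names: list[str],
    method: str = "abs_correlation",
    threshold: float = 0.1,
) -> dict[int, GraphSpec]:
    """One adjacency per visit index, from that visit's training rows only.

    An alternative to the default single static matrix for analyses that
    allow edge strength to drift across visits.
    """
    t_index = np.asarray(t_index)
    out: dict[int, GraphSpec] = {}
    for t in np.unique(t_index):
        rows = np.asarray(train_summaries)[t_index == t]
        out[int(t)] = build_adjacency(rows, node_names, method=method, threshold=threshold)
    return out


def message_pass(A: np.ndarray, x: np.ndarray) -> np.ndarray:
    """One message-passing step: x_graph = A x.

    ``x`` may be a single node vector (length N) or a stack (..., N);
    the product is applied along the last axis.
    """
    A = np.asarray(A, dtype=float)
    x = np.asarray(x, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("A must be square")
    if x.shape[-1] != A.shape[1]:
        raise ValueError(
            f"dimension mismatch: A is {A.shape[0]}x{A.shape[1]}, x has {x.shape[-1]} nodes"
        )
    return x @ A.T
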