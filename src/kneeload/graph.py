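"""Temporal-graph representation of one serve: 101 time nodes carrying six
joint-angle features, completely connected, with all-ones edge attributes."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .preprocess import N_NODES, NormalizedTrial
from .synthetic import JOINTS


@dataclass
class ServeGraph:
    node_features: np.ndarray  # n_nodes x 6
    edge_index: np.ndarray  # 2 x n_edges, int
    edge_attr: np.ndarray  # n_edges, all ones
    target: np.ndarray  # n_nodes
    phase_labels: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.node_features = np.asarray(self.node_features, dtype=float)
        self.edge_index = np.asarray(self.edge_index, dtype=np.int64)
        self.edge_attr = np.asarray(self.edge_attr, dtype=float)
        self.target = np.asarray(self.target, dtype=float).ravel()
        if self.edge_index.ndim != 2 or self.edge_index.shape[0] != 2:
            raise DataError("edge_index must be 2 x n_edges")
        if self.edge_attr.shape != (self.edge_index.shape[1],):
            raise DataError("edge_attr must have one value per edge")
        if self.target.shape != (self.n_nodes,):
            raise DataError("target must have one value per node")

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_index.shape[1]


def complete_edge_index(n_nodes: int, self_loops: bool = True) -> np.ndarray:
    """All ordered pairs, lexicographically sorted; diagonal iff self_loops."""
    src, dst = np.meshgrid(np.arange(n_nodes), np.arange(n_nodes), indexing="ij")
    src, dst = src.ravel(), dst.ravel()
    if not self_loops:
        keep = src != dst
        src, dst = src[keep], dst[keep]
    return np.stack([src, dst]).astype(np.int64)


def build_graph(trial: NormalizedTrial, self_loops: bool = True) -> ServeGraph:
    """Complete directed temporal graph; node t holds column t of the
    6 x 101 angle matrix."""
    if trial.angles.shape != (6, N_NODES):
        raise DataError("trial angle matrix must be 6 x 101")
    edge_index = complete_edge_index(N_NODES, self_loops=self_loops)
    return ServeGraph(
        node_features=trial.angles.T.copy(),
        edge_index=edge_index,
        edge_attr=np.ones(edge_index.shape[1]),
        target=trial.resultant_moment.copy(),
        phase_labels=None if trial.phase_labels is None else trial.phase_labels.copy(),
        meta={
            "participant_id": trial.participant_id,
            "trial_id": trial.trial_id,
            "self_loops": bool(self_loops),
        },
    )


def validate_graph(graph: ServeGraph) -> dict[str, dict]:
    """Check every ServeGraph invariant; reports, never raises.

    Returns {check_name: {"passed": bool, "count": int}} where count is the
    number of offending items (0 when passed).
    """
    report: dict[str, dict] = {}

    n_bad = abs(graph.n_nodes - N_NODES)
    report["node_count_101"] = {"passed": graph.n_nodes == N_NODES, "count": n_bad}

    feat_ok = graph.node_features.ndim == 2 and graph.node_features.shape[1] == 6
    report["six_features_per_node"] = {
        "passed": bool(feat_ok),
        "count": 0 if feat_ok else 1,
    }

    pairs = [tuple(e) for e in graph.edge_index.T]
    seen: set[tuple[int, int]] = set()
    dupes = 0
    for p in pairs:
        if p in seen:
            dupes += 1
        seen.add(p)
    report["no_duplicate_edges"] = {"passed": dupes == 0, "count": dupes}

    loops = {p for p in seen if p[0] == p[1]}
    non_loop = seen - loops
    expected = {
        (u, v)
        for u in range(graph.n_nodes)
        for v in range(graph.n_nodes)
        if u != v
    }
    missing = len(expected - non_loop)
    report["complete_connectivity"] = {"passed": missing == 0, "count": missing}

    asym = sum(1 for (u, v) in non_loop if (v, u) not in non_loop)
    report["symmetric_adjacency"] = {"passed": asym == 0, "count": asym}

    bad_attr = int(np.sum(graph.edge_attr != 1.0))
    report["all_ones_edge_attr"] = {"passed": bad_attr == 0, "count": bad_attr}

    in_range = np.all((graph.edge_index >= 0) & (graph.edge_index < graph.n_nodes))
    n_out = int(np.sum((graph.edge_index < 0) | (graph.edge_index >= graph.n_nodes)))
    report["edge_indices_in_range"] = {"passed": bool(in_range), "count": n_out}

    return report


def write_graph_tsv(graph: ServeGraph, nodes_path: str | Path, edges_path: str | Path) -> None:
    """Two-file plain-text dump for inspection."""
    nodes = pd.DataFrame(
        graph.node_features, columns=list(JOINTS)
    )
    nodes.insert(0, "node_index", np.arange(graph.n_nodes))
    nodes.to_csv(nodes_path, sep="\t", index=False, float_format="%.12g")
    edges = pd.DataFrame(
        {
            "src": graph.edge_index[0],
            "dst": graph.edge_index[1],
            "attr": graph.edge_attr,
        }
    )
    edges.to_csv(edges_path, sep="\t", index=False, float_format="%.12g")
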