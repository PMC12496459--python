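"""Layer-wise relevance propagation through the affine head, the unrolled
GRU, and the graph-convolution stack, down to the 101 x 6 input features.

Rules (all epsilon-stabilized):

* affine maps: z-rule, ``R_i = sum_j x_i W_ij / (z_j + eps*sign(z_j)) R_j``;
* GRU step: relevance of ``h_t`` splits between the carry term
  ``(1-z)*h_prev`` and the candidate term ``z*hcand`` in proportion to their
  stabilized share of ``h_t``; gates are treated as constants; the candidate
  share flows through the candidate affine map onto the step input and
  ``r*h_prev`` (assigned to ``h_prev``);
* graph convolution: treated as the dense linear map from flattened input
  to flattened output induced by the normalized adjacency;
* elementwise nonlinearities (tanh, ReLU) pass relevance through unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ArgumentError, NumericalError, StateError
from .graph import ServeGraph
from .model import MomentNet, TrainState, _a_hat
from .synthetic import JOINTS


@dataclass
class RelevanceMap:
    raw: np.ndarray  # 101 x 6, signed
    normalized: np.ndarray  # 101 x 6, in [0, 1]
    epsilon: float
    explained_output: dict

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        self.normalized = np.asarray(self.normalized, dtype=float)
        if self.raw.shape != self.normalized.shape:
            raise ArgumentError("raw and normalized maps must share a shape")


def _stabilize(z: np.ndarray, epsilon: float) -> np.ndarray:
    if epsilon == 0.0:
        if np.any(z == 0.0):
            raise NumericalError(
                "zero pre-activation with epsilon = 0; relevance undefined"
            )
        return z
    return z + epsilon * np.where(z >= 0.0, 1.0, -1.0)


def lrp_linear(
    x: np.ndarray,
    W: np.ndarray,
    b: np.ndarray,
    R_out: np.ndarray,
    epsilon: float = 1e-6,
) -> np.ndarray:
    """Epsilon rule for one affine map ``z = x @ W + b``."""
    x = np.asarray(x, dtype=float)
    W = np.asarray(W, dtype=float)
    b = np.asarray(b, dtype=float)
    R_out = np.asarray(R_out, dtype=float)
    if x.ndim != 1 or W.ndim != 2 or W.shape[0] != x.size:
        raise ArgumentError("lrp_linear shape mismatch between x and W")
    if R_out.shape != (W.shape[1],) or b.shape != (W.shape[1],):
        raise ArgumentError("lrp_linear shape mismatch on outputs")
    if epsilon < 0:
        raise ArgumentError("epsilon must be >= 0")
    z = x @ W + b
    s = R_out / _stabilize(z, epsilon)
    return x * (W @ s)


def lrp_gru_step(
    step_cache: dict,
    weights: dict,
    R_ht: np.ndarray,
    epsilon: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Distribute relevance of ``h_t`` onto ``h_{t-1}`` and the step input.

    ``step_cache`` must provide the cached forward quantities ``r``, ``z``,
    ``hcand``, ``h_prev``, ``x`` for the step; ``weights`` must provide
    ``Wxh``, ``Whh``, ``bh``.
    """
    required = ("r", "z", "hcand", "h_prev", "x")
    missing = [k for k in required if k not in step_cache]
    if missing:
        raise StateError(f"GRU step cache lacks {missing}; run the forward pass first")
    r, z, hcand, h_prev, x = (np.asarray(step_cache[k], dtype=float) for k in required)

    c_carry = (1.0 - z) * h_prev
    c_cand = z * hcand
    denom = _stabilize(c_carry + c_cand, epsilon)
    R_carry = R_ht * c_carry / denom
    R_cand = R_ht * c_cand / denom

    W_cat = np.vstack([weights["Wxh"], weights["Whh"]])
    x_cat = np.concatenate([x, r * h_prev])
    R_cat = lrp_linear(x_cat, W_cat, weights["bh"], R_cand, epsilon)
    R_x = R_cat[: x.size]
    R_h_prev = R_carry + R_cat[x.size :]
    return R_h_prev, R_x


def lrp_gcn(
    graph: ServeGraph,
    X: np.ndarray,
    W: np.ndarray,
    b: np.ndarray,
    R_out: np.ndarray,
    epsilon: float = 1e-6,
) -> np.ndarray:
    """Epsilon rule through one graph convolution, redistributing relevance
    across neighbor nodes and input features simultaneously."""
    X = np.asarray(X, dtype=float)
    W = np.asarray(W, dtype=float)
    R_out = np.asarray(R_out, dtype=float)
    a_hat = _a_hat(graph)
    if X.shape[0] != a_hat.shape[0] or W.shape[0] != X.shape[1]:
        raise ArgumentError("lrp_gcn shape mismatch between graph, X, and W")
    if R_out.shape != (X.shape[0], W.shape[1]):
        raise ArgumentError("R_out must be n_nodes x out_width")
    Z = a_hat @ X @ W + np.asarray(b, dtype=float)
    S = R_out / _stabilize(Z, epsilon)
    return X * (a_hat.T @ (S @ W.T))


def explain(
    model: TrainState | MomentNet,
    graph: ServeGraph,
    epsilon: float = 1e-6,
    output_weights: np.ndarray | None = None,
) -> RelevanceMap:
    """Back-propagate relevance from the predicted curve to the inputs.

    By default every output node is seeded with its own predicted value
    (scaled-target space), giving signed, magnitude-weighted attributions;
    pass ``output_weights`` (e.g. all ones) for uniform seeding.
    """
    net = model.net if isinstance(model, TrainState) else model
    cache = net.forward_cached(graph)
    p = net.params
    y = cache["y"]
    T = y.size

    if output_weights is None:
        R0 = y.copy()
        seeding = "predicted"
    else:
        R0 = np.asarray(output_weights, dtype=float).ravel()
        if R0.shape != (T,):
            raise ArgumentError("output_weights must have one value per output node")
        seeding = "custom"

    # head: y_t = h_t . w + b, relevance of each scalar back onto h_t
    denom_y = _stabilize(y, epsilon)
    R_head = cache["h"] * p["head_w"][None, :] * (R0 / denom_y)[:, None]

    weights = {"Wxh": p["Wxh"], "Whh": p["Whh"], "bh": p["bh"]}
    S = cache["gru_input"]
    R_x = np.zeros_like(S)
    R_next = np.zeros(net.config.gru_width)
    for t in range(T - 1, -1, -1):
        step_cache = {
            "r": cache["r"][t],
            "z": cache["z"][t],
            "hcand": cache["hcand"][t],
            "h_prev": cache["h_prev"][t],
            "x": S[t],
        }
        R_next, R_x[t] = lrp_gru_step(
            step_cache, weights, R_head[t] + R_next, epsilon
        )

    R = R_x
    if not net.config.baseline_mode:
        for layer in range(net.config.n_gcn_layers - 1, -1, -1):
            R = lrp_gcn(
                graph,
                cache["gcn_inputs"][layer],
                p[f"gcn{layer}_W"],
                p[f"gcn{layer}_b"],
                R,
                epsilon,
            )

    if not np.all(np.isfinite(R)):
        raise NumericalError("non-finite relevance at the input layer")

    normalized = _minmax(np.abs(R))
    return RelevanceMap(
        raw=R,
        normalized=normalized,
        epsilon=epsilon,
        explained_output={
            "seeding": seeding,
            "space": "scaled-target",
            "total_initial_relevance": float(R0.sum()),
            "n_outputs": int(T),
        },
    )


def _minmax(values: np.ndarray, axis=None) -> np.ndarray:
    lo = values.min(axis=axis, keepdims=axis is not None)
    hi = values.max(axis=axis, keepdims=axis is not None)
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(span > 0, (values - lo) / np.where(span > 0, span, 1.0), 0.0)
    return out


def aggregate_and_normalize(
    maps: list[RelevanceMap], method: str = "global"
) -> np.ndarray:
    """Mean absolute relevance across maps, min-max normalized to [0, 1].

    ``global`` normalizes over the whole 101 x 6 array; ``per_feature``
    normalizes each feature column independently.  Constant input maps
    yield all zeros by convention.
    """
    if not maps:
        raise ArgumentError("need at least one relevance map to aggregate")
    shapes = {m.raw.shape for m in maps}
    if len(shapes) != 1:
        raise ArgumentError("relevance maps have inconsistent shapes")
    mean_abs = np.mean([np.abs(m.raw) for m in maps], axis=0)
    if method == "global":
        return _minmax(mean_abs)
    if method == "per_feature":
        return _minmax(mean_abs, axis=0)
    raise ArgumentError(f"unknown normalization method {method!r}")


def phase_contribution_summary(
    curves: np.ndarray, phase_labels: np.ndarray
) -> pd.DataFrame:
    """Mean contribution per feature within each PP/FP/LP node partition."""
    labels = np.asarray([str(x) for x in phase_labels])
    rows = {}
    for phase in ("PP", "FP", "LP"):
        mask = labels == phase
        rows[phase] = curves[mask].mean(axis=0)
    return pd.DataFrame(rows, index=list(JOINTS))


def write_contributions_csv(
    curves: np.ndarray,
    path: str | Path,
    sidecar: dict | None = None,
) -> None:
    """101 x 7 contribution CSV plus a JSON sidecar with provenance."""
    df = pd.DataFrame(curves, columns=list(JOINTS))
    df.insert(0, "node_index", np.arange(curves.shape[0]))
    df.to_csv(path, index=False, float_format="%.12g", encoding="utf-8")
    if sidecar is not None:
        Path(str(path) + ".json").write_text(
            json.dumps(sidecar, indent=2, sort_keys=True), encoding="utf-8"
        )
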