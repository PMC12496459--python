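"""Spatiotemporal regression model: a stack of symmetric-normalized graph
convolutions with ReLU, a GRU over the 101 temporal nodes, and a shared
affine head mapping each hidden state to one scalar of the moment curve.

Implemented directly on NumPy with hand-derived gradients.  This keeps the
full forward cache available to the relevance-propagation engine and avoids
any heavyweight deep-learning dependency.

Conventions (documented because libraries differ):

* graph convolution: ``H' = D^-1/2 (A + I) D^-1/2 H W + b`` with self-loops
  always added for normalization, edge attributes ignored (all ones means
  uniform weighting);
* GRU update gate gates the candidate:
  ``h_t = (1 - z_t) * h_{t-1} + z_t * htilde_t``;
* weight init: uniform in ``+- 1/sqrt(fan_in)`` (torch-style), seeded.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit

from .errors import ArgumentError, ConfigurationError, DataError, TrainingError
from .graph import ServeGraph
from .preprocess import SplitIndices

CHECKPOINT_FORMAT = "kneeload-checkpoint-v1"


@dataclass
class ModelConfig:
    n_gcn_layers: int = 3
    gcn_width: int = 64
    gru_width: int = 64
    learning_rate: float = 0.001
    epochs: int = 100
    loss_name: str = "mse"
    seed: int = 0
    baseline_mode: bool = False
    scale_inputs: bool = True
    scale_target: bool = True

    def __post_init__(self) -> None:
        if self.gcn_width < 1 or self.gru_width < 1 or self.n_gcn_layers < 0:
            raise ConfigurationError("layer widths/counts must be positive")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.loss_name != "mse":
            raise ConfigurationError(f"unsupported loss {self.loss_name!r}")


def dense_normalized_adjacency(graph: ServeGraph) -> np.ndarray:
    """Dense ``D^-1/2 (A + I) D^-1/2`` from the graph's edge list.

    A self-loop is added to every node that lacks one, so graphs built with
    or without explicit self-loops normalize identically.
    """
    n = graph.n_nodes
    A = np.zeros((n, n))
    A[graph.edge_index[0], graph.edge_index[1]] = 1.0
    np.fill_diagonal(A, 1.0)
    deg = A.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    return A * np.outer(d_inv_sqrt, d_inv_sqrt)


def _a_hat(graph: ServeGraph) -> np.ndarray:
    cached = getattr(graph, "_a_hat_cache", None)
    if cached is None:
        cached = dense_normalized_adjacency(graph)
        graph._a_hat_cache = cached  # type: ignore[attr-defined]
    return cached


def gcn_forward(
    graph: ServeGraph,
    weights: np.ndarray,
    bias: np.ndarray,
    relu: bool = False,
) -> np.ndarray:
    """One graph-convolution layer on the graph's node features."""
    X = graph.node_features
    weights = np.asarray(weights, dtype=float)
    bias = np.asarray(bias, dtype=float)
    if weights.ndim != 2 or weights.shape[0] != X.shape[1]:
        raise ArgumentError(
            f"weight shape {weights.shape} incompatible with {X.shape[1]} features"
        )
    if bias.shape != (weights.shape[1],):
        raise ArgumentError("bias shape must match output width")
    out = _a_hat(graph) @ X @ weights + bias
    return np.maximum(out, 0.0) if relu else out


def _uniform_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, shape)


class MomentNet:
    """GCN-stack + GRU + affine head (or plain GRU in baseline mode)."""

    GRU_KEYS = ("Wxr", "Whr", "br", "Wxz", "Whz", "bz", "Wxh", "Whh", "bh")

    def __init__(self, config: ModelConfig, n_features: int = 6):
        self.config = config
        self.n_features = n_features
        self.feature_mean = np.zeros(n_features)
        self.feature_std = np.ones(n_features)
        self.target_mean = 0.0
        self.target_std = 1.0
        self.params: dict[str, np.ndarray] = {}
        self._init_params()

    # -- parameters ---------------------------------------------------------

    def _init_params(self) -> None:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        p: dict[str, np.ndarray] = {}
        width_in = self.n_features
        if not cfg.baseline_mode:
            for layer in range(cfg.n_gcn_layers):
                p[f"gcn{layer}_W"] = _uniform_init(
                    rng, (width_in, cfg.gcn_width), width_in
                )
                p[f"gcn{layer}_b"] = _uniform_init(rng, (cfg.gcn_width,), width_in)
                width_in = cfg.gcn_width
        H = cfg.gru_width
        for gate in ("r", "z", "h"):
            p[f"Wx{gate}"] = _uniform_init(rng, (width_in, H), width_in)
            p[f"Wh{gate}"] = _uniform_init(rng, (H, H), H)
            p[f"b{gate}"] = _uniform_init(rng, (H,), H)
        p["head_w"] = _uniform_init(rng, (H,), H)
        p["head_b"] = _uniform_init(rng, (1,), H)[0:1]
        self.params = p
        self.gru_input_dim = width_in

    # -- scaling ------------------------------------------------------------

    def fit_scalers(self, graphs: list[ServeGraph]) -> None:
        X = np.concatenate([g.node_features for g in graphs], axis=0)
        y = np.concatenate([g.target for g in graphs])
        if self.config.scale_inputs:
            self.feature_mean = X.mean(axis=0)
            self.feature_std = np.where(X.std(axis=0) > 1e-12, X.std(axis=0), 1.0)
        if self.config.scale_target:
            self.target_mean = float(y.mean())
            sd = float(y.std())
            self.target_std = sd if sd > 1e-12 else 1.0

    def scale_features(self, X: np.ndarray) -> np.ndarray:
        return (X - self.feature_mean) / self.feature_std

    def scale_target(self, y: np.ndarray) -> np.ndarray:
        return (y - self.target_mean) / self.target_std

    def unscale_target(self, y: np.ndarray) -> np.ndarray:
        return y * self.target_std + self.target_mean

    # -- forward ------------------------------------------------------------

    def forward_cached(self, graph: ServeGraph) -> dict:
        """Full forward pass with every intermediate needed for backprop
        and relevance propagation.  Output ``y`` is in scaled target space."""
        cfg = self.config
        p = self.params
        X = self.scale_features(graph.node_features)
        cache: dict = {"X_scaled": X, "graph": graph}

        H_nodes = X
        if not cfg.baseline_mode:
            a_hat = _a_hat(graph)
            cache["a_hat"] = a_hat
            gcn_inputs, gcn_pre = [], []
            for layer in range(cfg.n_gcn_layers):
                gcn_inputs.append(H_nodes)
                Z = a_hat @ H_nodes @ p[f"gcn{layer}_W"] + p[f"gcn{layer}_b"]
                gcn_pre.append(Z)
                H_nodes = np.maximum(Z, 0.0)
            cache["gcn_inputs"] = gcn_inputs
            cache["gcn_pre"] = gcn_pre
        cache["gru_input"] = H_nodes

        T = H_nodes.shape[0]
        Hd = cfg.gru_width
        # time-major precomputation of the input projections; the r and z
        # gates share one matvec per step via concatenated hidden weights
        xrz = np.concatenate(
            [H_nodes @ p["Wxr"] + p["br"], H_nodes @ p["Wxz"] + p["bz"]], axis=1
        )
        xh = H_nodes @ p["Wxh"] + p["bh"]
        W_hrz = np.concatenate([p["Whr"], p["Whz"]], axis=1)
        r = np.empty((T, Hd))
        z = np.empty((T, Hd))
        hcand = np.empty((T, Hd))
        h_prev_arr = np.empty((T, Hd))
        h_arr = np.empty((T, Hd))
        a_cand = np.empty((T, Hd))
        h = np.zeros(Hd)
        for t in range(T):
            h_prev_arr[t] = h
            rz = expit(xrz[t] + h @ W_hrz)
            r[t] = rz[:Hd]
            z[t] = rz[Hd:]
            a_cand[t] = xh[t] + (rz[:Hd] * h) @ p["Whh"]
            hcand[t] = np.tanh(a_cand[t])
            h = (1.0 - rz[Hd:]) * h + rz[Hd:] * hcand[t]
            h_arr[t] = h
        cache.update(
            r=r, z=z, hcand=hcand, a_cand=a_cand, h_prev=h_prev_arr, h=h_arr
        )
        cache["y"] = h_arr @ p["head_w"] + p["head_b"][0]
        return cache

    def forward(self, graph: ServeGraph) -> np.ndarray:
        """Predicted 1 x 101 moment curve in physical units."""
        if graph.node_features.shape[1] != self.n_features:
            raise DataError("graph feature width does not match the model")
        return self.unscale_target(self.forward_cached(graph)["y"])

    # -- backward -----------------------------------------------------------

    def backward(self, cache: dict, dy: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of a scalar loss wrt all parameters given dL/dy."""
        cfg = self.config
        p = self.params
        grads = {k: np.zeros_like(v) for k, v in p.items()}

        h_arr, h_prev = cache["h"], cache["h_prev"]
        r, z, hcand = cache["r"], cache["z"], cache["hcand"]
        S = cache["gru_input"]
        T = S.shape[0]

        grads["head_w"] = h_arr.T @ dy
        grads["head_b"] = np.array([dy.sum()])
        dh_arr = np.outer(dy, p["head_w"])  # T x H

        # the loop only resolves the recurrent dependency; all weight
        # gradients are accumulated as matmuls afterwards
        Whh_T = p["Whh"].T
        W_hrz_back = np.concatenate([p["Whr"].T, p["Whz"].T], axis=0)  # (2H, H)
        da_r = np.empty((T, self.config.gru_width))
        da_z = np.empty_like(da_r)
        da_h = np.empty_like(da_r)
        gh = np.zeros(self.config.gru_width)
        for t in range(T - 1, -1, -1):
            gh = gh + dh_arr[t]
            hp = h_prev[t]
            zt, rt, hct = z[t], r[t], hcand[t]
            da_h[t] = (gh * zt) * (1.0 - hct**2)
            d_rh = da_h[t] @ Whh_T
            da_r[t] = (d_rh * hp) * rt * (1.0 - rt)
            da_z[t] = (gh * (hct - hp)) * zt * (1.0 - zt)
            gh = (
                gh * (1.0 - zt)
                + d_rh * rt
                + np.concatenate([da_r[t], da_z[t]]) @ W_hrz_back
            )

        grads["Wxr"] = S.T @ da_r
        grads["Wxz"] = S.T @ da_z
        grads["Wxh"] = S.T @ da_h
        grads["Whr"] = h_prev.T @ da_r
        grads["Whz"] = h_prev.T @ da_z
        grads["Whh"] = (r * h_prev).T @ da_h
        grads["br"] = da_r.sum(axis=0)
        grads["bz"] = da_z.sum(axis=0)
        grads["bh"] = da_h.sum(axis=0)
        dS = da_h @ p["Wxh"].T + da_r @ p["Wxr"].T + da_z @ p["Wxz"].T

        if not cfg.baseline_mode:
            a_hat = cache["a_hat"]
            dH = dS
            for layer in range(cfg.n_gcn_layers - 1, -1, -1):
                dZ = dH * (cache["gcn_pre"][layer] > 0)
                AX = a_hat @ cache["gcn_inputs"][layer]
                grads[f"gcn{layer}_W"] = AX.T @ dZ
                grads[f"gcn{layer}_b"] = dZ.sum(axis=0)
                dH = a_hat.T @ (dZ @ p[f"gcn{layer}_W"].T)
        return grads

    # -- persistence --------------------------------------------------------

    def to_payload(self) -> dict:
        return {
            "format": CHECKPOINT_FORMAT,
            "config": asdict(self.config),
            "n_features": self.n_features,
            "feature_mean": self.feature_mean.tolist(),
            "feature_std": self.feature_std.tolist(),
            "target_mean": self.target_mean,
            "target_std": self.target_std,
            "params": {k: v.tolist() for k, v in self.params.items()},
        }

    @classmethod
    def from_payload(cls, payload: dict) -> "MomentNet":
        if payload.get("format") != CHECKPOINT_FORMAT:
            raise DataError(
                f"unknown checkpoint format {payload.get('format')!r}"
            )
        net = cls(ModelConfig(**payload["config"]), payload["n_features"])
        net.feature_mean = np.asarray(payload["feature_mean"], dtype=float)
        net.feature_std = np.asarray(payload["feature_std"], dtype=float)
        net.target_mean = float(payload["target_mean"])
        net.target_std = float(payload["target_std"])
        net.params = {k: np.asarray(v, dtype=float) for k, v in payload["params"].items()}
        return net


@dataclass
class TrainState:
    net: MomentNet
    loss_history: list[dict] = field(default_factory=list)
    best_epoch: int = 0
    config: ModelConfig = field(default_factory=ModelConfig)

    def save(self, path: str | Path) -> None:
        payload = self.net.to_payload()
        payload["loss_history"] = self.loss_history
        payload["best_epoch"] = self.best_epoch
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "TrainState":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        net = MomentNet.from_payload(payload)
        return cls(
            net=net,
            loss_history=payload.get("loss_history", []),
            best_epoch=int(payload.get("best_epoch", 0)),
            config=net.config,
        )


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps
            )


def _mean_mse(net: MomentNet, graphs: list[ServeGraph], idx: np.ndarray) -> float:
    total = 0.0
    for i in idx:
        y = net.forward_cached(graphs[i])["y"]
        t = net.scale_target(graphs[i].target)
        total += float(np.mean((y - t) ** 2))
    return total / max(len(idx), 1)


def train(
    graphs: list[ServeGraph],
    config: ModelConfig,
    split: SplitIndices,
) -> TrainState:
    """Adam on per-graph MSE over the training split.

    One optimizer step per graph, graphs visited in a seeded shuffled order
    each epoch; training and validation losses (scaled space) are recorded
    per epoch.
    """
    if len(split.train) == 0:
        raise ArgumentError("training split is empty")
    net = MomentNet(config, n_features=graphs[0].node_features.shape[1])
    net.fit_scalers([graphs[i] for i in split.train])
    adam = _Adam(net.params, config.learning_rate)
    order_rng = np.random.default_rng(config.seed + 1)

    history: list[dict] = []
    for epoch in range(config.epochs):
        order = order_rng.permutation(split.train)
        epoch_loss = 0.0
        for i in order:
            g = graphs[i]
            cache = net.forward_cached(g)
            resid = cache["y"] - net.scale_target(g.target)
            loss = float(np.mean(resid**2))
            if not np.isfinite(loss):
                raise TrainingError(
                    f"training loss became non-finite at epoch {epoch}", epoch=epoch
                )
            epoch_loss += loss
            grads = net.backward(cache, 2.0 * resid / resid.size)
            adam.step(net.params, grads)
        val_loss = (
            _mean_mse(net, graphs, split.validation)
            if len(split.validation)
            else None
        )
        history.append(
            {
                "epoch": epoch,
                "train_loss": epoch_loss / len(order),
                "val_loss": val_loss,
            }
        )

    val_curve = [h["val_loss"] for h in history]
    if all(v is None for v in val_curve):
        best_epoch = int(np.argmin([h["train_loss"] for h in history]))
    else:
        best_epoch = int(
            np.argmin([np.inf if v is None else v for v in val_curve])
        )
    return TrainState(net=net, loss_history=history, best_epoch=best_epoch, config=config)


def evaluate_mse(state: TrainState, graphs: list[ServeGraph], idx: np.ndarray) -> float:
    """Mean scaled-space MSE of a trained model over the given indices."""
    return _mean_mse(state.net, graphs, np.asarray(idx))
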