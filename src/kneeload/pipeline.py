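"""Pipeline orchestration: simulate -> preprocess -> train -> explain ->
evaluate -> report, with per-stage manifests (parameters, seed, content
hashes) for reproducibility."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ArgumentError, ConfigurationError
from .graph import build_graph
from .lrp import (
    aggregate_and_normalize,
    explain,
    phase_contribution_summary,
    write_contributions_csv,
)
from .model import ModelConfig, TrainState, train
from .preprocess import (
    assemble_matrices,
    read_normalized_csv,
    split_dataset,
    write_normalized_csv,
)
from .stats import cohens_d_pooled, paired_t, regression_metrics, spm_paired_t
from .synthetic import (
    JOINTS,
    config_from_dict,
    read_dataset,
    simulate_dataset,
    write_dataset,
)

log = logging.getLogger("kneeload")

STAGES = ("simulate", "preprocess", "train", "explain", "evaluate", "report")


@dataclass
class RunConfig:
    out_dir: Path
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    simulate: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)
    train: dict = field(default_factory=dict)
    explain: dict = field(default_factory=dict)
    evaluate: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ConfigurationError(f"unknown stages: {bad}")

    @classmethod
    def from_yaml(cls, path: str | Path, out_dir: str | Path | None = None) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if out_dir is not None:
            payload["out_dir"] = out_dir
        if "stages" in payload:
            payload["stages"] = tuple(payload["stages"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ConfigurationError(f"unknown run options: {sorted(unknown)}")
        return cls(**payload)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(stage_dir: Path, stage: str, params: dict, seed: int, outputs: list[Path]) -> None:
    manifest = {
        "stage": stage,
        "seed": seed,
        "params": params,
        "package_version": __version__,
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
    }
    (stage_dir / "stage_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )


def _require(paths: list[Path], stage: str) -> None:
    missing = [str(p) for p in paths if not p.exists()]
    if missing:
        raise ArgumentError(f"stage {stage!r} requires missing artifacts: {missing}")


def _stage_simulate(config: RunConfig) -> None:
    params = dict(config.simulate)
    params.setdefault("seed", config.seed)
    sim_config = config_from_dict(params)
    out = config.out_dir / "simulate"
    trials = simulate_dataset(sim_config)
    write_dataset(trials, out)
    outputs = sorted(out.glob("*.csv"))
    _write_manifest(out, "simulate", {k: str(v) for k, v in params.items()}, config.seed, outputs)
    log.info("simulate: wrote %d trials to %s", len(trials), out)


def _stage_preprocess(config: RunConfig) -> None:
    src = config.out_dir / "simulate" / "manifest.csv"
    _require([src], "preprocess")
    params = dict(config.preprocess)
    cutoff = params.get("cutoff", 10.0)
    order = params.get("order", 4)
    fold_id = params.get("fold_id", 0)
    group_by_participant = params.get("group_by_participant", True)

    trials = read_dataset(src)
    out = config.out_dir / "preprocess"
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for trial in trials:
        norm = assemble_matrices(trial, cutoff=cutoff, order=order)
        name = f"norm_p{trial.participant_id:03d}_t{trial.trial_id:03d}.csv"
        write_normalized_csv(norm, out / name)
        rows.append(
            {
                "participant_id": trial.participant_id,
                "trial_id": trial.trial_id,
                "path": name,
            }
        )
    manifest_df = pd.DataFrame(rows)
    manifest_df.to_csv(out / "manifest.csv", index=False, encoding="utf-8")

    groups = manifest_df["participant_id"].to_numpy() if group_by_participant else None
    split = split_dataset(
        len(trials), fold_id=fold_id, seed=config.seed, groups=groups
    )
    (out / "split.json").write_text(
        json.dumps(
            {
                "fold_id": fold_id,
                "seed": config.seed,
                "train": split.train.tolist(),
                "validation": split.validation.tolist(),
                "test": split.test.tolist(),
            },
            indent=2,
        ),
        encoding="utf-8",
    )
    _write_manifest(out, "preprocess", params, config.seed, sorted(out.glob("*.csv")) + [out / "split.json"])
    log.info("preprocess: normalized %d trials", len(trials))


def _load_graphs(config: RunConfig):
    pre = config.out_dir / "preprocess"
    _require([pre / "manifest.csv", pre / "split.json"], "train/explain/evaluate")
    manifest = pd.read_csv(pre / "manifest.csv")
    normalized = [
        read_normalized_csv(pre / row.path, int(row.participant_id), int(row.trial_id))
        for row in manifest.itertuples()
    ]
    graphs = [build_graph(n) for n in normalized]
    split_payload = json.loads((pre / "split.json").read_text(encoding="utf-8"))
    from .preprocess import SplitIndices

    split = SplitIndices(
        train=np.array(split_payload["train"], dtype=int),
        validation=np.array(split_payload["validation"], dtype=int),
        test=np.array(split_payload["test"], dtype=int),
        fold_id=int(split_payload["fold_id"]),
        seed=int(split_payload["seed"]),
    )
    return normalized, graphs, split


def _stage_train(config: RunConfig) -> None:
    _, graphs, split = _load_graphs(config)
    params = dict(config.train)
    params.setdefault("seed", config.seed)
    model_config = ModelConfig(**params)
    out = config.out_dir / "train"
    out.mkdir(parents=True, exist_ok=True)

    state = train(graphs, model_config, split)
    state.save(out / "model.json")
    baseline_config = dataclasses.replace(model_config, baseline_mode=True)
    baseline_state = train(graphs, baseline_config, split)
    baseline_state.save(out / "baseline.json")

    pd.DataFrame(state.loss_history).to_csv(out / "loss_history.csv", index=False)
    pd.DataFrame(baseline_state.loss_history).to_csv(
        out / "baseline_loss_history.csv", index=False
    )
    _write_manifest(
        out,
        "train",
        {k: str(v) for k, v in params.items()},
        config.seed,
        [out / "model.json", out / "baseline.json", out / "loss_history.csv", out / "baseline_loss_history.csv"],
    )
    log.info("train: fitted model (best epoch %d) and baseline", state.best_epoch)


def _stage_explain(config: RunConfig) -> None:
    normalized, graphs, split = _load_graphs(config)
    model_path = config.out_dir / "train" / "model.json"
    _require([model_path], "explain")
    params = dict(config.explain)
    epsilon = params.get("epsilon", 1e-6)
    norm = params.get("norm", "global")

    state = TrainState.load(model_path)
    maps = [explain(state, graphs[i], epsilon=epsilon) for i in split.test]
    curves = aggregate_and_normalize(maps, method=norm)
    out = config.out_dir / "explain"
    out.mkdir(parents=True, exist_ok=True)
    write_contributions_csv(
        curves,
        out / "contributions.csv",
        sidecar={
            "epsilon": epsilon,
            "normalization": norm,
            "seeding": "predicted",
            "n_trials_averaged": len(maps),
            "seed": config.seed,
        },
    )
    labels = normalized[split.test[0]].phase_labels
    phase_contribution_summary(curves, labels).to_csv(out / "phase_summary.csv")
    _write_manifest(
        out, "explain", params, config.seed,
        [out / "contributions.csv", out / "phase_summary.csv"],
    )
    log.info("explain: aggregated %d relevance maps", len(maps))


def _stage_evaluate(config: RunConfig) -> None:
    _, graphs, split = _load_graphs(config)
    train_dir = config.out_dir / "train"
    _require([train_dir / "model.json", train_dir / "baseline.json"], "evaluate")
    params = dict(config.evaluate)
    alpha = params.get("alpha", 0.05)
    spm_mode = params.get("spm", "rft")

    states = {
        "gnn_gru": TrainState.load(train_dir / "model.json"),
        "gru": TrainState.load(train_dir / "baseline.json"),
    }
    rows = []
    curves: dict[str, list[np.ndarray]] = {name: [] for name in states}
    actual = []
    for i in split.test:
        g = graphs[i]
        actual.append(g.target)
        for name, state in states.items():
            pred = state.net.forward(g)
            curves[name].append(pred)
            mae, mse, r2 = regression_metrics(g.target, pred)
            rows.append(
                {"trial_index": int(i), "model": name, "mae": mae, "mse": mse, "r2": r2}
            )
    metrics = pd.DataFrame(rows)
    out = config.out_dir / "evaluate"
    out.mkdir(parents=True, exist_ok=True)
    metrics.to_csv(out / "metrics.csv", index=False, float_format="%.12g")

    comparison_rows = []
    for metric in ("mae", "mse", "r2"):
        a = metrics.loc[metrics["model"] == "gnn_gru", metric].to_numpy()
        b = metrics.loc[metrics["model"] == "gru", metric].to_numpy()
        t, p, normal = paired_t(a, b)
        d = cohens_d_pooled(a.mean(), a.std(ddof=1), b.mean(), b.std(ddof=1))
        comparison_rows.append(
            {
                "metric": metric,
                "gnn_gru_mean": a.mean(),
                "gnn_gru_sd": a.std(ddof=1),
                "gru_mean": b.mean(),
                "gru_sd": b.std(ddof=1),
                "t": t,
                "p": p,
                "normality": normal,
                "cohens_d": d,
            }
        )
    pd.DataFrame(comparison_rows).to_csv(
        out / "comparison.csv", index=False, float_format="%.12g"
    )

    spm = spm_paired_t(
        np.vstack(curves["gnn_gru"]), np.vstack(actual), alpha=alpha,
        mode=spm_mode, seed=config.seed,
    )
    (out / "spm.json").write_text(
        json.dumps(
            {
                "t_field": spm.t_field.tolist(),
                "dof": spm.dof,
                "fwhm_estimate": spm.fwhm_estimate,
                "critical_t": spm.critical_t,
                "clusters": spm.clusters,
                "alpha": spm.alpha,
                "mode": spm.mode,
            },
            indent=2,
        ),
        encoding="utf-8",
    )
    _write_manifest(
        out, "evaluate", params, config.seed,
        [out / "metrics.csv", out / "comparison.csv", out / "spm.json"],
    )
    log.info("evaluate: %d test trials, SPM clusters: %d", len(split.test), len(spm.clusters))


def run_pipeline(config: RunConfig) -> None:
    """Execute the selected stages in canonical order."""
    config.out_dir.mkdir(parents=True, exist_ok=True)
    runners = {
        "simulate": _stage_simulate,
        "preprocess": _stage_preprocess,
        "train": _stage_train,
        "explain": _stage_explain,
        "evaluate": _stage_evaluate,
        "report": lambda cfg: (cfg.out_dir / "report.txt").write_text(
            report(cfg.out_dir), encoding="utf-8"
        ),
    }
    for stage in STAGES:
        if stage in config.stages:
            log.info("running stage %s", stage)
            runners[stage](config)


def report(artifacts_dir: str | Path) -> str:
    """Human-readable summary of a completed pipeline run."""
    base = Path(artifacts_dir)
    needed = {
        "metrics": base / "evaluate" / "metrics.csv",
        "comparison": base / "evaluate" / "comparison.csv",
        "spm": base / "evaluate" / "spm.json",
        "contributions": base / "explain" / "contributions.csv",
        "phase_summary": base / "explain" / "phase_summary.csv",
    }
    missing = [str(p) for p in needed.values() if not p.exists()]
    if missing:
        raise ArgumentError(f"report requires missing artifacts: {missing}")

    comparison = pd.read_csv(needed["comparison"])
    spm = json.loads(needed["spm"].read_text(encoding="utf-8"))
    phase_summary = pd.read_csv(needed["phase_summary"], index_col=0)

    lines = ["kneeload run report", "===================", ""]
    lines.append("Model comparison on the test split (GNN-GRU vs GRU):")
    for row in comparison.itertuples():
        lines.append(
            f"  {row.metric.upper():>4}: {row.gnn_gru_mean:.4f} ({row.gnn_gru_sd:.4f})"
            f"  vs  {row.gru_mean:.4f} ({row.gru_sd:.4f})"
            f"   p = {row.p:.4g}, d = {row.cohens_d:.3f}"
        )
    lines.append("")
    lines.append(
        f"SPM paired t (predicted vs actual): critical |t| = {spm['critical_t']:.3f}"
        f" at alpha = {spm['alpha']}, FWHM = {spm['fwhm_estimate']:.2f} nodes"
    )
    if spm["clusters"]:
        for c in spm["clusters"]:
            lines.append(
                f"  suprathreshold cluster nodes {c['start']}..{c['end']} (p = {c['p']:.4g})"
            )
    else:
        lines.append("  no suprathreshold clusters (predicted ~ actual, p > alpha)")
    lines.append("")
    lines.append("Mean normalized contribution per feature and phase:")
    header = "  feature      " + "".join(f"{p:>8}" for p in phase_summary.columns)
    lines.append(header)
    for feature in JOINTS:
        vals = phase_summary.loc[feature]
        lines.append(
            f"  {feature:<12} " + "".join(f"{vals[p]:8.3f}" for p in phase_summary.columns)
        )
    return "\n".join(lines) + "\n"
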