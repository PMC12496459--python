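"""Signal chain: low-pass filtering, 101-point time normalization,
resultant-moment computation, ratio-based dataset splitting, and assembly
of the 6 x 101 / 1 x 101 model matrices."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import interpolate, signal

from .errors import ArgumentError, DataError
from .synthetic import JOINTS, PHASES, ServeTrial

N_NODES = 101


@dataclass
class NormalizedTrial:
    """Time-normalized model matrices for one serve."""

    angles: np.ndarray  # 6 x 101, degrees
    resultant_moment: np.ndarray  # 101, N*m, nonnegative
    phase_labels: np.ndarray  # 101 strings in {"PP", "FP", "LP"}
    participant_id: int = 0
    trial_id: int = 0

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.resultant_moment = np.asarray(self.resultant_moment, dtype=float).ravel()
        self.phase_labels = np.asarray(self.phase_labels, dtype=object)
        if self.angles.shape != (6, N_NODES):
            raise DataError(f"angles must be 6 x {N_NODES}, got {self.angles.shape}")
        if self.resultant_moment.shape != (N_NODES,):
            raise DataError("resultant_moment must have 101 samples")
        if np.any(self.resultant_moment < 0):
            raise DataError("resultant moment must be nonnegative")
        if self.phase_labels.shape != (N_NODES,):
            raise DataError("phase_labels must have 101 entries")
        labels = [str(x) for x in self.phase_labels]
        order = [labels[0]]
        for lab in labels[1:]:
            if lab != order[-1]:
                order.append(lab)
        if order != list(PHASES[: len(order)]):
            raise DataError("phase labels must partition nodes contiguously PP/FP/LP")

    def phase_index(self) -> np.ndarray:
        lookup = {name: i for i, name in enumerate(PHASES)}
        return np.array([lookup[str(x)] for x in self.phase_labels], dtype=int)


@dataclass(frozen=True)
class SplitIndices:
    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    fold_id: int
    seed: int

    def __post_init__(self) -> None:
        sets = [set(self.train), set(self.validation), set(self.test)]
        n = sum(len(s) for s in sets)
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise DataError("split partitions overlap")
        if sets[0] | sets[1] | sets[2] != set(range(n)):
            raise DataError("split partitions do not cover all trial indices")


def lowpass_filter(
    series: np.ndarray,
    fs: float,
    cutoff: float = 10.0,
    order: int = 4,
    zero_phase: bool = True,
) -> np.ndarray:
    """Butterworth low-pass. Zero-phase (forward-backward) by default, which
    doubles the effective attenuation: the net gain at ``f`` is
    ``1 / (1 + (f/cutoff)^(2*order))``.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ArgumentError("lowpass_filter expects a 1-D series")
    if not 0 < cutoff < fs / 2:
        raise ArgumentError(
            f"cutoff must lie in (0, Nyquist)={fs / 2}; got {cutoff}"
        )
    if np.any(~np.isfinite(series)):
        raise DataError("series contains NaN or infinite values")
    if series.size <= 3 * order:
        raise DataError("series too short for the requested filter order")
    sos = signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
    if zero_phase:
        return signal.sosfiltfilt(sos, series)
    return signal.sosfilt(sos, series)


def time_normalize(
    series: np.ndarray, n: int = N_NODES, method: str = "pchip"
) -> np.ndarray:
    """Resample a series onto ``n`` uniformly spaced points over its span.

    ``pchip`` (monotone cubic) is the default; ``linear`` is available.
    Endpoints are preserved exactly.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or series.size < 2:
        raise DataError("time_normalize needs a 1-D series of length >= 2")
    x = np.linspace(0.0, 1.0, series.size)
    xi = np.linspace(0.0, 1.0, n)
    if method == "pchip":
        out = interpolate.PchipInterpolator(x, series)(xi)
    elif method == "linear":
        out = np.interp(xi, x, series)
    else:
        raise ArgumentError(f"unknown interpolation method {method!r}")
    out[0], out[-1] = series[0], series[-1]
    return out


def resultant_moment(
    mx: np.ndarray, my: np.ndarray, mz: np.ndarray
) -> np.ndarray:
    """Pointwise Euclidean norm of the three moment components."""
    mx, my, mz = (np.asarray(m, dtype=float) for m in (mx, my, mz))
    if not (mx.shape == my.shape == mz.shape):
        raise DataError("moment components must have identical lengths")
    if any(np.any(~np.isfinite(m)) for m in (mx, my, mz)):
        raise DataError("moment components contain non-finite values")
    return np.sqrt(mx**2 + my**2 + mz**2)


def split_dataset(
    n_trials: int,
    ratio: tuple[int, int, int] = (8, 1, 1),
    fold_id: int = 0,
    seed: int = 0,
    groups: np.ndarray | None = None,
) -> SplitIndices:
    """Rotating-block split after a seeded shuffle.

    Trials (or whole groups, when ``groups`` is given) are shuffled once and
    cut into ``sum(ratio)`` contiguous blocks with boundaries at
    ``floor(n * b / k)``; fold ``f`` uses block ``f mod k`` (and the next
    ``ratio[2] - 1`` blocks) as test, the following ``ratio[1]`` blocks as
    validation, the rest as training.  Over ``k`` fold ids every trial
    appears in the test set exactly ``ratio[2]`` times.
    """
    if n_trials < 10:
        raise ArgumentError("need at least 10 trials to split 8:1:1")
    ratio = tuple(int(r) for r in ratio)
    if len(ratio) != 3 or min(ratio) < 1:
        raise ArgumentError("ratio must be three positive integers")
    k = sum(ratio)
    rng = np.random.default_rng(seed)

    if groups is None:
        order = rng.permutation(n_trials)
        bounds = [n_trials * b // k for b in range(k + 1)]
        blocks = [order[bounds[b] : bounds[b + 1]] for b in range(k)]
    else:
        groups = np.asarray(groups)
        if groups.shape != (n_trials,):
            raise ArgumentError("groups must have one label per trial")
        uniq = rng.permutation(np.unique(groups))
        blocks_lists: list[list[int]] = [[] for _ in range(k)]
        for g in uniq:
            members = np.flatnonzero(groups == g)
            target = min(range(k), key=lambda b: (len(blocks_lists[b]), b))
            blocks_lists[target].extend(members.tolist())
        blocks = [np.array(b, dtype=int) for b in blocks_lists]

    n_test, n_val = ratio[2], ratio[1]
    test_ids = [(fold_id + i) % k for i in range(n_test)]
    val_ids = [(fold_id + n_test + i) % k for i in range(n_val)]
    rest = [b for b in range(k) if b not in test_ids + val_ids]
    cat = lambda ids: np.sort(np.concatenate([blocks[b] for b in ids])).astype(int)
    return SplitIndices(
        train=cat(rest),
        validation=cat(val_ids),
        test=cat(test_ids),
        fold_id=fold_id,
        seed=seed,
    )


def map_phase_boundaries(
    boundaries: tuple[int, int], n_samples: int, n: int = N_NODES
) -> tuple[int, int]:
    """Nearest-node mapping of raw-sample phase boundaries onto the 0..n-1 grid."""
    b1, b2 = boundaries
    g1 = int(round(b1 / (n_samples - 1) * (n - 1)))
    g2 = int(round(b2 / (n_samples - 1) * (n - 1)))
    g1 = min(max(g1, 1), n - 2)
    g2 = min(max(g2, g1 + 1), n - 1)
    return g1, g2


def phase_labels_from_nodes(g1: int, g2: int, n: int = N_NODES) -> np.ndarray:
    labels = np.empty(n, dtype=object)
    labels[:g1] = "PP"
    labels[g1:g2] = "FP"
    labels[g2:] = "LP"
    return labels


def assemble_matrices(
    trial: ServeTrial,
    cutoff: float = 10.0,
    order: int = 4,
    zero_phase: bool = True,
    interp: str = "pchip",
) -> NormalizedTrial:
    """Filter -> time-normalize -> resultant norm, producing model matrices."""
    fs = trial.sampling_rate_hz
    angles = np.vstack(
        [
            time_normalize(
                lowpass_filter(row, fs, cutoff=cutoff, order=order, zero_phase=zero_phase),
                method=interp,
            )
            for row in trial.angles_raw
        ]
    )
    comps = [
        time_normalize(
            lowpass_filter(row, fs, cutoff=cutoff, order=order, zero_phase=zero_phase),
            method=interp,
        )
        for row in trial.moment_components_raw
    ]
    moment = resultant_moment(*comps)
    g1, g2 = map_phase_boundaries(trial.phase_boundaries, trial.n_samples)
    return NormalizedTrial(
        angles=angles,
        resultant_moment=moment,
        phase_labels=phase_labels_from_nodes(g1, g2),
        participant_id=trial.participant_id,
        trial_id=trial.trial_id,
    )


# ---------------------------------------------------------------------------
# CSV round-trip (101 rows x 8 data columns + phase label)

NORMALIZED_COLUMNS = ["node_index", *JOINTS, "resultant_moment", "phase"]


def write_normalized_csv(trial: NormalizedTrial, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "node_index": np.arange(N_NODES),
            **{name: trial.angles[j] for j, name in enumerate(JOINTS)},
            "resultant_moment": trial.resultant_moment,
            "phase": [str(x) for x in trial.phase_labels],
        }
    )
    df.to_csv(path, index=False, float_format="%.12g", encoding="utf-8")


def read_normalized_csv(
    path: str | Path, participant_id: int = 0, trial_id: int = 0
) -> NormalizedTrial:
    df = pd.read_csv(path)
    missing = [c for c in NORMALIZED_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"normalized CSV {path} lacks columns: {missing}")
    return NormalizedTrial(
        angles=df[list(JOINTS)].to_numpy().T,
        resultant_moment=df["resultant_moment"].to_numpy(),
        phase_labels=df["phase"].to_numpy(dtype=object),
        participant_id=participant_id,
        trial_id=trial_id,
    )
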