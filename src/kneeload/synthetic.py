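"""Synthetic serve-trial generator.

Produces smooth, band-limited bilateral joint-angle curves over a
three-phase movement cycle (preparation / flight / landing) together with
three joint-moment components generated from the angles by a known,
configurable mapping.  Because the generative mapping is known, attribution
methods can be tested for recovery of the true per-phase feature weights.

Generative moment model (evaluated per moment component ``c`` and sample
``t``, with ``p = phase(t)``)::

    m_c[t] = component_scales[c]
             * sum_j G[p, j] * ( (theta_j[t] - baseline_j)
                                 + velocity_coefficient * dtheta_j/dt [t] )
             + noise,   noise ~ N(0, noise_sd)

where ``G`` is the configured per-phase 6-vector of generative weights and
``dtheta/dt`` is the central finite difference (``numpy.gradient``) of the
angle in deg/s.  This exact formula is the oracle contract relied on by the
test suite.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

JOINTS = ("l_ankle", "l_knee", "l_hip", "r_ankle", "r_knee", "r_hip")
PHASES = ("PP", "FP", "LP")
N_JOINTS = 6
N_PHASES = 3

#: Index of the supporting-side knee in the fixed joint ordering.
SUPPORT_KNEE = 1

# Per-joint, per-phase bump coefficients shaping the default angle
# waveforms: rows = joints, columns = PP/FP/LP.  Values are relative
# excursions of each joint within each phase.
DEFAULT_PHASE_SHAPE = np.array(
    [
        [0.5, 1.0, 0.8],  # l_ankle
        [1.0, 0.6, 0.9],  # l_knee
        [0.7, 1.0, 0.6],  # l_hip
        [0.4, 0.9, 0.3],  # r_ankle
        [0.8, 0.7, 0.5],  # r_knee
        [0.6, 1.0, 0.4],  # r_hip
    ]
)

# Per-phase generative feature weights (rows = PP/FP/LP, columns = joints).
# The supporting knee (index 1) is the strict maximum in PP and LP; ankles
# and hips dominate the flight phase.
DEFAULT_GENERATIVE_WEIGHTS = np.array(
    [
        [0.30, 1.00, 0.30, 0.20, 0.40, 0.20],  # PP
        [0.90, 0.50, 0.85, 0.60, 0.30, 0.55],  # FP
        [0.70, 1.00, 0.60, 0.30, 0.50, 0.30],  # LP
    ]
)


@dataclass(frozen=True)
class WaveformParams:
    """Amplitude/baseline/timing description of one joint's angle curve."""

    amplitude_deg: float
    baseline_deg: float
    timing_jitter_sd: float = 0.02


DEFAULT_WAVEFORMS = (
    WaveformParams(25.0, -10.0),  # l_ankle
    WaveformParams(60.0, 20.0),  # l_knee
    WaveformParams(45.0, 15.0),  # l_hip
    WaveformParams(20.0, -8.0),  # r_ankle
    WaveformParams(50.0, 18.0),  # r_knee
    WaveformParams(40.0, 12.0),  # r_hip
)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic serve generator.

    ``seed`` plus (participant_id, trial_id) fully determine a trial;
    participant-level parameters are drawn from a stream keyed by
    (seed, participant_id) only, so every trial of a participant shares
    them.
    """

    n_participants: int = 30
    trials_per_participant: int = 12
    sampling_rate_hz: float = 200.0
    duration_s: float = 1.2
    phase_fractions: tuple[float, float, float] = (0.4, 0.3, 0.3)
    angle_waveform_params: tuple[WaveformParams, ...] = DEFAULT_WAVEFORMS
    phase_shape: np.ndarray = field(
        default_factory=lambda: DEFAULT_PHASE_SHAPE.copy()
    )
    generative_weights: np.ndarray = field(
        default_factory=lambda: DEFAULT_GENERATIVE_WEIGHTS.copy()
    )
    noise_sd: float = 0.5
    seed: int = 0
    between_subject_amp_sd: float = 0.12
    within_subject_amp_sd: float = 0.03
    velocity_coefficient: float = 0.02
    component_scales: tuple[float, float, float] = (1.0, 0.4, 0.2)
    #: SD (deg) of smooth band-limited (2-8 Hz) observation noise added to
    #: the *stored* angles only, mimicking soft-tissue/marker artifact; the
    #: generative moment mapping always uses the latent noise-free angles.
    angle_noise_sd: float = 5.0

    def __post_init__(self) -> None:
        self.phase_shape = np.asarray(self.phase_shape, dtype=float)
        self.generative_weights = np.asarray(self.generative_weights, dtype=float)
        if self.n_participants < 1 or self.trials_per_participant < 1:
            raise ConfigurationError("participant and trial counts must be >= 1")
        fr = np.asarray(self.phase_fractions, dtype=float)
        if fr.shape != (3,) or np.any(fr <= 0):
            raise ConfigurationError("phase_fractions must be three positive values")
        if abs(fr.sum() - 1.0) > 1e-12:
            raise ConfigurationError(
                f"phase_fractions must sum to 1 (got {fr.sum()!r})"
            )
        if len(self.angle_waveform_params) != N_JOINTS:
            raise ConfigurationError("need waveform parameters for all six joints")
        amps = [w.amplitude_deg for w in self.angle_waveform_params]
        if not np.all(np.isfinite(amps)):
            raise ConfigurationError("waveform amplitudes must be finite")
        if self.noise_sd < 0 or self.angle_noise_sd < 0:
            raise ConfigurationError("noise SDs must be >= 0")
        if self.generative_weights.shape != (N_PHASES, N_JOINTS):
            raise ConfigurationError("generative_weights must be 3 x 6")
        if self.phase_shape.shape != (N_JOINTS, N_PHASES):
            raise ConfigurationError("phase_shape must be 6 x 3")
        if self.sampling_rate_hz <= 0 or self.duration_s <= 0:
            raise ConfigurationError("sampling rate and duration must be positive")
        if self.n_samples < 101:
            raise ConfigurationError(
                "duration_s * sampling_rate_hz must give at least 101 samples"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sampling_rate_hz))

    @property
    def n_trials(self) -> int:
        return self.n_participants * self.trials_per_participant


@dataclass
class ServeTrial:
    """One serve's raw-rate angle and moment-component series."""

    angles_raw: np.ndarray  # 6 x T, degrees
    moment_components_raw: np.ndarray  # 3 x T, N*m
    phase_boundaries: tuple[int, int]
    participant_id: int
    trial_id: int
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        self.angles_raw = np.asarray(self.angles_raw, dtype=float)
        self.moment_components_raw = np.asarray(
            self.moment_components_raw, dtype=float
        )
        T = self.angles_raw.shape[1]
        if self.angles_raw.shape[0] != N_JOINTS:
            raise DataError("angles_raw must have six rows")
        if self.moment_components_raw.shape != (3, T):
            raise DataError("moment_components_raw must be 3 x T")
        if T < 101:
            raise DataError("trials must have at least 101 samples")
        if not (
            np.all(np.isfinite(self.angles_raw))
            and np.all(np.isfinite(self.moment_components_raw))
        ):
            raise DataError("trial series contain non-finite values")
        b1, b2 = self.phase_boundaries
        if not (0 < b1 < b2 < T):
            raise DataError("phase boundaries must be strictly increasing in (0, T)")

    @property
    def n_samples(self) -> int:
        return self.angles_raw.shape[1]

    def phase_of_sample(self) -> np.ndarray:
        """Phase index (0=PP, 1=FP, 2=LP) for every raw sample."""
        b1, b2 = self.phase_boundaries
        idx = np.zeros(self.n_samples, dtype=int)
        idx[b1:b2] = 1
        idx[b2:] = 2
        return idx


def phase_boundaries_from_fractions(
    phase_fractions: tuple[float, float, float], n_samples: int
) -> tuple[int, int]:
    f1, f2, _ = phase_fractions
    b1 = int(round(f1 * n_samples))
    b2 = int(round((f1 + f2) * n_samples))
    b1 = min(max(b1, 1), n_samples - 2)
    b2 = min(max(b2, b1 + 1), n_samples - 1)
    return b1, b2


def _participant_rng(config: SimulationConfig, participant_id: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, 7919, participant_id])


def _trial_rng(
    config: SimulationConfig, participant_id: int, trial_id: int
) -> np.random.Generator:
    return np.random.default_rng([config.seed, 104729, participant_id, trial_id])


def _phase_bumps(
    n_samples: int,
    boundaries: tuple[int, int],
    jitter: np.ndarray,
) -> np.ndarray:
    """Raised-cosine bump per phase, one row per phase, shape 3 x T.

    ``jitter`` (per phase) warps the bump peak inside the phase while
    pinning the endpoints, so curves stay smooth and band-limited.
    """
    b1, b2 = boundaries
    edges = (0, b1, b2, n_samples)
    bumps = np.zeros((N_PHASES, n_samples))
    for p in range(N_PHASES):
        lo, hi = edges[p], edges[p + 1]
        u = np.linspace(0.0, 1.0, hi - lo, endpoint=False)
        u = np.clip(u + jitter[p] * np.sin(np.pi * u), 0.0, 1.0)
        bumps[p, lo:hi] = 0.5 * (1.0 - np.cos(2.0 * np.pi * u))
    return bumps


def synthesize_angles(
    config: SimulationConfig,
    amp_factors: np.ndarray,
    jitter: np.ndarray,
) -> np.ndarray:
    """Deterministic 6 x T angle matrix from per-joint amplitude factors
    and per-joint, per-phase timing jitter."""
    T = config.n_samples
    boundaries = phase_boundaries_from_fractions(config.phase_fractions, T)
    angles = np.empty((N_JOINTS, T))
    for j, wf in enumerate(config.angle_waveform_params):
        bumps = _phase_bumps(T, boundaries, jitter[j])
        curve = config.phase_shape[j] @ bumps
        angles[j] = wf.baseline_deg + wf.amplitude_deg * amp_factors[j] * curve
    return angles


def generative_moments(
    config: SimulationConfig,
    angles: np.ndarray,
    phase_idx: np.ndarray,
) -> np.ndarray:
    """Noise-free 3 x T moment components from the documented formula."""
    baselines = np.array([w.baseline_deg for w in config.angle_waveform_params])
    vel = np.gradient(angles, axis=1) * config.sampling_rate_hz
    drive = (angles - baselines[:, None]) + config.velocity_coefficient * vel
    weights = config.generative_weights[phase_idx]  # T x 6
    combined = np.einsum("tj,jt->t", weights, drive)
    scales = np.asarray(config.component_scales, dtype=float)
    return scales[:, None] * combined[None, :]


def _smooth_observation_noise(
    rng: np.random.Generator,
    n_samples: int,
    fs: float,
    sd: float,
    f_lo: float = 1.5,
    f_hi: float = 6.0,
) -> np.ndarray:
    """Exactly band-limited noise with the requested SD (one row per joint).

    Random spectra are synthesized on the DFT bins inside [f_lo, f_hi] and
    inverted, so the noise carries no power at or above the 10 Hz filter
    cutoff by construction.
    """
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    band = (freqs >= f_lo) & (freqs <= f_hi)
    out = np.empty((N_JOINTS, n_samples))
    for j in range(N_JOINTS):
        coeffs = np.zeros(freqs.size, dtype=complex)
        coeffs[band] = rng.normal(size=band.sum()) + 1j * rng.normal(size=band.sum())
        row = np.fft.irfft(coeffs, n=n_samples)
        out[j] = row * (sd / max(row.std(), 1e-12))
    return out


def simulate_trial(
    config: SimulationConfig, participant_id: int, trial_id: int
) -> ServeTrial:
    """Generate one serve trial.

    Participant-level amplitude factors model between-subject variation;
    trial-level factors and timing jitter model within-subject variation.
    Moments are generated from the latent (noise-free) angles; smooth
    observation noise of SD ``angle_noise_sd`` is then added to the stored
    angle matrix only.
    """
    T = config.n_samples
    boundaries = phase_boundaries_from_fractions(config.phase_fractions, T)

    rng_p = _participant_rng(config, participant_id)
    participant_amp = rng_p.normal(1.0, config.between_subject_amp_sd, N_JOINTS)

    rng_t = _trial_rng(config, participant_id, trial_id)
    trial_amp = rng_t.normal(1.0, config.within_subject_amp_sd, N_JOINTS)
    jitter_sds = np.array(
        [w.timing_jitter_sd for w in config.angle_waveform_params]
    )
    jitter = rng_t.normal(0.0, 1.0, (N_JOINTS, N_PHASES)) * jitter_sds[:, None]

    angles = synthesize_angles(config, participant_amp * trial_amp, jitter)

    phase_idx = np.zeros(T, dtype=int)
    phase_idx[boundaries[0] : boundaries[1]] = 1
    phase_idx[boundaries[1] :] = 2
    moments = generative_moments(config, angles, phase_idx)
    if config.noise_sd > 0:
        moments = moments + rng_t.normal(0.0, config.noise_sd, (3, T))

    observed = angles
    if config.angle_noise_sd > 0:
        observed = angles + _smooth_observation_noise(
            rng_t, T, config.sampling_rate_hz, config.angle_noise_sd
        )

    return ServeTrial(
        angles_raw=observed,
        moment_components_raw=moments,
        phase_boundaries=boundaries,
        participant_id=participant_id,
        trial_id=trial_id,
        sampling_rate_hz=config.sampling_rate_hz,
    )


def simulate_dataset(config: SimulationConfig) -> list[ServeTrial]:
    """Generate all n_participants x trials_per_participant trials."""
    return [
        simulate_trial(config, p, t)
        for p in range(config.n_participants)
        for t in range(config.trials_per_participant)
    ]


def ground_truth_relevance(config: SimulationConfig) -> np.ndarray:
    """Per-phase generative weights normalized so each phase's max is 1.

    Returns a 3 x 6 matrix; the oracle against which attribution recovery
    is judged.
    """
    W = np.abs(config.generative_weights.astype(float))
    maxima = W.max(axis=1)
    if np.any(maxima == 0):
        zero = PHASES[int(np.argmax(maxima == 0))]
        raise ConfigurationError(f"generative weights are all zero in phase {zero}")
    return W / maxima[:, None]


# ---------------------------------------------------------------------------
# CSV round-trip

TRIAL_COLUMNS = ["time_index", *JOINTS, "mx", "my", "mz"]


def write_trial_csv(trial: ServeTrial, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "time_index": np.arange(trial.n_samples),
            **{name: trial.angles_raw[j] for j, name in enumerate(JOINTS)},
            "mx": trial.moment_components_raw[0],
            "my": trial.moment_components_raw[1],
            "mz": trial.moment_components_raw[2],
        }
    )
    df.to_csv(path, index=False, float_format="%.12g", encoding="utf-8")


def read_trial_csv(
    path: str | Path,
    phase_boundaries: tuple[int, int],
    participant_id: int,
    trial_id: int,
    sampling_rate_hz: float,
) -> ServeTrial:
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"trial CSV {path} lacks columns: {missing}")
    return ServeTrial(
        angles_raw=df[list(JOINTS)].to_numpy().T,
        moment_components_raw=df[["mx", "my", "mz"]].to_numpy().T,
        phase_boundaries=phase_boundaries,
        participant_id=participant_id,
        trial_id=trial_id,
        sampling_rate_hz=sampling_rate_hz,
    )


def write_dataset(
    trials: list[ServeTrial], out_dir: str | Path
) -> Path:
    """Write one CSV per trial plus a manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for trial in trials:
        name = f"trial_p{trial.participant_id:03d}_t{trial.trial_id:03d}.csv"
        write_trial_csv(trial, out_dir / name)
        rows.append(
            {
                "participant_id": trial.participant_id,
                "trial_id": trial.trial_id,
                "path": name,
                "phase_boundary_1": trial.phase_boundaries[0],
                "phase_boundary_2": trial.phase_boundaries[1],
                "sampling_rate_hz": trial.sampling_rate_hz,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False, encoding="utf-8")
    return manifest


def read_dataset(manifest_path: str | Path) -> list[ServeTrial]:
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path)
    return [
        read_trial_csv(
            base / row.path,
            (int(row.phase_boundary_1), int(row.phase_boundary_2)),
            int(row.participant_id),
            int(row.trial_id),
            float(row.sampling_rate_hz),
        )
        for row in df.itertuples()
    ]


def config_from_dict(payload: dict) -> SimulationConfig:
    """Build a SimulationConfig from a plain dict (YAML-friendly)."""
    payload = dict(payload)
    if "angle_waveform_params" in payload:
        payload["angle_waveform_params"] = tuple(
            WaveformParams(**w) if isinstance(w, dict) else WaveformParams(*w)
            for w in payload["angle_waveform_params"]
        )
    for key in ("phase_fractions", "component_scales"):
        if key in payload:
            payload[key] = tuple(payload[key])
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(payload) - known
    if unknown:
        raise ConfigurationError(f"unknown simulation options: {sorted(unknown)}")
    return SimulationConfig(**payload)
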