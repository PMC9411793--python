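"""Fully synthetic EEG-fMRI study generation.

This module stands in for human recordings: it builds a spherical toy head
model with a Gaussian-topography lead field, simulates ERP-like dipole
currents (Gaussian-windowed sinusoids over 1/f background activity), projects
them to the scalp through ``Y = G J + eps`` with spatially correlated sensor
noise, and produces BOLD series in which voxels near the active dipoles follow
an HRF-convolved trial-feature regressor.  Everything is a pure function of
``(config, seed)``: identical seeds give bit-identical studies.

The toy geometry is deliberately simple (sensors on the unit sphere, sources
on a concentric inner sphere) but preserves the two properties the inverse
solvers must handle: the problem is underdetermined (``s > m``) and the lead
field is full row rank.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .fmriprior import HRFKernel, canonical_hrf, convolve_feature_train

__all__ = [
    "HeadModel",
    "LeadField",
    "WaveformParams",
    "GroundTruth",
    "StudyConfig",
    "SubjectRecord",
    "SimulatedStudy",
    "make_head_model",
    "simulate_sources",
    "project_to_sensors",
    "simulate_bold",
    "generate_study",
    "default_ground_truth",
    "save_study",
    "load_study",
]

#: EEG sampling rate of the emulated recording system, Hz.
DEFAULT_SFREQ = 250.0
#: Epoch span relative to stimulus onset, seconds.
EPOCH_START, EPOCH_STOP = -0.2, 1.5
#: Gaussian topography width of the toy lead field, radians.
SIGMA_GAIN = 0.4
#: Radius of the source sphere (sensors sit on the unit sphere).
SOURCE_RADIUS = 0.8

CONDITIONS = ("neutral-watch", "negative-watch", "negative-reappraisal")


# ---------------------------------------------------------------------------
# geometry / forward model


@dataclass(frozen=True)
class HeadModel:
    """Spherical sensor/source geometry.

    sensor_positions : (m, 3) unit-norm coordinates
    source_positions : (s, 3) coordinates at radius ``SOURCE_RADIUS``
    source_spacing   : typical angular distance between neighbouring sources,
                       radians (median nearest-neighbour angle)
    """

    sensor_positions: np.ndarray
    source_positions: np.ndarray
    source_spacing: float

    @property
    def n_sensors(self) -> int:
        return self.sensor_positions.shape[0]

    @property
    def n_sources(self) -> int:
        return self.source_positions.shape[0]


@dataclass(frozen=True)
class LeadField:
    """Sensor x source gain matrix, microvolts per unit dipole moment."""

    G: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.G.shape


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (golden-angle spiral)."""
    i = np.arange(n)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    theta = golden * i
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def _angular_distance(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise great-circle angle between unit direction sets (na, 3), (nb, 3)."""
    an = a / np.linalg.norm(a, axis=1, keepdims=True)
    bn = b / np.linalg.norm(b, axis=1, keepdims=True)
    return np.arccos(np.clip(an @ bn.T, -1.0, 1.0))


def make_head_model(
    n_sensors: int, n_sources: int, seed: int | None = None
) -> tuple[HeadModel, LeadField]:
    """Build the toy spherical head model and its lead field.

    Sensors are Fibonacci-sphere sampled on the unit sphere, sources on a
    concentric sphere of radius 0.8.  The gain is a Gaussian function of the
    angular distance between sensor and source directions,
    ``G[i, j] = exp(-ang(i, j)^2 / (2 sigma^2))`` with sigma = 0.4 rad.
    Deterministic given its inputs (`seed` is accepted for API uniformity).
    """
    if n_sensors < 8:
        raise ValueError(f"need at least 8 sensors, got {n_sensors}")
    if n_sources < n_sensors:
        raise ValueError("need n_sources >= n_sensors (underdetermined inverse)")
    sensors = _fibonacci_sphere(n_sensors)
    sources = SOURCE_RADIUS * _fibonacci_sphere(n_sources)
    ang = _angular_distance(sensors, sources)
    G = np.exp(-(ang**2) / (2.0 * SIGMA_GAIN**2))
    src_ang = _angular_distance(sources, sources)
    np.fill_diagonal(src_ang, np.inf)
    spacing = float(np.median(src_ang.min(axis=1)))
    return HeadModel(sensors, sources, spacing), LeadField(G)


# ---------------------------------------------------------------------------
# ground truth and source currents


@dataclass(frozen=True)
class WaveformParams:
    """ERP-like waveform of one active dipole.

    amplitude : condition label -> peak amplitude (> 0), arbitrary current units
    latency   : envelope centre, s relative to stimulus onset
    width     : Gaussian envelope SD, s
    freq      : carrier frequency, Hz
    phase     : carrier phase offset, radians
    """

    amplitude: Mapping[str, float]
    latency: float
    width: float
    freq: float
    phase: float = 0.0


@dataclass(frozen=True)
class GroundTruth:
    """Active-dipole configuration used for recovery tests.

    phase_lags maps an ordered dipole pair ``(i, j)`` to a constant phase
    offset in (-pi, pi]; dipole ``j``'s carrier phase is set to dipole ``i``'s
    minus the offset, so the instantaneous phase difference phi_i - phi_j
    equals the offset throughout the envelope.  When the two dipoles fall in
    different parcels this induces the corresponding ROI-pair lag.
    """

    n_sources: int
    waveform_params: Mapping[int, WaveformParams] = field(default_factory=dict)
    phase_lags: Mapping[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, wp in self.waveform_params.items():
            if not 0 <= k < self.n_sources:
                raise ValueError(f"active dipole {k} outside [0, {self.n_sources})")
            if any(a <= 0 for a in wp.amplitude.values()):
                raise ValueError(f"dipole {k}: amplitudes must be > 0")
        for (i, j), lag in self.phase_lags.items():
            if i not in self.waveform_params or j not in self.waveform_params:
                raise ValueError(f"phase lag on inactive pair ({i}, {j})")
            if not (-np.pi < lag <= np.pi):
                raise ValueError(f"phase offset {lag} outside (-pi, pi]")

    @property
    def active_dipoles(self) -> np.ndarray:
        return np.array(sorted(self.waveform_params), dtype=int)


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """1/f-amplitude noise, unit variance per row, via FFT shaping."""
    n_rows, n = shape
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    scale[0] = 0.0
    out = np.fft.irfft(spec * scale, n=n, axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def simulate_sources(
    truth: GroundTruth,
    time_axis: np.ndarray,
    condition: str,
    rng: np.random.Generator | int | None = None,
    background_frac: float = 0.01,
) -> np.ndarray:
    """Source current matrix J (s x d) for one trial.

    Active dipoles carry ``amp * exp(-(t - latency)^2 / (2 width^2))
    * sin(2 pi f t + phi)``; inactive dipoles carry pink noise scaled to
    ``background_frac`` of the largest active amplitude (so a truth with no
    active dipoles yields exactly zero currents).
    """
    t = np.asarray(time_axis, dtype=float)
    J = np.zeros((truth.n_sources, t.size))
    phases = {}
    for k, wp in truth.waveform_params.items():
        if condition not in wp.amplitude:
            raise KeyError(
                f"unknown condition {condition!r}; dipole {k} defines "
                f"{sorted(wp.amplitude)}"
            )
        phases[k] = wp.phase
    for (i, j), lag in truth.phase_lags.items():
        phases[j] = phases[i] - lag

    max_amp = 0.0
    for k, wp in truth.waveform_params.items():
        amp = wp.amplitude[condition]
        max_amp = max(max_amp, amp)
        env = amp * np.exp(-((t - wp.latency) ** 2) / (2.0 * wp.width**2))
        J[k] = env * np.sin(2.0 * np.pi * wp.freq * t + phases[k])

    if max_amp > 0 and background_frac > 0:
        rng = np.random.default_rng(rng)
        inactive = np.setdiff1d(np.arange(truth.n_sources), truth.active_dipoles)
        if inactive.size:
            J[inactive] = background_frac * max_amp * _pink_noise(
                rng, (inactive.size, t.size)
            )
    return J


# ---------------------------------------------------------------------------
# sensor projection


def noise_covariance_true(m: int, sigma2: float = 1.0) -> np.ndarray:
    """The generating sensor-noise covariance sigma^2 (0.9 I + 0.1 11'/m).

    Deliberately non-diagonal (rank-one common-mode term) so that noise
    covariance estimation downstream is non-trivially exercised.
    """
    return sigma2 * (0.9 * np.eye(m) + 0.1 * np.ones((m, m)) / m)


def project_to_sensors(
    G: np.ndarray | LeadField,
    J_true: np.ndarray,
    snr: float,
    seed: int | np.random.Generator | None = None,
    n_trials: int = 1,
) -> np.ndarray:
    """Project source currents to the scalp: Y = G J + eps, shape (m, d, n_trials).

    eps is zero-mean Gaussian with covariance ``sigma^2 (0.9 I + 0.1 11'/m)``,
    sigma^2 chosen so that the expected power ratio power(GJ)/power(eps)
    equals ``snr**2``.  ``snr=inf`` disables the noise.  With identically zero
    signal the ratio is undefined and unit noise variance is used.
    """
    G = G.G if isinstance(G, LeadField) else np.asarray(G, dtype=float)
    J_true = np.asarray(J_true, dtype=float)
    if G.shape[1] != J_true.shape[0]:
        raise ValueError(
            f"lead field has {G.shape[1]} sources but J has {J_true.shape[0]} rows"
        )
    if not snr > 0:
        raise ValueError("snr must be > 0")
    m = G.shape[0]
    signal = G @ J_true
    Y = np.repeat(signal[:, :, None], n_trials, axis=2)
    if np.isinf(snr):
        return Y
    sig_power = float(np.mean(signal**2))
    # expected per-entry noise power is sigma^2 * trace(C0)/m with C0 the
    # unit-variance template below
    per_entry = 0.9 + 0.1 / m
    sigma2 = sig_power / (snr**2 * per_entry) if sig_power > 0 else 1.0
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(noise_covariance_true(m, sigma2))
    eps = np.einsum("ij,jkt->ikt", L, rng.standard_normal((m, J_true.shape[1], n_trials)))
    return Y + eps


# ---------------------------------------------------------------------------
# BOLD


def simulate_bold(
    trial_features: Sequence[float],
    onsets: Sequence[float],
    hrf: HRFKernel,
    active_voxels: Sequence[int],
    n_voxels: int,
    n_volumes: int,
    tr: float,
    noise_sd: float,
    seed: int | np.random.Generator | None = None,
    beta: float = 2.0,
) -> np.ndarray:
    """BOLD array (n_voxels x n_volumes), arbitrary units.

    Active voxels follow ``beta *`` (feature-weighted onset stick train
    convolved with the HRF, resampled at the TR) plus Gaussian noise;
    inactive voxels are noise only.
    """
    if tr <= 0:
        raise ValueError("tr must be > 0")
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size and onsets.max() >= n_volumes * tr:
        raise ValueError("onset beyond scan end")
    signal = convolve_feature_train(trial_features, onsets, hrf, tr, n_volumes)
    rng = np.random.default_rng(seed)
    bold = noise_sd * rng.standard_normal((n_voxels, n_volumes))
    bold[np.asarray(active_voxels, dtype=int)] += beta * signal
    return bold


# ---------------------------------------------------------------------------
# full study


@dataclass(frozen=True)
class StudyConfig:
    """Study-level generator settings.

    Defaults mirror the emulated design: 15 subjects, three viewing/regulation
    conditions, 30 trials per condition, 250 Hz epochs spanning -0.2 to 1.5 s,
    16 sensors / 200 dipoles, sensor SNR 3.
    """

    n_subjects: int = 15
    conditions: tuple[str, ...] = CONDITIONS
    n_trials: int = 30
    n_sensors: int = 16
    n_sources: int = 200
    sampling_rate: float = DEFAULT_SFREQ
    t_start: float = EPOCH_START
    t_stop: float = EPOCH_STOP
    snr: float = 3.0
    background_frac: float = 0.01
    n_voxels: int = 400
    n_volumes: int = 200
    tr: float = 2.0
    bold_noise_sd: float = 1.0
    bold_beta: float = 2.0
    feature_jitter: float = 0.1
    voxels_per_dipole: int = 3
    voxel_jitter: float = 0.2  # voxel scatter around active dipoles, x source spacing
    hrf_dt: float = 0.1

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_trials < 1:
            raise ValueError("n_subjects and n_trials must be >= 1")
        if len(self.conditions) < 1:
            raise ValueError("need at least one condition")
        if self.t_stop <= self.t_start:
            raise ValueError("empty epoch span")
        n_trials_total = self.n_trials * len(self.conditions)
        scan_len = self.n_volumes * self.tr
        if 10.0 + 4.0 * n_trials_total > scan_len:
            raise ValueError(
                f"{n_trials_total} trials at 4 s spacing do not fit a "
                f"{scan_len:.0f} s scan; increase n_volumes"
            )

    def time_axis(self) -> np.ndarray:
        n = int(round((self.t_stop - self.t_start) * self.sampling_rate)) + 1
        return self.t_start + np.arange(n) / self.sampling_rate


@dataclass
class SubjectRecord:
    """One simulated participant."""

    subject: int
    eeg: dict[str, np.ndarray]  # condition -> (m, d, n_trials) microvolts
    bold: np.ndarray  # (n_voxels, n_volumes)
    onsets: np.ndarray  # trial onsets within the scan, s
    trial_conditions: list[str]  # condition of each scan trial, in onset order
    trial_features: np.ndarray  # per-trial EEG feature fed to the BOLD regressor


@dataclass
class SimulatedStudy:
    """A complete synthetic EEG-fMRI study."""

    config: StudyConfig
    seed: int
    head_model: HeadModel
    lead_field: LeadField
    time_axis: np.ndarray
    sampling_rate: float
    tr: float
    voxel_positions: np.ndarray  # (n_voxels, 3), source-space frame
    active_voxels: np.ndarray  # indices of truly responsive voxels
    truth: GroundTruth
    subjects: list[SubjectRecord]


def default_ground_truth(
    n_sources: int, conditions: Sequence[str] = CONDITIONS
) -> GroundTruth:
    """Condition-modulated truth with one ERP-like dipole per analysis window.

    Amplitude ordering encodes the emulated effect: negative images evoke the
    largest response, reappraisal partially downregulates it, neutral is
    smallest.  A gamma-band dipole pair with a constant pi/2 lag provides the
    controlled ROI-coupling target.
    """
    if n_sources < 80:
        raise ValueError("default truth expects at least 80 dipoles")
    amp = {conditions[0]: 1.0}
    if len(conditions) > 1:
        amp[conditions[1]] = 1.5
    if len(conditions) > 2:
        amp[conditions[2]] = 1.1
    # dipole picks scale with the source count so small test geometries work;
    # the fractions keep the pair well separated (different parcels)
    k_early = round(0.10 * n_sources)
    k_pair_a = round(0.40 * n_sources)
    k_pair_b = round(0.75 * n_sources)
    k_late = round(0.60 * n_sources)
    wf = {
        # early visual response, peaks inside the 60-172 ms window
        k_early: WaveformParams(amp, latency=0.116, width=0.030, freq=10.0, phase=0.5),
        # mid-latency pair with constant pi/2 gamma-band lag (428-580 ms window)
        k_pair_a: WaveformParams(amp, latency=0.504, width=0.060, freq=35.0, phase=0.0),
        k_pair_b: WaveformParams(amp, latency=0.504, width=0.060, freq=35.0, phase=0.0),
        # late slow component (1164-1276 ms window)
        k_late: WaveformParams(amp, latency=1.220, width=0.050, freq=6.0, phase=1.0),
    }
    return GroundTruth(
        n_sources=n_sources,
        waveform_params=wf,
        phase_lags={(k_pair_a, k_pair_b): np.pi / 2},
    )


def _subject_seed_seq(master_seed: int, subject: int) -> np.random.SeedSequence:
    # fixed splitting rule: adding subjects never reshuffles earlier ones
    return np.random.SeedSequence(entropy=(int(master_seed), int(subject)))


def generate_study(
    config: StudyConfig | None = None,
    seed: int = 0,
    truth: GroundTruth | None = None,
) -> SimulatedStudy:
    """Generate the full multi-subject study.

    Per-subject randomness is drawn from ``SeedSequence((seed, subject))`` so
    the record for subject *k* is invariant to the total subject count.
    Voxel geometry is shared across subjects (one emulated anatomy).
    """
    config = config or StudyConfig()
    head, lead = make_head_model(config.n_sensors, config.n_sources)
    if truth is None:
        truth = default_ground_truth(config.n_sources, config.conditions)
    if truth.n_sources != config.n_sources:
        raise ValueError("truth.n_sources does not match config.n_sources")
    t = config.time_axis()
    hrf = canonical_hrf(config.hrf_dt)

    # shared voxel geometry: a few voxels co-located with each active dipole,
    # the rest scattered over the source shell
    geo_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=(int(seed), 0x9E0))
    )
    active = truth.active_dipoles
    vox_active = []
    for k in active:
        base = head.source_positions[k]
        for _ in range(config.voxels_per_dipole):
            jitter = config.voxel_jitter * head.source_spacing * geo_rng.standard_normal(3)
            vox_active.append(base + jitter)
    n_rest = config.n_voxels - len(vox_active)
    if n_rest < 0:
        raise ValueError("n_voxels too small for the active-voxel layout")
    directions = geo_rng.standard_normal((n_rest, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    radii = SOURCE_RADIUS * (0.95 + 0.1 * geo_rng.random((n_rest, 1)))
    vox = np.vstack([np.array(vox_active).reshape(-1, 3), radii * directions])
    active_voxels = np.arange(len(vox_active))

    cond_scale = {
        c: max(wp.amplitude[c] for wp in truth.waveform_params.values())
        if truth.waveform_params
        else 1.0
        for c in config.conditions
    }

    n_total = config.n_trials * len(config.conditions)
    onsets = 10.0 + 4.0 * np.arange(n_total)

    subjects = []
    for si in range(config.n_subjects):
        rng = np.random.default_rng(_subject_seed_seq(seed, si))
        order = rng.permutation(np.repeat(np.arange(len(config.conditions)), config.n_trials))
        trial_conditions = [config.conditions[c] for c in order]
        features = np.array(
            [cond_scale[c] for c in trial_conditions]
        ) * (1.0 + config.feature_jitter * rng.standard_normal(n_total))

        eeg: dict[str, np.ndarray] = {}
        for cond in config.conditions:
            trials = []
            for _ in range(config.n_trials):
                J = simulate_sources(
                    truth, t, cond, rng=rng, background_frac=config.background_frac
                )
                trials.append(
                    project_to_sensors(lead.G, J, config.snr, seed=rng, n_trials=1)[:, :, 0]
                )
            eeg[cond] = np.stack(trials, axis=2)

        bold = simulate_bold(
            features,
            onsets,
            hrf,
            active_voxels,
            config.n_voxels,
            config.n_volumes,
            config.tr,
            config.bold_noise_sd,
            seed=rng,
            beta=config.bold_beta,
        )
        subjects.append(
            SubjectRecord(si, eeg, bold, onsets, trial_conditions, features)
        )

    return SimulatedStudy(
        config=config,
        seed=int(seed),
        head_model=head,
        lead_field=lead,
        time_axis=t,
        sampling_rate=config.sampling_rate,
        tr=config.tr,
        voxel_positions=vox,
        active_voxels=active_voxels,
        truth=truth,
        subjects=subjects,
    )


# ---------------------------------------------------------------------------
# on-disk layout


def _truth_to_json(truth: GroundTruth) -> dict:
    return {
        "n_sources": truth.n_sources,
        "waveform_params": {
            str(k): {
                "amplitude": dict(wp.amplitude),
                "latency": wp.latency,
                "width": wp.width,
                "freq": wp.freq,
                "phase": wp.phase,
            }
            for k, wp in truth.waveform_params.items()
        },
        "phase_lags": [[i, j, lag] for (i, j), lag in truth.phase_lags.items()],
    }


def _truth_from_json(d: dict) -> GroundTruth:
    return GroundTruth(
        n_sources=d["n_sources"],
        waveform_params={
            int(k): WaveformParams(**wp) for k, wp in d["waveform_params"].items()
        },
        phase_lags={(int(i), int(j)): lag for i, j, lag in d["phase_lags"]},
    )


def save_study(study: SimulatedStudy, out_dir: str | Path) -> Path:
    """Write a study: one numeric container + JSON sidecar per subject,
    shared geometry, and the ground truth as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = study.config
    meta = {
        "seed": study.seed,
        "sampling_rate": study.sampling_rate,
        "tr": study.tr,
        "time_axis": study.time_axis.tolist(),
        "conditions": list(cfg.conditions),
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(cfg).items()
        },
    }
    (out / "study.json").write_text(json.dumps(meta, indent=1))
    (out / "truth.json").write_text(json.dumps(_truth_to_json(study.truth), indent=1))
    np.savez(
        out / "geometry.npz",
        sensor_positions=study.head_model.sensor_positions,
        source_positions=study.head_model.source_positions,
        source_spacing=study.head_model.source_spacing,
        lead_field=study.lead_field.G,
        voxel_positions=study.voxel_positions,
        active_voxels=study.active_voxels,
    )
    for rec in study.subjects:
        tag = f"sub-{rec.subject:02d}"
        np.savez(
            out / f"{tag}.npz",
            bold=rec.bold,
            onsets=rec.onsets,
            trial_features=rec.trial_features,
            **{f"eeg__{c}": rec.eeg[c] for c in rec.eeg},
        )
        sidecar = {
            "subject": rec.subject,
            "conditions": list(rec.eeg),
            "eeg_shape": {c: list(rec.eeg[c].shape) for c in rec.eeg},
            "trial_conditions": rec.trial_conditions,
            "units": {"eeg": "microvolt", "bold": "a.u."},
        }
        (out / f"{tag}.json").write_text(json.dumps(sidecar, indent=1))
    return out


def load_study(in_dir: str | Path) -> SimulatedStudy:
    """Read a study written by :func:`save_study`."""
    src = Path(in_dir)
    meta = json.loads((src / "study.json").read_text())
    cfg_d = dict(meta["config"])
    cfg_d["conditions"] = tuple(cfg_d["conditions"])
    cfg = StudyConfig(**cfg_d)
    truth = _truth_from_json(json.loads((src / "truth.json").read_text()))
    geo = np.load(src / "geometry.npz")
    head = HeadModel(
        geo["sensor_positions"], geo["source_positions"], float(geo["source_spacing"])
    )
    subjects = []
    for path in sorted(src.glob("sub-*.npz")):
        data = np.load(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        eeg = {
            key[len("eeg__"):]: data[key] for key in data.files if key.startswith("eeg__")
        }
        subjects.append(
            SubjectRecord(
                subject=sidecar["subject"],
                eeg=eeg,
                bold=data["bold"],
                onsets=data["onsets"],
                trial_conditions=sidecar["trial_conditions"],
                trial_features=data["trial_features"],
            )
        )
    return SimulatedStudy(
        config=cfg,
        seed=meta["seed"],
        head_model=head,
        lead_field=LeadField(geo["lead_field"]),
        time_axis=np.asarray(meta["time_axis"]),
        sampling_rate=meta["sampling_rate"],
        tr=meta["tr"],
        voxel_positions=geo["voxel_positions"],
        active_voxels=geo["active_voxels"],
        truth=truth,
        subjects=subjects,
    )
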