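"""EEG-informed fMRI analysis and the fMRI prior source covariance.

A per-trial EEG feature train is convolved with the canonical double-gamma
HRF to predict BOLD; a massively univariate ordinary-least-squares GLM scores
every voxel against that regressor; supra-threshold voxels are mapped into
source space, and the resulting activation set defines the diagonal prior
covariance R_f used by the fMRI-weighted inverse solver: weight 1 inside the
activation regions, 0.1 outside, off-diagonals zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist

__all__ = [
    "HRFKernel",
    "GLMResult",
    "ActivationMask",
    "PriorDiagonal",
    "canonical_hrf",
    "convolve_feature_train",
    "build_regressor",
    "glm_fit",
    "threshold_map",
    "map_voxels_to_sources",
    "build_fmri_prior",
]

ACTIVE_WEIGHT = 1.0
INACTIVE_WEIGHT = 0.1


@dataclass(frozen=True)
class HRFKernel:
    """Hemodynamic response kernel sampled at resolution ``dt`` seconds."""

    samples: np.ndarray
    dt: float

    @property
    def duration(self) -> float:
        return self.samples.size * self.dt


def canonical_hrf(dt: float = 0.1) -> HRFKernel:
    """Canonical double-gamma HRF: response peak at 6 s, undershoot at 16 s,
    undershoot ratio 1/6, 32 s support, peak-normalized to 1."""
    if not 0 < dt <= 1.0:
        raise ValueError("dt must be in (0, 1] s")
    t = np.arange(0.0, 32.0, dt)
    # gamma densities with unit scale peak at shape-1, so shapes 7 and 17
    # put the response/undershoot modes at 6 s and 16 s
    h = stats.gamma.pdf(t, a=7.0) - stats.gamma.pdf(t, a=17.0) / 6.0
    return HRFKernel(h / h.max(), dt)


def convolve_feature_train(
    trial_features: Sequence[float],
    onsets: Sequence[float],
    hrf: HRFKernel,
    tr: float,
    n_volumes: int,
) -> np.ndarray:
    """Feature-weighted onset sticks convolved with the HRF, resampled at the TR.

    Returns the raw (uncentered) predicted response at the ``n_volumes``
    acquisition times ``0, tr, 2 tr, ...``.
    """
    trial_features = np.asarray(trial_features, dtype=float)
    onsets = np.asarray(onsets, dtype=float)
    if trial_features.shape != onsets.shape:
        raise ValueError("trial_features and onsets must have equal length")
    scan_len = n_volumes * tr
    if onsets.size and (onsets.min() < 0 or onsets.max() >= scan_len):
        raise ValueError("onsets outside the scan")
    dt = hrf.dt
    n_fine = int(np.ceil(scan_len / dt)) + hrf.samples.size
    sticks = np.zeros(n_fine)
    idx = np.round(onsets / dt).astype(int)
    np.add.at(sticks, idx, trial_features)
    fine = np.convolve(sticks, hrf.samples)[:n_fine]
    vol_times = np.arange(n_volumes) * tr
    return np.interp(vol_times, np.arange(n_fine) * dt, fine)


def build_regressor(
    trial_features: Sequence[float],
    onsets: Sequence[float],
    hrf: HRFKernel,
    tr: float,
    n_volumes: int,
) -> np.ndarray:
    """Mean-centered EEG-informed BOLD regressor (length ``n_volumes``).

    Centering removes the scale ambiguity between the regression coefficient
    and the baseline; pair with an explicit intercept in the GLM.
    """
    reg = convolve_feature_train(trial_features, onsets, hrf, tr, n_volumes)
    return reg - reg.mean()


@dataclass(frozen=True)
class GLMResult:
    """Per-voxel OLS fit of BOLD against the EEG-informed regressor."""

    beta: np.ndarray  # regressor coefficient per voxel
    tstat: np.ndarray  # beta / SE(beta)
    dof: int  # n_volumes - n_regressors
    design: np.ndarray  # (n_volumes, n_regressors) incl. intercept


def glm_fit(
    bold: np.ndarray,
    regressor: np.ndarray,
    confounds: np.ndarray | None = None,
) -> GLMResult:
    """Ordinary least squares per voxel; t = beta / SE(beta).

    ``bold`` is (n_voxels, n_volumes).  The design is [intercept, regressor,
    confounds...]; the reported beta/t are for the regressor column.
    """
    bold = np.atleast_2d(np.asarray(bold, dtype=float))
    regressor = np.asarray(regressor, dtype=float)
    n_vol = bold.shape[1]
    if regressor.size != n_vol:
        raise ValueError("regressor length does not match number of volumes")
    cols = [np.ones(n_vol), regressor]
    if confounds is not None:
        cols.extend(np.atleast_2d(np.asarray(confounds, dtype=float)))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design matrix")
    if n_vol <= X.shape[1] + 1:
        raise ValueError("need n_volumes > n_regressors + 1")
    XtX_inv = np.linalg.inv(X.T @ X)
    coef = bold @ X @ XtX_inv.T  # (n_voxels, p)
    resid = bold - coef @ X.T
    dof = n_vol - X.shape[1]
    sigma2 = np.sum(resid**2, axis=1) / dof
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef[:, 1] / se, 0.0)
    return GLMResult(beta=coef[:, 1], tstat=t, dof=dof, design=X)


@dataclass(frozen=True)
class ActivationMask:
    """Boolean activation map plus a record of the rule that produced it."""

    active_voxels: np.ndarray  # boolean per voxel
    threshold_rule: dict = field(default_factory=dict)


def threshold_map(result: GLMResult, p_unc: float = 0.001) -> ActivationMask:
    """One-sided (positive) uncorrected voxel threshold."""
    p = stats.t.sf(result.tstat, df=result.dof)
    return ActivationMask(
        active_voxels=p < p_unc,
        threshold_rule={"test": "one-sided t", "p_unc": p_unc, "dof": result.dof},
    )


def map_voxels_to_sources(
    mask: ActivationMask | np.ndarray,
    voxel_positions: np.ndarray,
    source_positions: np.ndarray,
    radius: float,
) -> np.ndarray:
    """Indices of dipoles with at least one active voxel within ``radius``
    (Euclidean, shared coordinate frame)."""
    active = mask.active_voxels if isinstance(mask, ActivationMask) else np.asarray(mask)
    voxel_positions = np.asarray(voxel_positions, dtype=float)
    source_positions = np.asarray(source_positions, dtype=float)
    if voxel_positions.shape[1] != source_positions.shape[1]:
        raise ValueError("voxel and source coordinate frames differ in dimension")
    pos = voxel_positions[np.asarray(active, dtype=bool)]
    if pos.size == 0:
        return np.array([], dtype=int)
    d = cdist(source_positions, pos)
    return np.flatnonzero((d <= radius).any(axis=1))


@dataclass(frozen=True)
class PriorDiagonal:
    """Diagonal of the source covariance R (off-diagonals are zero).

    kind is one of {"uninformative", "fmri", "fused_window"}; the fMRI prior
    takes only the values 1 (inside the activation regions) and 0.1 outside.
    """

    weights: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w <= 0):
            raise ValueError("prior weights must be strictly positive")
        object.__setattr__(self, "weights", w)


def build_fmri_prior(active_dipoles: Sequence[int], s: int) -> PriorDiagonal:
    """R_f diagonal: 1 on dipoles inside the activation regions, 0.1 elsewhere."""
    active = np.asarray(active_dipoles, dtype=int)
    if active.size and (active.min() < 0 or active.max() >= s):
        raise IndexError("active dipole index out of range")
    w = np.full(s, INACTIVE_WEIGHT)
    w[active] = ACTIVE_WEIGHT
    return PriorDiagonal(weights=w, kind="fmri")
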