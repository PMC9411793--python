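"""ROI extraction over a 68-region cortical parcellation, instantaneous
phase via the analytic signal, and phase-lag-index (PLI) connectivity.

The PLI between two series is ``| mean_l sign(dphi(t_l)) |`` where dphi is
the wrapped instantaneous phase difference from the Hilbert analytic signal.
It is 0 for identical signals (and, more generally, for any zero-lag
coupling, which makes it insensitive to volume conduction) and 1 for a fixed
nonzero phase relationship.  Edge samples are trimmed before averaging
because the frequency-domain Hilbert construction is unreliable at the
record boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "DK_LABELS",
    "Parcellation",
    "ROITimeSeries",
    "PhaseSeries",
    "PLIMatrix",
    "default_parcellation",
    "extract_roi_timeseries",
    "analytic_phase",
    "pli_from_phase_diff",
    "pli_pair",
    "pli_matrix",
]

logger = logging.getLogger(__name__)

#: Sign tolerance: |dphi| below this counts as a zero phase difference.
SIGN_TOL = 1e-9
#: Fraction of samples discarded at each record edge before sign averaging.
DEFAULT_TRIM = 0.05

_DK_BASE = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "frontalpole",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "insula",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "paracentral",
    "parahippocampal",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "temporalpole",
    "transversetemporal",
)

#: The 68 Desikan-Killiany cortical labels, left hemisphere first.
DK_LABELS = tuple(f"l.{n}" for n in _DK_BASE) + tuple(f"r.{n}" for n in _DK_BASE)


@dataclass(frozen=True)
class Parcellation:
    """68-label map from dipoles to cortical regions."""

    labels: tuple[str, ...]
    dipole_to_label: np.ndarray  # (s,) label index per dipole

    def __post_init__(self) -> None:
        if len(self.labels) != 68:
            raise ValueError("parcellation must have exactly 68 labels")
        mapping = np.asarray(self.dipole_to_label, dtype=int)
        counts = np.bincount(mapping, minlength=68)
        if counts.min() < 1:
            raise ValueError("every label needs at least one dipole")
        object.__setattr__(self, "dipole_to_label", mapping)

    @property
    def n_labels(self) -> int:
        return len(self.labels)


def default_parcellation(head_model) -> Parcellation:
    """Partition the toy source sphere into 68 contiguous angular patches.

    Hemispheres are split by the sign of the x coordinate (34 labels each);
    within a hemisphere dipoles are ordered by polar angle (azimuth as the
    tie-break) and chunked into 34 patches whose sizes differ by at most one.
    Deterministic for a given head model.
    """
    pos = np.asarray(head_model.source_positions, dtype=float)
    s = pos.shape[0]
    if s < 68:
        raise ValueError(f"{s} dipoles cannot populate 68 labels")
    mapping = np.empty(s, dtype=int)
    left = np.flatnonzero(pos[:, 0] < 0)
    right = np.flatnonzero(pos[:, 0] >= 0)
    for hemi_idx, (hemi, offset) in enumerate(((left, 0), (right, 34))):
        if hemi.size < 34:
            raise ValueError("fewer dipoles than labels in one hemisphere")
        p = pos[hemi]
        polar = np.arccos(np.clip(p[:, 2] / np.linalg.norm(p, axis=1), -1, 1))
        azim = np.arctan2(p[:, 1], p[:, 0])
        order = hemi[np.lexsort((azim, polar))]
        for li, chunk in enumerate(np.array_split(order, 34)):
            mapping[chunk] = offset + li
    return Parcellation(labels=DK_LABELS, dipole_to_label=mapping)


@dataclass(frozen=True)
class ROITimeSeries:
    """(68 x d) region-level series for one trial/window."""

    data: np.ndarray
    band: str = ""
    condition: str = ""


def extract_roi_timeseries(J, parc: Parcellation, agg: str = "mean") -> ROITimeSeries:
    """Aggregate dipole series into ROI series.

    agg="mean" is the plain arithmetic mean of the member dipoles.  Note the
    sign-cancellation hazard of plain averaging: two member dipoles with
    series x and -x cancel to zero.  "abs_mean" (mean of magnitudes) and
    "first_pc" (sign-aligned leading principal component) are provided as
    alternatives.
    """
    from .inverse import SourceEstimate

    Jm = J.J if isinstance(J, SourceEstimate) else np.asarray(J, dtype=float)
    if Jm.shape[0] != parc.dipole_to_label.size:
        raise ValueError("estimate rows do not match the parcellation")
    k = parc.n_labels
    counts = np.bincount(parc.dipole_to_label, minlength=k).astype(float)
    out = np.zeros((k, Jm.shape[1]))
    if agg == "mean":
        np.add.at(out, parc.dipole_to_label, Jm)
        out /= counts[:, None]
    elif agg == "abs_mean":
        np.add.at(out, parc.dipole_to_label, np.abs(Jm))
        out /= counts[:, None]
    elif agg == "first_pc":
        for li in range(k):
            rows = Jm[parc.dipole_to_label == li]
            u, sv, vt = np.linalg.svd(rows - rows.mean(axis=1, keepdims=True),
                                      full_matrices=False)
            pc = sv[0] * vt[0]
            # orient along the mean so the component has a deterministic sign
            if pc @ rows.mean(axis=0) < 0:
                pc = -pc
            out[li] = pc / np.sqrt(max(rows.shape[0], 1))
    else:
        raise ValueError(f"unknown aggregation {agg!r}")
    return ROITimeSeries(data=out)


@dataclass(frozen=True)
class PhaseSeries:
    """Instantaneous phase (radians, in (-pi, pi]) and analytic components."""

    phase: np.ndarray
    analytic_real: np.ndarray
    analytic_imag: np.ndarray


def analytic_phase(x: np.ndarray) -> PhaseSeries:
    """Instantaneous phase from the frequency-domain analytic signal
    x_H(t) = x(t) + i x~(t); the phase is the four-quadrant arctangent of
    (x~, x).  Constant input has no defined phase and is rejected."""
    x = np.asarray(x, dtype=float)
    if x.size < 16:
        raise ValueError("need at least 16 samples for a usable phase estimate")
    if np.ptp(x) == 0:
        raise ValueError("constant input: instantaneous phase undefined")
    a = signal.hilbert(x)
    return PhaseSeries(phase=np.angle(a), analytic_real=a.real, analytic_imag=a.imag)


def _wrap(dphi: np.ndarray) -> np.ndarray:
    return (dphi + np.pi) % (2.0 * np.pi) - np.pi


def _sign_wrapped(dphi: np.ndarray) -> np.ndarray:
    """sign of the (-pi, pi]-wrapped phase difference, with |.| < 1e-9
    counting as zero.  Branch-free for inputs already inside (-2 pi, 2 pi)
    (the case for differences of two phases), falling back to an explicit
    wrap otherwise."""
    d = np.asarray(dphi, dtype=float)
    a = np.abs(d)
    if a.size and a.max() >= 2.0 * np.pi:
        d = _wrap(d)
        a = np.abs(d)
    s = np.sign(d)
    np.negative(s, out=s, where=a > np.pi)
    s[(a < SIGN_TOL) | (np.abs(a - 2.0 * np.pi) < SIGN_TOL)] = 0.0
    return s


def pli_from_phase_diff(dphi: np.ndarray) -> float:
    """|mean sign(dphi)| over an already-trimmed phase-difference series.

    The sign of a zero difference (|dphi| < 1e-9 rad after wrapping)
    contributes 0, which makes the self-PLI exactly zero in floating point.
    """
    return float(abs(_sign_wrapped(dphi).mean()))


def _trim_slice(n: int, trim_frac: float) -> slice:
    k = int(round(trim_frac * n))
    return slice(k, n - k if k else n)


def pli_pair(x: np.ndarray, y: np.ndarray, trim_frac: float = DEFAULT_TRIM) -> float:
    """Phase lag index between two series, in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    n = x.size
    sl = _trim_slice(n, trim_frac)
    if sl.stop - sl.start < 8:
        raise ValueError("fewer than 8 samples remain after edge trimming")
    px = analytic_phase(x).phase
    py = analytic_phase(y).phase
    return pli_from_phase_diff((px - py)[sl])


@dataclass(frozen=True)
class PLIMatrix:
    """Symmetric (K x K) PLI values in [0, 1] with zero diagonal."""

    values: np.ndarray
    band: str = ""
    condition: str = ""
    subject: int | None = None
    M: int = 0  # phase-difference samples per pair
    n_trials: int = 1

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("PLI matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("PLI matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("PLI diagonal must be exactly zero")
        if v.min() < 0 or v.max() > 1:
            raise ValueError("PLI values must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def K(self) -> int:
        return self.values.shape[0]


def _pli_matrix_one_trial(series: np.ndarray, trim_frac: float) -> np.ndarray | None:
    """All-pairs PLI for one trial's (K x d) series; None if any row is
    constant (phase undefined)."""
    if np.any(np.ptp(series, axis=1) == 0):
        return None
    phases = np.angle(signal.hilbert(series, axis=1))
    sl = _trim_slice(series.shape[1], trim_frac)
    ph = phases[:, sl]
    k = series.shape[0]
    iu = np.triu_indices(k, k=1)
    s = _sign_wrapped(ph[iu[0]] - ph[iu[1]])  # (n_pairs, M)
    vec = np.abs(s.mean(axis=1))
    vals = np.zeros((k, k))
    vals[iu] = vec
    vals.T[iu] = vec
    return vals


def pli_matrix(
    trials,
    band: str = "",
    condition: str = "",
    subject: int | None = None,
    trim_frac: float = DEFAULT_TRIM,
) -> PLIMatrix:
    """Trial-averaged all-pairs PLI matrix.

    ``trials`` is an iterable of (K x d) arrays (or ROITimeSeries), one per
    trial.  The PLI is computed per trial then averaged arithmetically;
    trials containing a constant ROI series (undefined phase) are dropped
    with a logged warning.
    """
    mats = []
    M = 0
    dropped = 0
    for tr in trials:
        arr = tr.data if isinstance(tr, ROITimeSeries) else np.asarray(tr, dtype=float)
        vals = _pli_matrix_one_trial(arr, trim_frac)
        if vals is None:
            dropped += 1
            continue
        sl = _trim_slice(arr.shape[1], trim_frac)
        M = sl.stop - sl.start
        mats.append(vals)
    if dropped:
        logger.warning("dropped %d trial(s) with undefined phase", dropped)
    if not mats:
        raise ValueError("no usable trials (all had undefined phase or none given)")
    mean = np.mean(mats, axis=0)
    mean = 0.5 * (mean + mean.T)  # enforce exact symmetry against fp drift
    np.fill_diagonal(mean, 0.0)
    return PLIMatrix(
        values=np.clip(mean, 0.0, 1.0),
        band=band,
        condition=condition,
        subject=subject,
        M=M,
        n_trials=len(mats),
    )
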