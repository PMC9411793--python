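"""Minimal EEG conditioning: re-referencing, zero-phase FIR band-pass,
baseline correction, and per-band decomposition.

All operations are linear, deterministic, and shape/time-axis preserving, so
filtering and re-referencing commute.  Filtering is applied zero-phase
(forward-backward) because the downstream phase-lag analysis must not be
corrupted by filter delay.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

__all__ = [
    "SensorEpochs",
    "BandDefinition",
    "DEFAULT_BANDS",
    "rereference_common_average",
    "bandpass_fir",
    "baseline_correct",
    "band_decompose",
]


@dataclass(frozen=True)
class SensorEpochs:
    """Trial-level sensor data: (m channels, d samples, n trials), microvolts."""

    data: np.ndarray
    time_axis: np.ndarray
    sampling_rate: float
    condition: str = ""
    reference: str = "original"  # or "common_average"

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim == 2:
            d = d[:, :, None]
        if d.ndim != 3:
            raise ValueError("data must be (channels, samples[, trials])")
        if d.shape[1] != np.asarray(self.time_axis).size:
            raise ValueError("time_axis length does not match sample count")
        object.__setattr__(self, "data", d)
        object.__setattr__(self, "time_axis", np.asarray(self.time_axis, dtype=float))

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]


@dataclass(frozen=True)
class BandDefinition:
    """A named analysis frequency band [lo, hi] Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"band {self.name}: lo must be < hi")


#: The five analysis bands: delta 1-3, theta 3-8, alpha 8-13, beta 13-30,
#: gamma 30-40 Hz.  Adjacent bands share their single edge frequency.
DEFAULT_BANDS = (
    BandDefinition("delta", 1.0, 3.0),
    BandDefinition("theta", 3.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 40.0),
)


def _as_epochs(x) -> tuple[np.ndarray, SensorEpochs | None]:
    if isinstance(x, SensorEpochs):
        return x.data, x
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    return arr, None


def rereference_common_average(epochs):
    """Subtract the instantaneous mean across channels (common average
    reference).  Idempotent; rejects single-channel input."""
    data, container = _as_epochs(epochs)
    if data.shape[0] < 2:
        raise ValueError("common-average reference needs at least 2 channels")
    out = data - data.mean(axis=0, keepdims=True)
    if container is None:
        return out if np.asarray(epochs).ndim == 3 else out[:, :, 0]
    return replace(container, data=out, reference="common_average")


def design_bandpass(
    lo: float, hi: float, sampling_rate: float, n_samples: int
) -> np.ndarray:
    """Linear-phase FIR taps for the band [lo, hi].

    Tap count is 3 carrier cycles of the low edge (3 * fs / lo), capped at a
    third of the data length so forward-backward application remains
    well-conditioned on short epochs, and forced odd.  A low edge below half
    a cycle per record is unrealizable at the record length and the filter
    degrades to a low-pass at ``hi`` (the high-pass role is then carried by
    baseline correction).
    """
    nyq = sampling_rate / 2.0
    if not 0 <= lo < hi < nyq:
        raise ValueError(f"band edges ({lo}, {hi}) out of range for fs={sampling_rate}")
    record_len = n_samples / sampling_rate
    lowpass_only = lo <= 0 or lo < 0.5 / record_len
    ntaps = int(min(3 * sampling_rate / max(lo, 1e-12), n_samples // 3))
    if lowpass_only:
        ntaps = int(min(3 * sampling_rate / hi * 4, n_samples // 3))
    ntaps = max(ntaps, 9)
    if ntaps % 2 == 0:
        ntaps -= 1
    if lowpass_only:
        return signal.firwin(ntaps, hi, fs=sampling_rate)
    return signal.firwin(ntaps, [lo, hi], pass_zero=False, fs=sampling_rate)


def bandpass_fir(epochs, lo: float, hi: float):
    """Zero-phase FIR band-pass via forward-backward filtering."""
    data, container = _as_epochs(epochs)
    fs = container.sampling_rate if container is not None else None
    if fs is None:
        raise ValueError("pass a SensorEpochs or use bandpass_fir_array with fs")
    out = bandpass_fir_array(data, lo, hi, fs)
    return replace(container, data=out)


def bandpass_fir_array(
    data: np.ndarray, lo: float, hi: float, sampling_rate: float, axis: int = 1
) -> np.ndarray:
    """Array form of :func:`bandpass_fir`; filters along ``axis``."""
    data = np.asarray(data, dtype=float)
    n = data.shape[axis]
    taps = design_bandpass(lo, hi, sampling_rate, n)
    padlen = min(3 * taps.size, n - 1)
    return signal.filtfilt(taps, [1.0], data, axis=axis, padlen=padlen)


def baseline_correct(epochs, t0: float = -0.200, t1: float = 0.0):
    """Subtract, per channel and trial, the mean over the [t0, t1] window."""
    data, container = _as_epochs(epochs)
    if container is None:
        raise ValueError("baseline correction needs a SensorEpochs (time axis)")
    t = container.time_axis
    win = (t >= t0) & (t <= t1)
    if not win.any():
        raise ValueError(f"empty baseline window [{t0}, {t1}]")
    base = data[:, win, :].mean(axis=1, keepdims=True)
    return replace(container, data=data - base)


def band_decompose(epochs, bands=DEFAULT_BANDS) -> dict:
    """One zero-phase filtered copy per band; the input is left untouched."""
    return {b.name: bandpass_fir(epochs, b.lo, b.hi) for b in bands}
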