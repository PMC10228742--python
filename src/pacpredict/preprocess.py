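"""Filtering front end: notch, Butterworth band decomposition, artifact hook.

All filters are applied zero-phase (forward-backward) so that downstream
Hilbert phase estimates carry no group delay.  Filters are always applied to
the full continuous record, never to individual 30-s windows, to keep edge
transients out of the analysis windows.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "Band",
    "CANONICAL_BAND_EDGES",
    "canonical_bands",
    "notch_filter",
    "bandpass",
    "decompose_bands",
    "ica_hook",
]

#: canonical human-EEG band edges in Hz
CANONICAL_BAND_EDGES = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 80.0),
}

#: fraction of the sampling rate used to cap a band's upper edge
_UPPER_EDGE_CAP = 0.45


@dataclass(frozen=True)
class Band:
    """A named frequency band ``[lo, hi]`` in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.lo < self.hi):
            raise ValueError(f"band {self.name}: need 0 <= lo < hi, got [{self.lo}, {self.hi}]")

    def validate_for_fs(self, fs: float) -> None:
        if self.hi >= fs / 2:
            raise ValueError(
                f"band {self.name} upper edge {self.hi} Hz is at or above Nyquist ({fs / 2} Hz)"
            )


def canonical_bands(fs: float, exclude_delta: bool = False) -> list[Band]:
    """Return the canonical bands valid for sampling rate *fs*.

    The upper edge of the highest band is capped at ``0.45 * fs`` so that the
    gamma band stays realizable at low sampling rates.  ``exclude_delta``
    drops the delta band (used for recordings that were high-pass
    pre-filtered at acquisition time).
    """
    bands = []
    for name, (lo, hi) in CANONICAL_BAND_EDGES.items():
        if exclude_delta and name == "delta":
            continue
        hi = min(hi, _UPPER_EDGE_CAP * fs)
        if hi <= lo:
            continue  # band not realizable at this rate
        bands.append(Band(name, lo, hi))
    return bands


def notch_filter(x: np.ndarray, fs: float, line_freq: float, q: float = 30.0) -> np.ndarray:
    """Remove power-line interference at *line_freq* with a zero-phase IIR notch.

    Parameters
    ----------
    x : array, shape (n,) or (channels, n)
    fs : sampling rate in Hz
    line_freq : notch centre frequency in Hz (50 or 60 for mains)
    q : notch quality factor; bandwidth is ``line_freq / q``
    """
    if line_freq >= fs / 2:
        raise ValueError(f"line frequency {line_freq} Hz is at or above Nyquist ({fs / 2} Hz)")
    if line_freq <= 0:
        raise ValueError("line frequency must be positive")
    b, a = sps.iirnotch(line_freq, q, fs=fs)
    return sps.filtfilt(b, a, np.asarray(x, dtype=float), axis=-1)


def bandpass(x: np.ndarray, fs: float, band: Band, order: int = 5) -> np.ndarray:
    """Zero-phase Butterworth band-pass of *x* into *band*.

    A 5th-order design applied forward-backward (effective order doubled,
    magnitude squared) so the phase response is identically zero.
    """
    band.validate_for_fs(fs)
    sos = sps.butter(order, (band.lo, band.hi), btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def decompose_bands(
    x: np.ndarray,
    fs: float,
    bands: Optional[Sequence[Band]] = None,
    exclude_delta: bool = False,
    order: int = 5,
) -> dict[str, np.ndarray]:
    """Band-pass *x* into every band; returns ``{band name: filtered signal}``."""
    if bands is None:
        bands = canonical_bands(fs, exclude_delta=exclude_delta)
    bands = list(bands)
    if not bands:
        raise ValueError("empty band list")
    return {b.name: bandpass(x, fs, b, order=order) for b in bands}


def ica_hook(
    signal: np.ndarray,
    spec: Optional[Mapping[str, object]] = None,
) -> np.ndarray:
    """Artifact-removal hook; a no-op unless an unmixing spec is supplied.

    Automatic artifact-component selection is deliberately not implemented
    (it requires manual judgement on clinical data and synthetic data needs
    none).  A caller that has run ICA externally can pass
    ``{"unmixing": W, "reject": [component indices]}`` where ``W`` maps
    channels to components; the rejected components are zeroed and the data
    reconstructed.
    """
    if spec is None:
        return signal
    w = np.asarray(spec["unmixing"], dtype=float)
    reject = list(spec.get("reject", []))
    sources = w @ signal
    sources[reject, :] = 0.0
    return np.linalg.pinv(w) @ sources
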