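"""Per-window, per-channel features: phase-amplitude coupling and band spectra.

The coupling measure is the modulation index: the high-band amplitude
envelope is averaged inside 18 bins of low-band phase (20 degrees each,
spanning -180 to 180), the binned means are normalized to a distribution
``P``, and the Kullback-Leibler distance of ``P`` from uniform is expressed
as a fraction of its maximum::

    H(P) = -sum_j P(j) log P(j)
    MI   = (log N - H(P)) / log N

MI is 0 for a flat envelope and 1 when all amplitude concentrates in one
phase bin, and does not depend on the logarithm base.  Spectral features are
the Welch-PSD peak frequency and median frequency inside each band.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.signal import hilbert, welch

from .preprocess import Band, bandpass, canonical_bands
from .segmentation import WindowSet
from .synthetic import Recording

logger = logging.getLogger(__name__)

__all__ = [
    "N_PHASE_BINS",
    "PhaseAmpPair",
    "AmplitudeDistribution",
    "FeatureConfig",
    "band_pairs",
    "instantaneous_phase",
    "amplitude_envelope",
    "amplitude_distribution",
    "modulation_index",
    "comodulogram",
    "mi_surrogate_null",
    "spectral_features",
    "build_feature_table",
]

#: number of phase bins (18 bins of 20 degrees)
N_PHASE_BINS = 18

#: metadata columns of a feature table (everything else is a feature)
META_COLUMNS = ("channel", "window_start", "label", "seizure_id")


@dataclass(frozen=True)
class PhaseAmpPair:
    """A (low phase band, high amplitude band) pair; amp band strictly higher."""

    phase_band: Band
    amp_band: Band

    def __post_init__(self) -> None:
        if self.amp_band.lo < self.phase_band.hi:
            raise ValueError(
                f"amplitude band {self.amp_band.name} is not strictly above "
                f"phase band {self.phase_band.name}"
            )

    @property
    def name(self) -> str:
        return f"{self.phase_band.name}_{self.amp_band.name}"


@dataclass(frozen=True)
class AmplitudeDistribution:
    """Normalized phase-binned mean amplitudes ``P(j)``, ``j = 1..n_bins``."""

    p: np.ndarray
    n_bins: int = N_PHASE_BINS

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "p", p)
        if p.shape != (self.n_bins,):
            raise ValueError(f"expected {self.n_bins} bins, got shape {p.shape}")
        if np.any(p < 0):
            raise ValueError("distribution entries must be non-negative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"distribution must sum to 1, got {p.sum()!r}")

    @property
    def bin_edges(self) -> np.ndarray:
        return np.linspace(-180.0, 180.0, self.n_bins + 1)


def band_pairs(bands: Sequence[Band]) -> list[PhaseAmpPair]:
    """All lower-triangle (phase, amplitude) pairs from an ordered band list."""
    ordered = sorted(bands, key=lambda b: b.lo)
    return [
        PhaseAmpPair(lo, hi)
        for i, lo in enumerate(ordered)
        for hi in ordered[i + 1 :]
        if hi.lo >= lo.hi
    ]


def instantaneous_phase(band_signal: np.ndarray) -> np.ndarray:
    """Analytic-signal phase of a band-limited signal, in degrees (-180, 180]."""
    x = np.asarray(band_signal, dtype=float)
    if not np.any(x):
        raise ValueError("phase of an all-zero signal is undefined")
    return np.degrees(np.angle(hilbert(x)))


def amplitude_envelope(band_signal: np.ndarray) -> np.ndarray:
    """Analytic-signal modulus (instantaneous amplitude) of a band signal."""
    return np.abs(hilbert(np.asarray(band_signal, dtype=float)))


def amplitude_distribution(
    phase: np.ndarray, amplitude: np.ndarray, n_bins: int = N_PHASE_BINS
) -> AmplitudeDistribution:
    """Mean amplitude per phase bin, normalized to sum to one.

    Bin ``j`` (0-based) covers ``[-180 + j*width, -180 + (j+1)*width)``
    degrees with ``width = 360 / n_bins``; a phase of exactly +180 maps to
    the last bin.  Empty bins contribute a zero mean.
    """
    phase = np.asarray(phase, dtype=float)
    amplitude = np.asarray(amplitude, dtype=float)
    if phase.shape != amplitude.shape or phase.ndim != 1:
        raise ValueError("phase and amplitude must be 1-D arrays of equal length")
    if n_bins < 2:
        raise ValueError("need at least 2 phase bins")
    if not np.any(amplitude):
        raise ValueError("all-zero amplitude sequence")
    if np.any(phase < -180.0) or np.any(phase > 180.0):
        raise ValueError("phase values must lie in [-180, 180] degrees")
    width = 360.0 / n_bins
    idx = np.floor((phase + 180.0) / width).astype(np.intp)
    idx[idx == n_bins] = n_bins - 1
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=amplitude, minlength=n_bins)
    means = np.divide(sums, counts, out=np.zeros(n_bins), where=counts > 0)
    return AmplitudeDistribution(p=means / means.sum(), n_bins=n_bins)


def modulation_index(dist: Union[AmplitudeDistribution, np.ndarray]) -> float:
    """KL-to-uniform of a phase-binned amplitude distribution, in [0, 1]."""
    if isinstance(dist, AmplitudeDistribution):
        p = dist.p
    else:
        p = np.asarray(dist, dtype=float)
        if abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0):
            raise ValueError("distribution must be non-negative and sum to 1")
    n = p.size
    nz = p > 0
    entropy = -float(np.sum(p[nz] * np.log(p[nz])))  # 0 * log 0 := 0
    mi = (math.log(n) - entropy) / math.log(n)
    return min(max(mi, 0.0), 1.0)


def comodulogram(
    window_signal: np.ndarray,
    fs: float,
    pairs: Optional[Sequence[PhaseAmpPair]] = None,
    bands: Optional[Sequence[Band]] = None,
    exclude_delta: bool = False,
    n_bins: int = N_PHASE_BINS,
) -> dict[str, float]:
    """MI for every (phase, amplitude) band pair of one window.

    Filters the window itself; for the table-building path prefer
    :func:`build_feature_table`, which filters the full record once.
    """
    if pairs is None:
        if bands is None:
            bands = canonical_bands(fs, exclude_delta=exclude_delta)
        pairs = band_pairs(bands)
    x = np.asarray(window_signal, dtype=float)
    needed = {p.phase_band for p in pairs} | {p.amp_band for p in pairs}
    filtered = {b.name: bandpass(x, fs, b) for b in needed}
    phases = {p.phase_band.name for p in pairs}
    amps = {p.amp_band.name for p in pairs}
    phase = {name: instantaneous_phase(filtered[name]) for name in phases}
    env = {name: amplitude_envelope(filtered[name]) for name in amps}
    return {
        p.name: modulation_index(
            amplitude_distribution(phase[p.phase_band.name], env[p.amp_band.name], n_bins)
        )
        for p in pairs
    }


def mi_surrogate_null(
    phase: np.ndarray,
    amplitude: np.ndarray,
    n_perm: int = 200,
    seed: int = 0,
    n_bins: int = N_PHASE_BINS,
) -> np.ndarray:
    """Circular-shift surrogate MI distribution (phase/amplitude decoupled)."""
    amplitude = np.asarray(amplitude, dtype=float)
    n = amplitude.size
    rng = np.random.default_rng(seed)
    shifts = rng.integers(1, n, size=n_perm)
    return np.array(
        [
            modulation_index(amplitude_distribution(phase, np.roll(amplitude, s), n_bins))
            for s in shifts
        ]
    )


def _peak_median(freqs: np.ndarray, psd: np.ndarray, band: Band) -> tuple[float, float]:
    mask = (freqs >= band.lo) & (freqs <= band.hi)
    if not mask.any() or psd[mask].sum() <= 0:
        raise ValueError(f"zero power in band {band.name}")
    fb, pb = freqs[mask], psd[mask]
    peak = float(fb[int(np.argmax(pb))])
    cum = np.cumsum(pb)
    median = float(fb[int(np.searchsorted(cum, cum[-1] / 2.0))])
    return peak, median


def spectral_features(
    window_signal: np.ndarray,
    fs: float,
    band: Band,
    seg_s: float = 2.0,
    overlap: float = 0.5,
) -> tuple[float, float]:
    """(peak frequency, median frequency) of the band-filtered window.

    Welch PSD with Hann-tapered ``seg_s``-second segments at fractional
    *overlap*; peak is the PSD argmax inside the band, median the lowest
    frequency at which cumulative band power reaches half the total.
    """
    x = bandpass(np.asarray(window_signal, dtype=float), fs, band)
    nperseg = int(round(seg_s * fs))
    if x.size < 2 * nperseg * (1 - overlap) + nperseg * overlap:
        raise ValueError("window too short for two Welch segments")
    freqs, psd = welch(x, fs=fs, window="hann", nperseg=nperseg, noverlap=int(nperseg * overlap))
    return _peak_median(freqs, psd, band)


@dataclass(frozen=True)
class FeatureConfig:
    """What to compute per window and channel."""

    feature_set: str = "both"  # 'pac' | 'spectral' | 'both'
    exclude_delta: bool = False
    pairs: Optional[Sequence[tuple[str, str]]] = None  # band-name pairs; None = all
    spectral_bands: Optional[Sequence[str]] = None  # band names; None = all
    channels: Optional[Sequence[str]] = None
    edge_guard_s: float = 1.0
    welch_seg_s: float = 2.0
    n_bins: int = N_PHASE_BINS

    def __post_init__(self) -> None:
        if self.feature_set not in ("pac", "spectral", "both"):
            raise ValueError(f"feature_set must be pac|spectral|both, got {self.feature_set!r}")


def _resolve_pairs(config: FeatureConfig, bands: Sequence[Band]) -> list[PhaseAmpPair]:
    if config.pairs is None:
        return band_pairs(bands)
    by_name = {b.name: b for b in bands}
    out = []
    for lo_name, hi_name in config.pairs:
        if lo_name not in by_name or hi_name not in by_name:
            raise ValueError(f"unknown band in pair ({lo_name}, {hi_name})")
        out.append(PhaseAmpPair(by_name[lo_name], by_name[hi_name]))
    return out


def build_feature_table(
    recording: Recording,
    windows: WindowSet,
    config: FeatureConfig = FeatureConfig(),
) -> pd.DataFrame:
    """One feature row per (window, channel).

    Band filtering, phase and envelope are computed once on the full
    continuous record and sliced per window, so no window sees a filter
    edge transient.  Windows that would reach within ``edge_guard_s`` of
    the record boundary (or past its end) are skipped with a log entry.
    Columns: ``mi_<phase>_<amp>`` per pair and/or ``peak_<band>`` /
    ``median_<band>``, plus channel, window_start, label, seizure_id.
    """
    fs = recording.fs
    bands = canonical_bands(fs, exclude_delta=config.exclude_delta)
    pairs = _resolve_pairs(config, bands) if config.feature_set in ("pac", "both") else []
    if config.feature_set in ("spectral", "both"):
        wanted = config.spectral_bands
        spec_bands = [b for b in bands if wanted is None or b.name in wanted]
    else:
        spec_bands = []

    feat_cols = [f"mi_{p.name}" for p in pairs]
    feat_cols += [c for b in spec_bands for c in (f"peak_{b.name}", f"median_{b.name}")]
    columns = list(META_COLUMNS) + feat_cols

    channel_names = list(recording.channel_names)
    if config.channels is not None:
        missing = [c for c in config.channels if c not in channel_names]
        if missing:
            raise ValueError(f"channels not in recording: {missing}")
        channel_names = list(config.channels)

    w_n = int(round(windows.window_s * fs))
    guard_n = int(round(config.edge_guard_s * fs))
    n_samp = recording.n_samples
    nperseg = int(round(config.welch_seg_s * fs))

    phase_names = {p.phase_band.name for p in pairs}
    amp_names = {p.amp_band.name for p in pairs}
    needed = {b.name: b for b in bands if b.name in (phase_names | amp_names)}
    for b in spec_bands:
        needed[b.name] = b

    rows = []
    for ch_name in channel_names:
        x = recording.signal[recording.channel_names.index(ch_name)]
        band_sig = {name: bandpass(x, fs, b) for name, b in needed.items()}
        phase = {n_: instantaneous_phase(band_sig[n_]) for n_ in phase_names}
        env = {n_: amplitude_envelope(band_sig[n_]) for n_ in amp_names}
        for win in windows:
            i0 = int(round(win.start_s * fs))
            i1 = i0 + w_n
            if i0 < guard_n or i1 > n_samp - guard_n:
                logger.info(
                    "window at %.1f s on %s skipped (record edge)", win.start_s, ch_name
                )
                continue
            row = {
                "channel": ch_name,
                "window_start": win.start_s,
                "label": win.label,
                "seizure_id": win.seizure_id,
            }
            for p in pairs:
                amp_slice = env[p.amp_band.name][i0:i1]
                if not np.any(amp_slice):
                    row[f"mi_{p.name}"] = np.nan
                    continue
                dist = amplitude_distribution(
                    phase[p.phase_band.name][i0:i1], amp_slice, config.n_bins
                )
                row[f"mi_{p.name}"] = modulation_index(dist)
            for b in spec_bands:
                seg = band_sig[b.name][i0:i1]
                freqs, psd = welch(
                    seg, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2
                )
                peak, median = _peak_median(freqs, psd, b)
                row[f"peak_{b.name}"] = peak
                row[f"median_{b.name}"] = median
            rows.append(row)
    return pd.DataFrame(rows, columns=columns)
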