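"""Band-wise power-spectral-density node features.

Each windowed segment is reduced to a channels x bands matrix: the PSD of
every channel is estimated (Welch by default, plain periodogram available),
averaged within the theta/alpha/beta/gamma bands, and z-scored per
(channel, band) with statistics fitted on training segments only. The
resulting feature cube is the node representation consumed by the graph
classifier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .preprocess import SegmentSet
from .synthetic import BAND_EDGES

__all__ = [
    "BandSpec",
    "FeatureCube",
    "NormalizationStats",
    "default_bands",
    "psd",
    "band_average",
    "segment_features",
    "fit_normalizer",
    "apply_normalizer",
]

PsdMethod = Literal["welch", "periodogram"]


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band [lo, hi) in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0 < self.lo < self.hi:
            raise ValueError(f"band {self.name}: need 0 < lo < hi")


def default_bands() -> list[BandSpec]:
    """theta 4-8, alpha 8-13, beta 13-30, gamma 30-45 Hz."""
    return [BandSpec(name, lo, hi) for name, (lo, hi) in BAND_EDGES.items()]


@dataclass(frozen=True)
class NormalizationStats:
    """Per-(channel, band) mean and population standard deviation."""

    mean: np.ndarray
    std: np.ndarray


@dataclass
class FeatureCube:
    """Node features: segments x channels x bands (band-average PSD).

    ``values`` is in uV^2/Hz before normalization and unitless after;
    ``normalization_stats`` is set once a normalizer has been applied.
    """

    values: np.ndarray
    band_specs: list[BandSpec]
    labels: np.ndarray | None = None
    normalization_stats: NormalizationStats | None = None

    @property
    def n_segments(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def channel_vectors(self) -> np.ndarray:
        """Per-channel observation vectors (channels x (segments*bands)),
        the input to functional-connectivity estimation."""
        return np.transpose(self.values, (1, 0, 2)).reshape(self.n_channels, -1)

    def to_frame(self, channel_names: Sequence[str] | None = None) -> pd.DataFrame:
        """Tabular export: one row per (segment, channel), band columns."""
        n_seg, n_ch, n_b = self.values.shape
        names = (
            list(channel_names)
            if channel_names is not None
            else [f"ch{i}" for i in range(n_ch)]
        )
        df = pd.DataFrame(
            self.values.reshape(n_seg * n_ch, n_b),
            columns=[b.name for b in self.band_specs],
        )
        df.insert(0, "channel", np.tile(names, n_seg))
        df.insert(0, "segment", np.repeat(np.arange(n_seg), n_ch))
        return df


def psd(
    segment: np.ndarray,
    fs: float,
    method: PsdMethod = "welch",
    *,
    subwindow_seconds: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided PSD estimate per channel.

    The estimator is the finite-sample squared-magnitude Fourier spectrum
    scaled by duration (density scaling), so that the integral of the PSD
    over frequency matches the time-domain signal variance (Parseval).
    Welch's method (Hann window, ``subwindow_seconds`` sub-windows, 50%
    overlap) is the default; ``method="periodogram"`` gives the plain
    single-window estimate.

    Returns ``(freqs, power)`` with ``power`` shaped channels x frequencies.
    """
    x = np.asarray(segment, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[-1] < 2:
        raise ValueError("need at least 2 samples")
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    if np.isnan(x).any():
        raise ValueError("segment contains NaN")
    if not np.any(x):
        raise ValueError("segment is identically zero")
    if method == "welch":
        nperseg = min(round(subwindow_seconds * fs), x.shape[-1])
        freqs, power = sps.welch(
            x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2,
            detrend=False, scaling="density", axis=-1,
        )
    elif method == "periodogram":
        freqs, power = sps.periodogram(
            x, fs=fs, window="boxcar", detrend=False, scaling="density", axis=-1
        )
    else:
        raise ValueError(f"unknown PSD method {method!r}")
    return freqs, power


def band_average(
    psd_array: np.ndarray, freqs: np.ndarray, band_specs: Iterable[BandSpec]
) -> np.ndarray:
    """Mean PSD over the bins with center frequency in [lo, hi) per band.

    Returns channels x bands (an extra leading axis, e.g. segments, is
    carried through).
    """
    psd_array = np.asarray(psd_array, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    cols = []
    for band in band_specs:
        if band.hi > freqs[-1] + 1e-9:
            raise ValueError(
                f"band {band.name} [{band.lo}, {band.hi}) exceeds the "
                f"frequency axis (max {freqs[-1]:g} Hz)"
            )
        mask = (freqs >= band.lo) & (freqs < band.hi)
        if not mask.any():
            raise ValueError(f"band {band.name} contains no frequency bins")
        cols.append(psd_array[..., mask].mean(axis=-1))
    return np.stack(cols, axis=-1)


def segment_features(
    segs: SegmentSet,
    band_specs: Sequence[BandSpec] | None = None,
    method: PsdMethod = "welch",
) -> FeatureCube:
    """Band-average PSD features for every segment of a SegmentSet."""
    bands = list(band_specs) if band_specs is not None else default_bands()
    pooled = segs.flatten()  # (trials*segments) x channels x window
    freqs, power = psd(
        pooled.reshape(-1, pooled.shape[-1]), segs.sampling_rate, method
    )
    power = power.reshape(pooled.shape[0], pooled.shape[1], -1)
    values = band_average(power, freqs, bands)
    return FeatureCube(values=values, band_specs=bands)


def fit_normalizer(features: FeatureCube | np.ndarray) -> NormalizationStats:
    """Per-(channel, band) mean and population (1/N) standard deviation
    over a training population of segments."""
    x = features.values if isinstance(features, FeatureCube) else np.asarray(features)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 training segments to fit")
    mean = x.mean(axis=0)
    std = x.std(axis=0, ddof=0)
    if np.any(std == 0):
        ch, band = map(int, np.argwhere(std == 0)[0])
        raise ValueError(
            f"degenerate feature: zero variance at channel {ch}, band {band}"
        )
    return NormalizationStats(mean=mean, std=std)


def apply_normalizer(
    features: FeatureCube, stats: NormalizationStats
) -> FeatureCube:
    """z = (x - mu) / sigma using stored statistics (no refit)."""
    z = (features.values - stats.mean) / stats.std
    return FeatureCube(
        values=z,
        band_specs=features.band_specs,
        labels=features.labels,
        normalization_stats=stats,
    )
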