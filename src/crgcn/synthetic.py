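"""Synthetic multichannel EEG with known class structure.

Generates trial arrays in the DEAP per-subject layout (trials x channels x
samples at 128 Hz; 3 s pre-stimulus baseline followed by 60 s of stimulus)
so that every downstream stage — baseline calibration, segmentation, band
PSD features, connectivity graphs, the classifier — can be exercised with a
known ground truth. Each trial is a sum of three components:

1. broadband 1/f-shaped noise, spatially correlated across channels with an
   exponential decay over inter-electrode distance;
2. band-limited oscillations (theta/alpha/beta/gamma) whose amplitudes are
   scaled per the trial's binary class through ``band_effect``, planting a
   recoverable class signal in band power;
3. a trial-invariant additive artifact, periodic with the baseline duration
   and present in both windows, standing in for stimulus-unrelated activity
   that baseline calibration must cancel exactly.

Only the statistical structure the method consumes is emulated — no dipole
forward model, no ocular or muscular artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .montage import Montage, deap32_montage

__all__ = [
    "SynthConfig",
    "TrialSet",
    "generate_trialset",
    "write_trialset",
    "read_trialset",
    "BAND_EDGES",
]

#: Conventional band edges (Hz); the 45 Hz ceiling matches DEAP's
#: preprocessing low-pass.
BAND_EDGES: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}

#: Baseline oscillation amplitudes (uV), class-independent before the
#: per-class multipliers of ``band_effect`` are applied.
_BASE_AMP: dict[str, float] = {
    "theta": 4.0,
    "alpha": 8.0,
    "beta": 3.0,
    "gamma": 3.0,
}

_N_RATING_AXES = 4  # valence, arousal, dominance, liking


def _default_band_effect() -> dict[str, tuple[float, float]]:
    # class 0 / class 1 amplitude multipliers per band; the gamma boost is
    # the planted, recoverable class signal
    return {"gamma": (1.0, 2.0)}


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic EEG generator.

    Attributes
    ----------
    band_effect : mapping band name -> (class0, class1) amplitude multipliers
        Oscillation amplitude scaling per class; bands absent from the map
        get multiplier 1 for both classes.
    spatial_corr_scale : float
        Decay length (unit head-radius scale) of the exponential
        inter-channel noise correlation; larger = smoother across the scalp.
    baseline_artifact_amp : float
        Amplitude (uV) of the injected trial-invariant artifact.
    channel_scale_spread : float
        Log-uniform half-width of a per-channel gain confound (0 disables);
        used to engineer scale heterogeneity that feature normalization
        should absorb.
    """

    n_subjects: int = 1
    n_trials_per_subject: int = 40
    n_channels: int = 32
    sampling_rate: float = 128.0
    baseline_seconds: float = 3.0
    stimulus_seconds: float = 60.0
    band_effect: Mapping[str, tuple[float, float]] = field(
        default_factory=_default_band_effect
    )
    noise_amp: float = 20.0
    spatial_corr_scale: float = 0.5
    baseline_artifact_amp: float = 10.0
    channel_scale_spread: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValueError("n_channels must be >= 2")
        for name in ("sampling_rate", "baseline_seconds", "stimulus_seconds",
                     "noise_amp", "spatial_corr_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.baseline_artifact_amp < 0 or self.channel_scale_spread < 0:
            raise ValueError("amplitudes must be nonnegative")
        total = (self.baseline_seconds + self.stimulus_seconds) * self.sampling_rate
        if abs(total - round(total)) > 1e-9:
            raise ValueError("total samples per trial must be an integer")

    @property
    def n_samples(self) -> int:
        return round(
            (self.baseline_seconds + self.stimulus_seconds) * self.sampling_rate
        )

    @property
    def n_baseline_samples(self) -> int:
        return round(self.baseline_seconds * self.sampling_rate)


@dataclass
class TrialSet:
    """Raw or calibrated trials for one subject.

    ``data`` is trials x channels x samples in uV; ``ratings`` is trials x 4
    on the 1-9 scale (valence, arousal, dominance, liking);
    ``baseline_seconds`` gives the length of the pre-stimulus window at the
    start of each trial (0 after calibration).
    """

    data: np.ndarray
    ratings: np.ndarray
    sampling_rate: float
    baseline_seconds: float
    subject_id: str = "synthetic"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.ratings = np.asarray(self.ratings, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be trials x channels x samples, got {self.data.shape}"
            )
        if self.ratings.shape != (self.data.shape[0], _N_RATING_AXES):
            raise ValueError(
                f"ratings must be shaped {self.data.shape[0]} x {_N_RATING_AXES}, "
                f"got {self.ratings.shape}"
            )
        if np.any(self.ratings < 1) or np.any(self.ratings > 9):
            raise ValueError("ratings must lie in [1, 9]")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def stimulus_seconds(self) -> float:
        return self.data.shape[2] / self.sampling_rate - self.baseline_seconds


def _spatial_mixing(montage: Montage, n_channels: int, scale: float) -> np.ndarray:
    """Cholesky factor of the exponential distance covariance."""
    d = montage.pairwise_distances()[:n_channels, :n_channels]
    cov = np.exp(-d / scale)
    # jitter for numerical positive-definiteness
    return np.linalg.cholesky(cov + 1e-10 * np.eye(n_channels))


def _one_over_f_noise(
    rng: np.random.Generator, n_channels: int, n_samples: int, fs: float
) -> np.ndarray:
    """Unit-RMS 1/f-amplitude noise per channel (white across channels)."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = 1.0 / np.sqrt(freqs[nz])
    shaping[0] = 0.0  # no DC drift in the noise component
    shaped = np.fft.irfft(spec * shaping, n=n_samples, axis=1)
    rms = shaped.std(axis=1, keepdims=True)
    return shaped / rms


def generate_trialset(
    cfg: SynthConfig,
    class_labels: Sequence[int],
    *,
    montage: Montage | None = None,
    subject_id: str = "synthetic",
) -> TrialSet:
    """Generate one subject's trials with planted class structure.

    ``class_labels`` holds the binary class of each trial (length
    ``cfg.n_trials_per_subject``); class 1 trials get the boosted band
    amplitudes from ``cfg.band_effect`` and ratings 7/7 on valence/arousal,
    class 0 trials get ratings 3/3. Fully reproducible from ``cfg.seed``.
    """
    labels = np.asarray(class_labels)
    if labels.shape != (cfg.n_trials_per_subject,):
        raise ValueError(
            f"class_labels must have length {cfg.n_trials_per_subject}, "
            f"got {labels.shape}"
        )
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("class_labels must be binary (0/1)")
    if montage is None:
        montage = deap32_montage()
    if cfg.n_channels > len(montage):
        raise ValueError("montage has fewer channels than n_channels")

    fs = cfg.sampling_rate
    n_samples = cfg.n_samples
    t = np.arange(n_samples) / fs
    rng = np.random.default_rng(cfg.seed)
    mix = _spatial_mixing(montage, cfg.n_channels, cfg.spatial_corr_scale)

    # trial-invariant artifact: smooth waveform periodic with the baseline
    # duration, identical in every trial, drawn from its own substream so
    # setting its amplitude to zero leaves the other components unchanged
    art_rng = np.random.default_rng((cfg.seed, 0xA27))
    phase = art_rng.uniform(0, 2 * np.pi, size=(cfg.n_channels, 1))
    weights = art_rng.uniform(0.5, 1.0, size=(cfg.n_channels, 1))
    base_freq = 1.0 / cfg.baseline_seconds
    artifact = cfg.baseline_artifact_amp * weights * np.sin(
        2 * np.pi * base_freq * t[None, :] + phase
    )

    if cfg.channel_scale_spread > 0:
        gain_rng = np.random.default_rng((cfg.seed, 0x5CA1))
        log_gain = gain_rng.uniform(
            -cfg.channel_scale_spread, cfg.channel_scale_spread, cfg.n_channels
        )
        gains = np.exp(log_gain)[:, None]
    else:
        gains = np.ones((cfg.n_channels, 1))

    data = np.empty((cfg.n_trials_per_subject, cfg.n_channels, n_samples))
    for trial, label in enumerate(labels):
        noise = mix @ _one_over_f_noise(rng, cfg.n_channels, n_samples, fs)
        signal = cfg.noise_amp * noise
        for band, (lo, hi) in BAND_EDGES.items():
            mult = cfg.band_effect.get(band, (1.0, 1.0))[int(label)]
            amp = _BASE_AMP[band] * mult
            freqs = rng.uniform(lo, hi, size=cfg.n_channels)
            phases = rng.uniform(0, 2 * np.pi, size=cfg.n_channels)
            signal += amp * np.sin(
                2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]
            )
        data[trial] = gains * (signal + artifact)

    ratings = np.full((cfg.n_trials_per_subject, _N_RATING_AXES), 5.0)
    ratings[:, 0] = np.where(labels == 1, 7.0, 3.0)  # valence
    ratings[:, 1] = np.where(labels == 1, 7.0, 3.0)  # arousal
    return TrialSet(
        data=data,
        ratings=ratings,
        sampling_rate=fs,
        baseline_seconds=cfg.baseline_seconds,
        subject_id=subject_id,
    )


def write_trialset(ts: TrialSet, path: str | Path) -> None:
    """Write one subject to an ``.npz`` container with arrays ``data``
    (trials x channels x samples) and ``labels`` (trials x 4), mirroring the
    DEAP per-subject layout, plus scalar metadata."""
    np.savez(
        path,
        data=ts.data,
        labels=ts.ratings,
        sampling_rate=np.float64(ts.sampling_rate),
        baseline_seconds=np.float64(ts.baseline_seconds),
        subject_id=np.str_(ts.subject_id),
    )


def read_trialset(path: str | Path, *, n_eeg_channels: int = 32) -> TrialSet:
    """Read a per-subject container written by :func:`write_trialset`.

    Containers holding more than ``n_eeg_channels`` channels (DEAP stores 40:
    32 EEG + 8 peripheral) are accepted and truncated to the first
    ``n_eeg_channels`` EEG channels.
    """
    with np.load(path, allow_pickle=False) as f:
        try:
            data = f["data"]
            labels = f["labels"]
        except KeyError as exc:
            raise ValueError(f"malformed container: missing array {exc}") from exc
        if data.ndim != 3:
            raise ValueError(
                f"data must be trials x channels x samples, got {data.shape}"
            )
        if labels.shape != (data.shape[0], _N_RATING_AXES):
            raise ValueError(
                f"labels must be shaped {data.shape[0]} x {_N_RATING_AXES}, "
                f"got {labels.shape}"
            )
        if data.shape[1] > n_eeg_channels:
            data = data[:, :n_eeg_channels, :]
        fs = float(f["sampling_rate"]) if "sampling_rate" in f else 128.0
        base = float(f["baseline_seconds"]) if "baseline_seconds" in f else 3.0
        sid = str(f["subject_id"]) if "subject_id" in f else Path(path).stem
    return TrialSet(
        data=data,
        ratings=labels,
        sampling_rate=fs,
        baseline_seconds=base,
        subject_id=sid,
    )
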