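"""Baseline calibration, sliding-window segmentation, label binarization.

Calibration removes stimulus-unrelated activity: the per-channel mean over
the pre-stimulus baseline epochs (for the usual single 3 s epoch, the epoch
itself) is tiled across the 60 s stimulus window and subtracted sample-wise.
Segmentation then cuts the calibrated stimulus into overlapping windows of
``T`` seconds advanced by a stride of ``S`` seconds, yielding
``floor((stimulus - T)/S) + 1`` segments per trial, each inheriting its
trial's label. Continuous 1-9 affect ratings are binarized at 5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .synthetic import TrialSet

__all__ = [
    "SegmentSet",
    "calibrate_baseline",
    "segment",
    "binarize_labels",
    "n_segments_per_trial",
]

RatingAxis = Literal["valence", "arousal"]
_AXIS_COLUMN = {"valence": 0, "arousal": 1}


@dataclass
class SegmentSet:
    """Windowed trial data: trials x n_segments x channels x window samples."""

    segments: np.ndarray
    window_seconds: float
    stride_seconds: float
    sampling_rate: float
    ratings: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.segments.shape[0]

    @property
    def n_segments(self) -> int:
        return self.segments.shape[1]

    def flatten(self) -> np.ndarray:
        """All segments pooled: (trials * n_segments) x channels x samples."""
        t, s, c, w = self.segments.shape
        return self.segments.reshape(t * s, c, w)

    def segment_labels(self, axis: RatingAxis = "valence",
                       threshold: float = 5.0,
                       tie_rule: Literal["low", "high"] = "low") -> np.ndarray:
        """Per-segment binary labels: each segment inherits its trial's."""
        trial_labels = binarize_labels(
            self.ratings, axis=axis, threshold=threshold, tie_rule=tie_rule
        )
        return np.repeat(trial_labels, self.n_segments)


def n_segments_per_trial(stimulus_seconds: float, window_seconds: float,
                         stride_seconds: float) -> int:
    """Closed-form segment count ``floor((stimulus - T)/S) + 1``."""
    if window_seconds > stimulus_seconds:
        raise ValueError("window exceeds stimulus duration")
    if stride_seconds <= 0:
        raise ValueError("stride must be positive")
    return int(np.floor((stimulus_seconds - window_seconds) / stride_seconds)) + 1


def calibrate_baseline(ts: TrialSet) -> TrialSet:
    """Subtract the tiled baseline template from the stimulus window.

    The baseline window is split into epochs of ``baseline_seconds`` (one
    epoch in the standard layout; the per-sample mean is taken if several
    exist), the resulting template is replicated ``stimulus/baseline`` times
    to span the stimulus, and subtracted. Returns a TrialSet holding only
    the calibrated stimulus (``baseline_seconds = 0``). Any signal component
    that is identical in every baseline repetition — e.g. a trial-invariant
    artifact periodic with the baseline duration — cancels exactly.
    """
    fs = ts.sampling_rate
    nb = round(ts.baseline_seconds * fs)
    if nb <= 0:
        raise ValueError("trial set has no baseline window to calibrate with")
    n_total = ts.data.shape[2]
    n_stim = n_total - nb
    if n_stim <= 0:
        raise ValueError("trial shorter than baseline + stimulus")
    reps, rem = divmod(n_stim, nb)
    if rem != 0:
        raise ValueError(
            "stimulus length must be an integer multiple of the baseline "
            f"length (got {n_stim} vs {nb} samples): replication count "
            "undefined"
        )
    baseline = ts.data[:, :, :nb]
    # single epoch -> the epoch itself; kept as an explicit mean so multiple
    # pre-stimulus epochs, were they present, would average
    template = baseline.reshape(ts.n_trials, ts.n_channels, -1, nb).mean(axis=2)
    tiled = np.tile(template, (1, 1, reps))
    calibrated = ts.data[:, :, nb:] - tiled
    return TrialSet(
        data=calibrated,
        ratings=ts.ratings,
        sampling_rate=fs,
        baseline_seconds=0.0,
        subject_id=ts.subject_id,
    )


def segment(ts: TrialSet, window_seconds: float = 6.0,
            stride_seconds: float = 3.0) -> SegmentSet:
    """Cut each trial's stimulus into overlapping windows.

    Windows are sample-aligned half-open intervals ``[start, start + T*fs)``
    starting at 0, S, 2S, ...; no partial trailing window is emitted. The
    stimulus is whatever follows the baseline (the whole trial after
    calibration).
    """
    fs = ts.sampling_rate
    nb = round(ts.baseline_seconds * fs)
    stim = ts.data[:, :, nb:]
    stim_seconds = stim.shape[2] / fs
    win = window_seconds * fs
    hop = stride_seconds * fs
    if abs(win - round(win)) > 1e-9 or abs(hop - round(hop)) > 1e-9:
        raise ValueError("window and stride must map to integer sample counts")
    win, hop = round(win), round(hop)
    if win < 2:
        raise ValueError("window too short")
    count = n_segments_per_trial(stim_seconds, window_seconds, stride_seconds)
    starts = np.arange(count) * hop
    idx = starts[:, None] + np.arange(win)[None, :]
    segments = stim[:, :, idx]                       # trials x ch x seg x win
    segments = np.transpose(segments, (0, 2, 1, 3))  # trials x seg x ch x win
    return SegmentSet(
        segments=np.ascontiguousarray(segments),
        window_seconds=window_seconds,
        stride_seconds=stride_seconds,
        sampling_rate=fs,
        ratings=ts.ratings,
    )


def binarize_labels(ratings: np.ndarray, axis: RatingAxis = "valence",
                    threshold: float = 5.0,
                    tie_rule: Literal["low", "high"] = "low") -> np.ndarray:
    """Binary labels from continuous 1-9 ratings.

    Ratings above ``threshold`` map to 1 (positive/high), below to 0
    (negative/low). A rating exactly at the threshold follows ``tie_rule``
    ("low" by default — only the strict inequalities are inherent to the
    task definition).
    """
    ratings = np.asarray(ratings, dtype=float)
    if np.any(ratings < 1) or np.any(ratings > 9):
        raise ValueError("ratings must lie in [1, 9]")
    values = ratings[:, _AXIS_COLUMN[axis]] if ratings.ndim == 2 else ratings
    if tie_rule == "low":
        return (values > threshold).astype(int)
    return (values >= threshold).astype(int)
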