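"""Metrics, cross-validated experiment runners, and ablation harnesses.

The experiment runner wires the full pipeline per cross-validation fold:
baseline calibration -> segmentation -> band-PSD features -> normalizer
fitted on the training split only -> functional-connectivity matrix from
the training split only -> fused channel graph -> classifier training ->
evaluation on the held-out split. Subject-dependent runs cross-validate
within each subject; subject-independent runs pool all subjects' segments
into shared 80/20 folds; a leave-one-subject-out mode is provided as a
stricter extension.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from . import features as feats
from . import preprocess as prep
from .graph import (
    ChannelGraph,
    calibrate_delta,
    connectivity_adjacency,
    distance_adjacency,
    fuse,
)
from .model import ChebGCN, ModelConfig
from .montage import Montage, deap32_montage
from .synthetic import TrialSet

__all__ = [
    "ConfusionCounts",
    "FoldResult",
    "EvalReport",
    "ExperimentConfig",
    "accuracy",
    "f1",
    "confusion_counts",
    "kfold_splits",
    "run_experiment",
    "run_ablation",
]

Mode = Literal["subject-dependent", "subject-independent", "loso"]
Task = Literal["valence", "arousal"]
AdjacencyVariant = Literal["distance", "cc", "fused"]


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion-matrix counts."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.shape != yp.shape:
        raise ValueError("label and prediction vectors differ in length")
    if yt.size == 0:
        raise ValueError("empty evaluation set")
    return ConfusionCounts(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        fp=int(np.sum((yt == 0) & (yp == 1))),
        tn=int(np.sum((yt == 0) & (yp == 0))),
        fn=int(np.sum((yt == 1) & (yp == 0))),
    )


def accuracy(counts: ConfusionCounts) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    if counts.total == 0:
        raise ValueError("empty evaluation set")
    return (counts.tp + counts.tn) / counts.total


def f1(counts: ConfusionCounts) -> float:
    """2 TP / (2 TP + FP + FN); NaN (with a warning) when no positives
    exist in either labels or predictions, and excluded from averages."""
    denom = 2 * counts.tp + counts.fp + counts.fn
    if denom == 0:
        warnings.warn(
            "F1 undefined: no positive labels or predictions", stacklevel=2
        )
        return float("nan")
    return 2 * counts.tp / denom


def kfold_splits(
    n: int,
    k: int = 5,
    seed: int = 0,
    groups: np.ndarray | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Random k-fold partition of ``range(n)`` into (train, test) pairs.

    Test sets are pairwise disjoint and cover all indices. With ``groups``
    (e.g. trial ids per segment) the partition is made over unique groups
    and mapped back to indices, so no group straddles train and test.
    """
    if groups is not None:
        groups = np.asarray(groups)
        uniq = np.unique(groups)
        gsplits = kfold_splits(len(uniq), k=k, seed=seed)
        out = []
        for gtr, gte in gsplits:
            tr_mask = np.isin(groups, uniq[gtr])
            out.append((np.flatnonzero(tr_mask), np.flatnonzero(~tr_mask)))
        return out
    if k < 2 or k > n:
        raise ValueError(f"k must lie in [2, {n}]")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    return [
        (np.sort(np.concatenate(folds[:i] + folds[i + 1 :])), np.sort(folds[i]))
        for i in range(k)
    ]


@dataclass(frozen=True)
class ExperimentConfig:
    """End-to-end pipeline configuration.

    ``adjacency`` picks the graph variant: "distance" (topology only),
    "cc" (thresholded functional connectivity only), or "fused" (their
    entrywise sum, the default). ``normalize`` toggles z-scoring of node
    features on statistics from the training split.
    """

    window_seconds: float = 6.0
    stride_seconds: float = 3.0
    tie_rule: Literal["low", "high"] = "low"
    psd_method: feats.PsdMethod = "welch"
    adjacency: AdjacencyVariant = "fused"
    lam: float = 0.98
    normalize: bool = True
    delta_target: float = 0.2
    delta_cutoff: float = 0.1
    connectivity_source: Literal["features", "raw"] = "features"
    laplacian_scaling: Literal["as_printed", "chebnet"] = "as_printed"
    k_folds: int = 5
    split_granularity: Literal["segment", "trial"] = "segment"
    model: ModelConfig = field(default_factory=ModelConfig)
    seed: int = 0


@dataclass(frozen=True)
class FoldResult:
    subject: str
    fold: int
    accuracy: float
    f1: float
    n_train: int
    n_test: int
    split_hash: str


@dataclass
class EvalReport:
    """Per-fold and aggregate results of one experiment."""

    task: Task
    mode: Mode
    adjacency_variant: AdjacencyVariant
    normalization: bool
    lam: float
    folds: list[FoldResult]

    def _acc(self) -> np.ndarray:
        return np.array([f.accuracy for f in self.folds])

    def _f1(self) -> np.ndarray:
        vals = np.array([f.f1 for f in self.folds])
        return vals[~np.isnan(vals)]

    @property
    def mean_accuracy(self) -> float:
        return float(self._acc().mean())

    @property
    def min_accuracy(self) -> float:
        return float(self._acc().min())

    @property
    def max_accuracy(self) -> float:
        return float(self._acc().max())

    @property
    def mean_f1(self) -> float:
        vals = self._f1()
        return float(vals.mean()) if vals.size else float("nan")

    @property
    def split_hashes(self) -> list[str]:
        return [f.split_hash for f in self.folds]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(f) for f in self.folds])
        df.insert(0, "task", self.task)
        df.insert(1, "mode", self.mode)
        df.insert(2, "adjacency", self.adjacency_variant)
        df.insert(3, "normalized", self.normalization)
        return df


def _split_hash(train_idx: np.ndarray, test_idx: np.ndarray) -> str:
    h = hashlib.sha1()
    h.update(np.asarray(train_idx, dtype=np.int64).tobytes())
    h.update(b"|")
    h.update(np.asarray(test_idx, dtype=np.int64).tobytes())
    return h.hexdigest()[:12]


@dataclass
class _SubjectData:
    features: feats.FeatureCube   # unnormalized
    labels: np.ndarray            # per-segment binary labels
    trial_ids: np.ndarray         # per-segment trial index
    raw_segments: np.ndarray      # (n_segments, channels, window) calibrated
    subject_id: str


def _prepare_subject(ts: TrialSet, cfg: ExperimentConfig, task: Task) -> _SubjectData:
    if ts.baseline_seconds > 0:
        ts = prep.calibrate_baseline(ts)
    segs = prep.segment(ts, cfg.window_seconds, cfg.stride_seconds)
    cube = feats.segment_features(segs, method=cfg.psd_method)
    labels = segs.segment_labels(axis=task, tie_rule=cfg.tie_rule)
    trial_ids = np.repeat(np.arange(segs.n_trials), segs.n_segments)
    return _SubjectData(
        features=cube,
        labels=labels,
        trial_ids=trial_ids,
        raw_segments=segs.flatten(),
        subject_id=ts.subject_id,
    )


def _build_graph(
    cfg: ExperimentConfig,
    montage: Montage,
    distance_graph: ChannelGraph,
    train_cube: feats.FeatureCube,
    train_raw: np.ndarray,
) -> ChannelGraph:
    """Adjacency for one fold; the connectivity part sees training data only."""
    if cfg.adjacency == "distance":
        return distance_graph
    if cfg.connectivity_source == "features":
        signals = train_cube.channel_vectors()
    else:
        n_seg, n_ch, n_w = train_raw.shape
        signals = np.transpose(train_raw, (1, 0, 2)).reshape(n_ch, -1)
    conn = connectivity_adjacency(
        signals, cfg.lam, channel_names=montage.names
    )
    if cfg.adjacency == "cc":
        return conn
    return fuse(distance_graph, conn)


def _run_fold(
    cfg: ExperimentConfig,
    montage: Montage,
    distance_graph: ChannelGraph,
    cube: feats.FeatureCube,
    raw: np.ndarray,
    labels: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    fold: int,
    subject: str,
    model_seed: int,
    instrument: Callable | None,
) -> FoldResult:
    train_vals = feats.FeatureCube(cube.values[train_idx], cube.band_specs)
    test_vals = feats.FeatureCube(cube.values[test_idx], cube.band_specs)
    if cfg.normalize:
        stats = feats.fit_normalizer(train_vals)
        train_vals = feats.apply_normalizer(train_vals, stats)
        test_vals = feats.apply_normalizer(test_vals, stats)
    else:
        stats = None
    graph = _build_graph(
        cfg, montage, distance_graph, train_vals, raw[train_idx]
    )
    model_cfg = replace(cfg.model, seed=model_seed)
    model = ChebGCN(graph, in_features=train_vals.values.shape[2], config=model_cfg)
    model.fit(train_vals.values, labels[train_idx])
    preds = model.predict(test_vals.values)
    counts = confusion_counts(labels[test_idx], preds)
    if instrument is not None:
        instrument(
            fold=fold, subject=subject, train_idx=train_idx, test_idx=test_idx,
            stats=stats, graph=graph, model=model,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f1_val = f1(counts)
    return FoldResult(
        subject=subject,
        fold=fold,
        accuracy=accuracy(counts),
        f1=f1_val,
        n_train=len(train_idx),
        n_test=len(test_idx),
        split_hash=_split_hash(train_idx, test_idx),
    )


def _derive_seed(base: int, *parts: int) -> int:
    x = int(base)
    for p in parts:
        x = (x * 6364136223846793005 + int(p) + 1) % 2**64
    return x % (2**31 - 1)


def run_experiment(
    trialsets: Sequence[TrialSet] | TrialSet,
    config: ExperimentConfig | None = None,
    mode: Mode = "subject-dependent",
    task: Task = "valence",
    *,
    montage: Montage | None = None,
    permute_labels: bool = False,
    instrument: Callable | None = None,
) -> EvalReport:
    """Cross-validated evaluation of the full pipeline.

    ``permute_labels`` randomly permutes the per-segment labels (seeded
    from the config) before splitting — the chance-level null for sanity
    checks.
    """
    cfg = config or ExperimentConfig()
    if isinstance(trialsets, TrialSet):
        trialsets = [trialsets]
    if montage is None:
        montage = deap32_montage()
    n_ch = trialsets[0].n_channels
    if n_ch != len(montage):
        montage = Montage(montage.names[:n_ch], montage.positions[:n_ch])
    delta = calibrate_delta(montage, cfg.delta_target, cfg.delta_cutoff)
    dist_graph = distance_adjacency(montage, delta)
    dist_graph = ChannelGraph(
        dist_graph.adjacency, "distance", channel_names=montage.names,
        delta=delta, scaling=cfg.laplacian_scaling,
    )

    subjects = [_prepare_subject(ts, cfg, task) for ts in trialsets]
    if permute_labels:
        perm_rng = np.random.default_rng(_derive_seed(cfg.seed, 0x9E37))
        for sd in subjects:
            sd.labels = perm_rng.permutation(sd.labels)

    folds: list[FoldResult] = []
    if mode == "subject-dependent":
        for si, sd in enumerate(subjects):
            groups = sd.trial_ids if cfg.split_granularity == "trial" else None
            splits = kfold_splits(
                len(sd.labels), cfg.k_folds,
                seed=_derive_seed(cfg.seed, si), groups=groups,
            )
            for fold, (tr, te) in enumerate(splits):
                folds.append(_run_fold(
                    cfg, montage, dist_graph, sd.features, sd.raw_segments,
                    sd.labels, tr, te, fold, sd.subject_id,
                    _derive_seed(cfg.seed, si, fold), instrument,
                ))
    elif mode in ("subject-independent", "loso"):
        cube = feats.FeatureCube(
            np.concatenate([sd.features.values for sd in subjects]),
            subjects[0].features.band_specs,
        )
        raw = np.concatenate([sd.raw_segments for sd in subjects])
        labels = np.concatenate([sd.labels for sd in subjects])
        subj_of = np.concatenate([
            np.full(len(sd.labels), si) for si, sd in enumerate(subjects)
        ])
        if mode == "subject-independent":
            groups = (
                np.concatenate([
                    sd.trial_ids + 10_000 * si
                    for si, sd in enumerate(subjects)
                ])
                if cfg.split_granularity == "trial" else None
            )
            splits = kfold_splits(
                len(labels), cfg.k_folds, seed=_derive_seed(cfg.seed, 0),
                groups=groups,
            )
        else:  # leave-one-subject-out (extension beyond the pooled design)
            splits = [
                (np.flatnonzero(subj_of != si), np.flatnonzero(subj_of == si))
                for si in range(len(subjects))
            ]
        for fold, (tr, te) in enumerate(splits):
            subject = (
                subjects[fold].subject_id if mode == "loso" else "pooled"
            )
            folds.append(_run_fold(
                cfg, montage, dist_graph, cube, raw, labels, tr, te,
                fold, subject, _derive_seed(cfg.seed, 0, fold), instrument,
            ))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    return EvalReport(
        task=task,
        mode=mode,
        adjacency_variant=cfg.adjacency,
        normalization=cfg.normalize,
        lam=cfg.lam,
        folds=folds,
    )


def run_ablation(
    trialsets: Sequence[TrialSet] | TrialSet,
    config: ExperimentConfig | None = None,
    variants: Sequence[dict] | None = None,
    mode: Mode = "subject-independent",
    task: Task = "valence",
    *,
    montage: Montage | None = None,
) -> tuple[list[EvalReport], pd.DataFrame]:
    """One EvalReport per adjacency/normalization variant on identical splits.

    Each variant is a dict overriding ``ExperimentConfig`` fields — e.g.
    ``{"adjacency": "cc", "lam": 0.5}`` or ``{"normalize": False}``. The
    shared config seed fixes the cross-validation splits, so differences
    between rows are attributable to the variant alone. Returns the reports
    plus a comparison table (mean/min/max accuracy and mean F1 per variant).
    """
    cfg = config or ExperimentConfig()
    if variants is None:
        variants = [
            {"adjacency": "distance"},
            {"adjacency": "cc", "lam": 0.5},
            {"adjacency": "cc", "lam": 0.98},
            {"adjacency": "fused", "lam": 0.5},
            {"adjacency": "fused", "lam": 0.98},
        ]
    reports = []
    rows = []
    for var in variants:
        vcfg = replace(cfg, **var)
        rep = run_experiment(
            trialsets, vcfg, mode=mode, task=task, montage=montage
        )
        reports.append(rep)
        label = rep.adjacency_variant
        if rep.adjacency_variant != "distance":
            label += f"@{rep.lam:g}"
        rows.append({
            "variant": label,
            "normalized": rep.normalization,
            "mean_accuracy": rep.mean_accuracy,
            "min_accuracy": rep.min_accuracy,
            "max_accuracy": rep.max_accuracy,
            "mean_f1": rep.mean_f1,
        })
    table = pd.DataFrame(rows)
    hashes = {tuple(r.split_hashes) for r in reports}
    if len(hashes) != 1:
        raise RuntimeError("ablation variants ran on differing splits")
    return reports, table
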