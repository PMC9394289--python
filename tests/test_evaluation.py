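"""Metrics, cross-validation splits, and the experiment/ablation runners."""

import numpy as np
import pytest
from sklearn.metrics import accuracy_score, f1_score

from crgcn import (
    ConfusionCounts,
    ExperimentConfig,
    ModelConfig,
    SynthConfig,
    accuracy,
    confusion_counts,
    f1,
    generate_trialset,
    kfold_splits,
    run_ablation,
    run_experiment,
)


class TestMetrics:
    def test_perfect_classification(self):
        c = ConfusionCounts(tp=5, fp=0, tn=5, fn=0)
        assert accuracy(c) == 1.0
        assert f1(c) == 1.0

    def test_positive_free_case_flagged(self):
        c = ConfusionCounts(tp=0, fp=0, tn=10, fn=0)
        assert accuracy(c) == 1.0
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(f1(c))

    def test_hand_computed_counts(self):
        c = ConfusionCounts(tp=3, fp=1, tn=4, fn=2)
        assert accuracy(c) == pytest.approx(0.7)
        assert f1(c) == pytest.approx(6 / 9)

    def test_matches_sklearn_on_random_vectors(self):
        """Independent confusion-matrix oracle on 100 random vectors."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(5, 60))
            yt = rng.integers(0, 2, n)
            yp = rng.integers(0, 2, n)
            if yt.sum() == 0 and yp.sum() == 0:
                continue
            c = confusion_counts(yt, yp)
            assert c.total == n
            assert accuracy(c) == accuracy_score(yt, yp)
            assert f1(c) == pytest.approx(f1_score(yt, yp, zero_division=0.0))

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            confusion_counts(np.array([]), np.array([]))


class TestKfoldSplits:
    def test_partition_arithmetic(self):
        splits = kfold_splits(100, k=5, seed=1)
        tests = [set(te) for _, te in splits]
        assert all(len(t) == 20 for t in tests)
        for i in range(5):
            for j in range(i + 1, 5):
                assert not tests[i] & tests[j]
        assert set().union(*tests) == set(range(100))
        for tr, te in splits:
            assert not set(tr) & set(te)
            assert len(tr) + len(te) == 100

    def test_seed_determinism(self):
        a = kfold_splits(50, seed=7)
        b = kfold_splits(50, seed=7)
        for (tra, tea), (trb, teb) in zip(a, b):
            assert np.array_equal(tra, trb) and np.array_equal(tea, teb)

    def test_group_splits_keep_trials_intact(self):
        groups = np.repeat(np.arange(10), 19)
        for tr, te in kfold_splits(190, k=5, seed=2, groups=groups):
            assert not set(groups[tr]) & set(groups[te])

    def test_k_larger_than_population_rejected(self):
        with pytest.raises(ValueError):
            kfold_splits(3, k=5)


def _tiny_subjects(n_subjects=2, n_trials=10, seed=100, **synth_kw):
    rng = np.random.default_rng(seed)
    out = []
    for si in range(n_subjects):
        labels = rng.permutation(np.arange(n_trials) % 2)
        cfg = SynthConfig(n_trials_per_subject=n_trials, seed=seed + si,
                          **synth_kw)
        out.append(generate_trialset(cfg, labels, subject_id=f"s{si}"))
    return out


_FAST_MODEL = ModelConfig(max_epochs=60, seed=0)


@pytest.fixture(scope="module")
def subjects():
    return _tiny_subjects()


class TestRunExperiment:

    @pytest.mark.parametrize("mode", ["subject-dependent", "subject-independent"])
    def test_recovers_planted_structure(self, subjects, mode):
        cfg = ExperimentConfig(model=_FAST_MODEL, seed=5)
        rep = run_experiment(subjects, cfg, mode=mode)
        assert rep.mean_accuracy >= 0.9
        assert rep.min_accuracy <= rep.mean_accuracy <= rep.max_accuracy
        assert 0 <= rep.mean_f1 <= 1

    def test_shuffled_labels_fall_to_chance(self, subjects):
        cfg = ExperimentConfig(model=_FAST_MODEL, seed=5)
        rep = run_experiment(subjects, cfg, mode="subject-independent",
                             permute_labels=True)
        assert 0.3 <= rep.mean_accuracy <= 0.7

    def test_subject_dependent_never_mixes_subjects(self, subjects):
        seen = []
        cfg = ExperimentConfig(model=ModelConfig(max_epochs=2, seed=0), seed=3)
        run_experiment(subjects, cfg, mode="subject-dependent",
                       instrument=lambda **kw: seen.append(kw))
        per_subject = 10 * 19
        for call in seen:
            assert len(call["train_idx"]) + len(call["test_idx"]) == per_subject
            assert not set(call["train_idx"]) & set(call["test_idx"])

    def test_loso_holds_out_whole_subjects(self, subjects):
        cfg = ExperimentConfig(model=ModelConfig(max_epochs=2, seed=0), seed=3)
        rep = run_experiment(subjects, cfg, mode="loso")
        assert [f.subject for f in rep.folds] == ["s0", "s1"]
        assert all(f.n_test == 10 * 19 for f in rep.folds)

    def test_train_only_statistics(self, subjects):
        """The normalizer and the connectivity matrix must be computable
        from the training split alone: recompute them outside and compare."""
        from crgcn import connectivity_adjacency, fit_normalizer
        from crgcn.evaluation import _prepare_subject

        cfg = ExperimentConfig(model=ModelConfig(max_epochs=2, seed=0), seed=9)
        captured = []
        run_experiment(subjects[0], cfg, mode="subject-dependent",
                       instrument=lambda **kw: captured.append(kw))
        sd = _prepare_subject(subjects[0], cfg, "valence")
        for call in captured:
            tr = call["train_idx"]
            stats = fit_normalizer(sd.features.values[tr])
            assert np.allclose(call["stats"].mean, stats.mean)
            assert np.allclose(call["stats"].std, stats.std)
            z = (sd.features.values[tr] - stats.mean) / stats.std
            signals = np.transpose(z, (1, 0, 2)).reshape(z.shape[1], -1)
            conn = connectivity_adjacency(signals, cfg.lam).adjacency
            np.fill_diagonal(conn, 0.0)
            fused = call["graph"].adjacency
            dist_part = fused - conn
            assert np.allclose(dist_part, dist_part.T)
            # off-diagonal fused entries decompose into distance + conn parts
            assert np.all(dist_part[~np.eye(32, dtype=bool)] >= -1e-12)


class TestRunAblation:
    def test_variants_share_identical_splits(self):
        subjects = _tiny_subjects(n_subjects=1, n_trials=6, seed=50)
        cfg = ExperimentConfig(model=ModelConfig(max_epochs=2, seed=0), seed=7)
        variants = [
            {"adjacency": "distance"},
            {"adjacency": "cc", "lam": 0.15},
            {"adjacency": "cc", "lam": 0.3},
            {"adjacency": "fused", "lam": 0.15},
            {"adjacency": "fused", "lam": 0.3},
        ]
        reports, table = run_ablation(subjects, cfg, variants=variants)
        assert len(reports) == 5
        hashes = {tuple(r.split_hashes) for r in reports}
        assert len(hashes) == 1
        assert set(table.columns) >= {"variant", "normalized", "mean_accuracy"}
        assert len(table) == 5

    def test_variant_overrides_applied(self):
        subjects = _tiny_subjects(n_subjects=1, n_trials=6, seed=51)
        cfg = ExperimentConfig(model=ModelConfig(max_epochs=2, seed=0), seed=8)
        reports, _ = run_ablation(
            subjects, cfg,
            variants=[{"adjacency": "distance", "normalize": False},
                      {"adjacency": "fused", "lam": 0.5}],
        )
        assert reports[0].adjacency_variant == "distance"
        assert reports[0].normalization is False
        assert reports[1].lam == 0.5
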