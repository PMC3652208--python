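"""Metric arithmetic, cluster-class matching, baselines, full pipeline."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgmmc.evaluate import (class_metrics, confusion, kmeans_baseline,
                             load_reference_beat_counts,
                             load_reference_confusion,
                             load_reference_performance, match_clusters,
                             metrics_report, micro_sensitivity, run_pipeline)
from ecgmmc.synthetic import gen_cluster_data


class TestMatchClusters:
    def test_identity_when_aligned(self):
        labels = np.array(["a", "b", "a", "c", "b"])
        assert match_clusters(labels, labels) == \
            {"a": "a", "b": "b", "c": "c"}

    def test_two_cluster_sign_flip(self):
        true = np.array([-1, -1, 1, 1])
        pred = -true
        mapping = match_clusters(pred, true)
        matched = np.array([mapping[p] for p in pred])
        assert np.array_equal(matched, true)

    def test_agreement_equals_best_permutation(self):
        rng = np.random.default_rng(0)
        true = rng.integers(0, 5, size=60)
        pred = rng.integers(0, 5, size=60)
        mapping = match_clusters(pred, true)
        got = int(np.sum(np.array([mapping[p] for p in pred]) == true))
        best = max(
            sum(np.sum((pred == c) & (true == perm[i]))
                for i, c in enumerate(range(5)))
            for perm in permutations(range(5)))
        assert got == best

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(1)
        true = rng.integers(0, 3, size=40)
        pred = rng.integers(0, 3, size=40)
        m1 = match_clusters(pred, true)
        a1 = np.sum(np.array([m1[p] for p in pred]) == true)
        shuffled = (pred + 7) * 3               # arbitrary relabeling
        m2 = match_clusters(shuffled, true)
        a2 = np.sum(np.array([m2[p] for p in shuffled]) == true)
        assert a1 == a2

    def test_rectangular_fallback(self):
        true = np.array(["x", "x", "y", "y", "y", "y"])
        pred = np.array([0, 0, 1, 1, 2, 2])
        mapping = match_clusters(pred, true)
        assert set(mapping) == {0, 1, 2}
        assert set(mapping.values()) <= {"x", "y"}


class TestConfusion:
    def test_perfect_prediction_is_diagonal(self):
        labels = np.array(["N", "V", "N", "V", "N"])
        cm = confusion(labels, labels)
        assert cm.to_numpy().sum() == 5
        assert np.all(cm.to_numpy() == np.diag(np.diag(cm.to_numpy())))

    def test_total_preserved(self):
        rng = np.random.default_rng(2)
        true = rng.choice(list("NSVFQ"), 100)
        pred = rng.choice(list("NSVFQ"), 100)
        cm = confusion(true, pred, class_names=list("NSVFQ"))
        assert cm.to_numpy().sum() == 100
        for c in "NSVFQ":
            assert cm.loc[c].sum() == int(np.sum(true == c))

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.array(["N"]), np.array(["Z"]), class_names=["N"])


class TestReferenceFixtures:
    def test_confusion_row_sums(self):
        cm = load_reference_confusion()
        assert cm.sum(axis=1).tolist() == [859, 218, 199, 195, 211]
        assert int(cm.to_numpy().sum()) == 1682

    def test_beat_count_totals(self):
        counts = load_reference_beat_counts()
        assert int(counts.to_numpy().sum()) == 1682
        assert counts.sum(axis=1).tolist() == [187, 237, 181, 208, 219,
                                               416, 234]

    def test_pooled_sensitivity_matches_reported_total(self):
        cm = load_reference_confusion()
        assert round(micro_sensitivity(cm), 1) == 90.3

    def test_performance_table_shape(self):
        perf = load_reference_performance()
        assert list(perf.index) == ["N", "S", "F", "V", "Q", "Total"]
        assert perf.loc["Total", "sensitivity"] == 90.3


class TestMetrics:
    def test_hand_worked_counts(self):
        cm = pd.DataFrame([[8, 1], [2, 9]], index=["pos", "neg"],
                          columns=["pos", "neg"])
        # TP=8 FN=2(?) -- careful: rows are true, columns predicted
        m = class_metrics(cm, "pos")
        assert (m["TP"], m["FN"], m["FP"], m["TN"]) == (8, 1, 2, 9)
        cm2 = pd.DataFrame([[8, 2], [1, 9]], index=["pos", "neg"],
                           columns=["pos", "neg"])
        m = class_metrics(cm2, "pos")
        assert (m["TP"], m["FN"], m["FP"], m["TN"]) == (8, 2, 1, 9)
        assert m["sensitivity"] == pytest.approx(80.0)
        assert m["specificity"] == pytest.approx(90.0)
        assert m["accuracy"] == pytest.approx(85.0)

    def test_perfect_matrix_all_hundred(self):
        cm = pd.DataFrame(np.diag([5, 7, 9]), index=list("abc"),
                          columns=list("abc"))
        for c in "abc":
            m = class_metrics(cm, c)
            assert m["sensitivity"] == 100.0
            assert m["specificity"] == 100.0
            assert m["accuracy"] == 100.0
        assert micro_sensitivity(cm) == 100.0

    def test_empty_class_undefined_not_nan(self):
        cm = pd.DataFrame([[0, 0], [1, 5]], index=["a", "b"],
                          columns=["a", "b"])
        assert class_metrics(cm, "a") is None

    def test_micro_sensitivity_random_matrix(self):
        rng = np.random.default_rng(3)
        vals = rng.integers(0, 30, size=(5, 5))
        vals[0, 0] += 1
        cm = pd.DataFrame(vals, index=list("NSVFQ"), columns=list("NSVFQ"))
        assert micro_sensitivity(cm) == pytest.approx(
            100 * vals.trace() / vals.sum())

    @given(st.lists(st.integers(0, 50), min_size=9, max_size=9))
    @settings(max_examples=50, deadline=None)
    def test_count_identities_any_matrix(self, cells):
        vals = np.array(cells).reshape(3, 3)
        cm = pd.DataFrame(vals, index=list("abc"), columns=list("abc"))
        n = vals.sum()
        for c in "abc":
            m = class_metrics(cm, c)
            if m is None:
                continue
            assert m["TP"] + m["FN"] + m["FP"] + m["TN"] == n
            for key in ("sensitivity", "accuracy"):
                assert 0.0 <= m[key] <= 100.0
            if m["specificity"] is not None:
                assert 0.0 <= m["specificity"] <= 100.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            micro_sensitivity(pd.DataFrame())


class TestKMeansBaseline:
    def test_n_equals_k_zero_inertia(self):
        X = np.arange(10, dtype=float).reshape(5, 2)
        labels = kmeans_baseline(X, k=5, seed=0)
        assert len(set(labels.tolist())) == 5

    def test_separable_blobs_partitioned(self):
        X, y = gen_cluster_data(n=80, k=2, separation=6, dims=2, seed=5)
        labels = kmeans_baseline(X, 2, seed=1)
        agree = max(np.mean((labels * 2 - 1) == y),
                    np.mean((1 - labels * 2) == y))
        assert agree == 1.0

    def test_seeded_determinism(self):
        X, _ = gen_cluster_data(n=40, k=3, dims=3, seed=6)
        assert np.array_equal(kmeans_baseline(X, 3, seed=2),
                              kmeans_baseline(X, 3, seed=2))


class TestPipeline:
    CONFIG = {
        "seed": 0,
        "synthetic": {"fs": 360, "duration": 40, "heart_rate": 70,
                      "beat_classes": ["N", "N", "V"], "rr_jitter": 0.03,
                      "seed": 42},
        "noise": {"bw_amp": 0.3, "bw_freq": 0.3, "emg_sd": 0.05, "seed": 7},
        "cluster": {"k": 2, "max_generations": 25, "stall": 6},
    }

    def test_end_to_end_report_contract(self, tmp_path):
        report = run_pipeline(dict(self.CONFIG), out_dir=tmp_path)
        assert "pooled_sensitivity" in report
        metrics = report["metrics"]
        assert set(metrics) == {"sensitivity", "specificity", "accuracy"}
        assert (tmp_path / "labels.csv").exists()
        assert (tmp_path / "metrics.json").exists()
        labels = pd.read_csv(tmp_path / "labels.csv")
        assert set(labels.columns) == {"beat_id", "cluster"}

    def test_deterministic(self, tmp_path):
        r1 = run_pipeline(dict(self.CONFIG), out_dir=tmp_path / "a")
        r2 = run_pipeline(dict(self.CONFIG), out_dir=tmp_path / "b")
        assert r1["pooled_sensitivity"] == r2["pooled_sensitivity"]
        a = (tmp_path / "a" / "labels.csv").read_text()
        b = (tmp_path / "b" / "labels.csv").read_text()
        assert a == b

    def test_stage_failure_names_stage(self):
        bad = dict(self.CONFIG)
        bad["filter"] = {"mu": 50.0}       # diverges
        with pytest.raises(RuntimeError, match="filter"):
            run_pipeline(bad)

    def test_two_class_record_pooled_sensitivity(self):
        """Noisy N-vs-V record, ~120 beats end to end: pooled sensitivity
        of the unsupervised clustering reaches 90%."""
        config = {
            "seed": 0,
            "synthetic": {"fs": 360, "duration": 98, "heart_rate": 70,
                          "beat_classes": ["N", "N", "V"],
                          "rr_jitter": 0.03, "seed": 1},
            "noise": {"bw_amp": 0.3, "bw_freq": 0.3, "emg_sd": 0.05,
                      "seed": 2},
            "cluster": {"k": 2},
        }
        report = run_pipeline(config)
        assert report["pooled_sensitivity"] >= 90.0
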