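"""Feature assembly and the leave-one-out linear-SVM protocol."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from sklearn.preprocessing import StandardScaler

from conftest import random_events, two_condition_clips
from facs_affect.classify import (
    FeatureMatrix,
    build_features,
    fit_linear_svm,
    loo_evaluate,
    select_c,
)
from facs_affect.events_io import AnnotationEvent, ClipRecord
from facs_affect.metrics import summarize


def summary_from(rows):
    return pd.DataFrame(rows, columns=["video_id", "code", "frequency", "max_duration"])


class TestBuildFeatures:
    def clips(self):
        return [
            ClipRecord("i1", "h1", "PRI", "transportation"),
            ClipRecord("c1", "h1", "PRI", "baseline"),
        ]

    def test_frequency_and_duration_blocks(self):
        s = summary_from([("i1", "AD38", 2, 1.5), ("c1", "AD38", 0, 0.0)])
        fm = build_features(s, self.clips(), codes=["AD38"], mode="both")
        assert fm.feature_names == ["AD38_freq", "AD38_maxdur"]
        assert fm.X.tolist() == [[2.0, 1.5], [0.0, 0.0]]
        assert fm.y.tolist() == [1, 0]

    def test_absent_code_contributes_zeros(self):
        s = summary_from([("i1", "AU145", 3, 0.2)])
        fm = build_features(s, self.clips(), codes=["AD38"], mode="both")
        assert fm.X.tolist() == [[0.0, 0.0], [0.0, 0.0]]

    def test_empty_code_set_rejected(self):
        s = summary_from([("i1", "AD38", 1, 0.5)])
        with pytest.raises(ValueError, match="empty"):
            build_features(s, self.clips(), codes=[])

    def test_matches_naive_assembly_oracle(self, rng):
        clips = two_condition_clips(4)
        events = []
        for c in clips:
            events += random_events(rng, 12, video=c.video_id)
        summary = summarize(events, clips)
        fm = build_features(summary, clips, mode="both")
        codes = sorted(summary["code"].unique())
        lookup = {
            (r.video_id, r.code): (r.frequency, r.max_duration)
            for r in summary.itertuples()
        }
        for row, clip in zip(fm.X, clips):
            expected = [lookup.get((clip.video_id, c), (0, 0))[0] for c in codes]
            expected += [lookup.get((clip.video_id, c), (0, 0))[1] for c in codes]
            assert row.tolist() == pytest.approx(expected)


def svm_dual_oracle(X, y, C):
    """Weighted soft-margin linear-SVM dual solved with SLSQP (oracle)."""
    n = len(y)
    sign = np.where(y == 1, 1.0, -1.0)
    counts = np.bincount(y)
    box = C * n / (2.0 * counts[y])  # 'balanced' class weights
    K = (sign[:, None] * sign[None, :]) * (X @ X.T)

    def neg_obj(a):
        return -(a.sum() - 0.5 * a @ K @ a)

    res = minimize(
        neg_obj,
        x0=np.full(n, 1e-3),
        bounds=[(0, b) for b in box],
        constraints=[{"type": "eq", "fun": lambda a: a @ sign}],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-12},
    )
    a = res.x
    w = (a * sign) @ X
    margin = (a > 1e-6) & (a < box - 1e-6)
    b = np.mean(sign[margin] - X[margin] @ w)
    return w, b


class TestSVMAgainstDualOracle:
    def test_weight_vector_matches_qp_solution(self):
        X = np.array(
            [[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [3.0, 3.0], [4.0, 3.0], [3.0, 4.0]]
        )
        y = np.array([0, 0, 0, 1, 1, 1])
        for C in (0.1, 1.0, 10.0):
            clf = fit_linear_svm(X, y, C)
            w_hat, b_hat = clf.coef_.ravel(), clf.intercept_[0]
            w, b = svm_dual_oracle(X, y, C)
            assert np.allclose(w_hat, w, atol=1e-3)
            assert b_hat == pytest.approx(b, abs=1e-3)

    def test_unbalanced_class_weights_match(self):
        X = np.array([[0.0], [0.5], [1.0], [3.0], [4.0], [3.5], [5.0], [4.5]])
        y = np.array([0, 0, 0, 1, 1, 1, 1, 1])
        clf = fit_linear_svm(X, y, 1.0)
        w, b = svm_dual_oracle(X, y, 1.0)
        assert np.allclose(clf.coef_.ravel(), w, atol=1e-3)
        assert clf.intercept_[0] == pytest.approx(b, abs=1e-3)


class TestLOO:
    def separable_matrix(self, n_per_class=5):
        X = np.vstack(
            [
                np.column_stack([np.arange(n_per_class), np.zeros(n_per_class)]),
                np.column_stack([10 + np.arange(n_per_class), np.ones(n_per_class)]),
            ]
        )
        y = np.array([0] * n_per_class + [1] * n_per_class)
        ids = [f"c{k}" for k in range(2 * n_per_class)]
        return FeatureMatrix(X, y, ["f0", "f1"], ids)

    def test_separable_clusters_classified_perfectly(self):
        report = loo_evaluate(self.separable_matrix(), seed=3)
        assert report.accuracy == 100.0
        assert report.precision == 100.0 and report.recall == 100.0

    def test_metrics_invariant_to_row_permutation(self, rng):
        fm = self.separable_matrix()
        X = fm.X + rng.normal(0, 3, fm.X.shape)  # overlap so errors occur
        perm = rng.permutation(len(fm.y))
        a = loo_evaluate(FeatureMatrix(X, fm.y, fm.feature_names, fm.clip_ids), seed=1)
        b = loo_evaluate(
            FeatureMatrix(X[perm], fm.y[perm], fm.feature_names,
                          [fm.clip_ids[i] for i in perm]),
            seed=1,
        )
        assert a.accuracy == b.accuracy
        assert a.precision == b.precision and a.recall == b.recall

    def test_constant_feature_dropped_with_warning(self):
        fm = self.separable_matrix()
        X = np.column_stack([fm.X, np.full(len(fm.y), 7.0)])
        with pytest.warns(UserWarning, match="constant"):
            report = loo_evaluate(
                FeatureMatrix(X, fm.y, fm.feature_names + ["const"], fm.clip_ids),
                seed=0,
            )
        assert report.accuracy == 100.0

    def test_too_few_clips_per_class_rejected(self):
        fm = FeatureMatrix(
            np.array([[0.0], [1.0], [2.0]]), np.array([0, 0, 1]), ["f"], list("abc")
        )
        with pytest.raises(ValueError, match="per class"):
            loo_evaluate(fm)

    def test_predictions_match_documented_protocol(self, rng):
        """Independent re-implementation of the LOO protocol (standardize on
        the training fold, pick C by stratified CV with ties to the smaller
        C, balanced linear SVM) reproduces every prediction."""
        n = 12
        X = rng.normal(0, 1, (n, 3))
        y = np.array([0, 1] * (n // 2))
        X[y == 1] += 0.8
        fm = FeatureMatrix(X, y, ["a", "b", "c"], [f"v{k}" for k in range(n)])
        report = loo_evaluate(fm, seed=11)
        for i in range(n):
            tr = np.arange(n) != i
            c = select_c(X[tr], y[tr], seed=11)
            scaler = StandardScaler().fit(X[tr])
            clf = fit_linear_svm(scaler.transform(X[tr]), y[tr], c)
            pred = clf.predict(scaler.transform(X[i : i + 1]))[0]
            assert pred == report.predictions[i]

    def test_global_c_bypasses_tuning(self):
        fm = self.separable_matrix()
        report = loo_evaluate(fm, global_c=1.0)
        assert set(report.c_values) == {1.0}
        assert report.accuracy == 100.0
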