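"""Feature-matrix construction, classifiers, CV precision-recall, ablation."""

import numpy as np
import pandas as pd
import pytest

from methylhet import predict
from methylhet.simulate import SimulationConfig, simulate_feature_table


def raw_inputs(rng, n=400):
    ids = [f"cgi_{i}" for i in range(n)]
    cgi = pd.DataFrame({
        "cgi_id": ids,
        "cpg_density": rng.uniform(0.02, 0.12, n),
        "normalized_cpg_density": rng.uniform(0.5, 1.0, n),
        "gc_fraction": rng.uniform(0.45, 0.75, n),
    })
    tracks = pd.DataFrame({
        "cgi_id": ids,
        "h3k4me3": rng.gamma(2.0, 2.0, n),
        "h3k27me3": rng.gamma(2.0, 1.0, n),
        "h3k36me3": rng.gamma(2.0, 0.5, n),
        "dnase": rng.gamma(2.0, 2.0, n),
    })
    meth = pd.DataFrame({
        "cgi_id": ids,
        "control_methylation": rng.uniform(0.0, 0.4, n),
        "label": rng.integers(0, 2, n),
    })
    return cgi, tracks, meth


class TestBuildFeatureMatrix:
    def test_log_pseudocount_of_zero_rpkm(self, rng):
        cgi, tracks, meth = raw_inputs(rng)
        tracks.loc[0, "h3k4me3"] = 0.0
        meth["control_methylation"] = 0.0
        df = cgi.merge(tracks, on="cgi_id").merge(meth, on="cgi_id")
        # before z-scoring, log(0 + 0.001) = -6.9078 (natural log)
        assert np.log(0.0 + predict.LOG_PSEUDOCOUNT) == pytest.approx(
            -6.9078, abs=1e-4)
        out = predict.build_feature_matrix(cgi, tracks, meth)
        assert out["h3k4me3"].min() == out.loc[
            out["cgi_id"] == "cgi_0", "h3k4me3"].iloc[0]

    def test_track_columns_are_zscored(self, rng):
        cgi, tracks, meth = raw_inputs(rng)
        out = predict.build_feature_matrix(cgi, tracks, meth)
        for col in predict.TRACK_COLUMNS:
            assert abs(out[col].mean()) < 1e-9
            assert out[col].std(ddof=0) == pytest.approx(1.0)

    def test_constant_track_becomes_zero(self, rng):
        cgi, tracks, meth = raw_inputs(rng)
        tracks["h3k36me3"] = 3.0
        out = predict.build_feature_matrix(cgi, tracks, meth)
        assert (out["h3k36me3"] == 0.0).all()

    def test_high_methylation_cgis_removed(self, rng):
        cgi, tracks, meth = raw_inputs(rng)
        out = predict.build_feature_matrix(cgi, tracks, meth)
        assert (out["control_methylation"] < 0.2).all()
        high = meth.loc[meth["control_methylation"] >= 0.25, "cgi_id"]
        assert not out["cgi_id"].isin(high).any()

    def test_99th_percentile_outliers_removed(self, rng):
        cgi, tracks, meth = raw_inputs(rng, n=1000)
        meth["control_methylation"] = 0.0
        out = predict.build_feature_matrix(cgi, tracks, meth)
        top = tracks.nlargest(10, "dnase")["cgi_id"]
        assert not out["cgi_id"].isin(top).any()

    def test_missing_track_rows_counted(self, rng):
        cgi, tracks, meth = raw_inputs(rng)
        out = predict.build_feature_matrix(cgi, tracks.iloc[5:], meth)
        assert out.attrs["n_missing_track"] == 5


class TestTrainClassifier:
    def test_separable_data_perfect_training_recall(self, rng):
        X = np.vstack([rng.normal(-3, 0.3, (100, 3)),
                       rng.normal(3, 0.3, (30, 3))])
        y = np.r_[np.zeros(100, int), np.ones(30, int)]
        model = predict.train_classifier(X, y, seed=0)
        scores = model.predict_proba(X)[:, 1]
        curve = predict._summarize(scores, y)
        assert curve.recall_at_fdr5 == 1.0

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(200, 4))
        y = (rng.random(200) < 0.3).astype(int)
        s = []
        for _ in range(2):
            model = predict.train_classifier(X, y, seed=3)
            s.append(model.predict_proba(X)[:, 1])
        assert np.array_equal(s[0], s[1])

    @pytest.mark.parametrize("method", predict.METHODS)
    def test_all_methods_fit_and_score(self, rng, method):
        X = rng.normal(size=(120, 4))
        y = (X[:, 0] + rng.normal(0, 0.5, 120) > 0).astype(int)
        model = predict.train_classifier(X, y, method=method, seed=1)
        p = model.predict_proba(X)[:, 1]
        assert p.shape == (120,) and np.all((p >= 0) & (p <= 1))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            predict.train_classifier(np.zeros((10, 2)), np.zeros(10, int))


def brute_force_pr(scores, labels):
    """Oracle: precision/recall at every score threshold by direct count."""
    pts = []
    for t in np.unique(scores):
        called = scores >= t
        tp = (called & (labels == 1)).sum()
        if called.sum() == 0:
            continue
        pts.append((tp / called.sum(), tp / (labels == 1).sum()))
    return pts


class TestCrossValidatedPr:
    def test_perfect_scores_give_full_recall(self):
        y = np.r_[np.ones(20, int), np.zeros(80, int)]
        curve = predict._summarize(y.astype(float), y)
        assert curve.recall_at_fdr5 == 1.0
        assert curve.auc_pr == pytest.approx(1.0)

    def test_random_scores_baseline_precision(self, rng):
        y = (rng.random(20_000) < 0.1).astype(int)
        scores = rng.random(20_000)
        curve = predict._summarize(scores, y)
        assert curve.auc_pr == pytest.approx(0.1, abs=0.02)
        assert curve.recall_at_fdr5 == 0.0

    def test_matches_brute_force_threshold_sweep(self, rng):
        y = (rng.random(300) < 0.3).astype(int)
        scores = np.round(rng.random(300), 2)
        curve = predict._summarize(scores, y)
        lib = set(zip(np.round(curve.precision[:-1], 10),
                      np.round(curve.recall[:-1], 10)))
        for p, r in brute_force_pr(scores, y):
            assert (round(p, 10), round(r, 10)) in lib

    def test_duplicating_rows_preserves_curve(self):
        cfg = SimulationConfig(seed=40)
        t = simulate_feature_table(cfg, 400)
        X = t[list(predict.FEATURE_COLUMNS)].to_numpy()
        y = t["label"].to_numpy()
        c1 = predict._summarize(X[:, 0], y)
        c2 = predict._summarize(np.r_[X[:, 0], X[:, 0]], np.r_[y, y])
        assert c1.auc_pr == pytest.approx(c2.auc_pr)
        assert c1.recall_at_fdr5 == pytest.approx(c2.recall_at_fdr5)

    def test_small_class_raises_with_name(self):
        X = np.zeros((20, 2))
        y = np.r_[np.ones(3, int), np.zeros(17, int)]
        with pytest.raises(ValueError, match="class 1"):
            predict.cross_validated_pr(X, y, k=5)

    def test_out_of_fold_evaluation_beats_chance_on_signal(self):
        cfg = SimulationConfig(seed=41)
        t = simulate_feature_table(cfg, 1200)
        curve = predict.cross_validated_pr(
            t[list(predict.FEATURE_COLUMNS)], t["label"].to_numpy(),
            seed=2)
        assert curve.auc_pr > 2 * t["label"].mean()


class TestFeatureAblation:
    def test_single_driver_feature_dominates_ablation(self):
        hits = 0
        for seed in range(5):
            cfg = SimulationConfig(seed=100 + seed)
            t = simulate_feature_table(cfg, 1500,
                                       label_weights={"h3k4me3": 3.0},
                                       intercept=-2.0)
            _, table = predict.feature_ablation(t, seed=seed)
            if table.iloc[0]["feature"] == "h3k4me3":
                hits += 1
        assert hits >= 4

    def test_noise_feature_ablation_is_negligible(self):
        deltas = []
        for seed in range(5):
            cfg = SimulationConfig(seed=200 + seed)
            t = simulate_feature_table(cfg, 1500)
            _, table = predict.feature_ablation(t, seed=seed)
            # h3k36me3 carries no label weight and only weak correlation
            deltas.append(float(table.set_index("feature")
                                .loc["h3k36me3", "delta_auc_pr"]))
        assert abs(np.mean(deltas)) < 0.02

    def test_common_folds_across_ablations(self):
        # fold assignment depends only on (y, k, seed); hash must agree
        y = (np.arange(100) % 3 == 0).astype(int)
        f1 = predict.make_folds(y, k=5, seed=9)
        f2 = predict.make_folds(y, k=5, seed=9)
        for (tr1, te1), (tr2, te2) in zip(f1, f2):
            assert np.array_equal(te1, te2)

    def test_needs_two_features(self):
        t = simulate_feature_table(SimulationConfig(seed=1), 200)
        with pytest.raises(ValueError):
            predict.feature_ablation(t, feature_columns=["h3k4me3"])
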