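"""Canonical discriminant analysis: fitting, scoring, Wilks, LOOCV, ROC."""

import numpy as np
import pandas as pd
import pytest

from burnhsi.cda import (SampleTable, canonical_scores, centroid_margin_scores,
                         classify, classify_features, expand_predictors, fit_cda,
                         loocv, one_vs_rest_roc, wilks_lambda, TIME_POINTS_S)


def make_table(features, labels, subjects=None):
    n = len(labels)
    return SampleTable(pd.DataFrame({
        "subject": subjects or [f"s{i}" for i in range(n)],
        "class": labels,
        "t_s": features[:, 0], "chbt": features[:, 1],
        "sto2": features[:, 2], "stmet": features[:, 3],
    }))


@pytest.fixture(scope="module")
def cluster_table():
    """Three well-separated clusters (inter-centroid distance >> within-SD)."""
    rng = np.random.default_rng(42)
    centers = {1: [300, 15, 60, 5], 2: [86400, 6, 40, 20], 3: [259200, 3, 30, 45]}
    rows, labels = [], []
    for c, mu in centers.items():
        pts = rng.normal(mu, [50, 0.3, 0.8, 0.8], size=(12, 4))
        rows.append(pts)
        labels += [c] * 12
    return make_table(np.vstack(rows), labels)


@pytest.fixture(scope="module")
def cluster_model(cluster_table):
    pm = expand_predictors(cluster_table)
    return fit_cda(pm, cluster_table.labels)


class TestExpandPredictors:
    def test_all_ones_row_expands_to_ones(self):
        from burnhsi.cda import _expand_raw
        raw, names = _expand_raw(np.ones((1, 4)))
        assert raw.shape == (1, 14)
        assert np.all(raw == 1.0)
        assert len(names) == 14

    def test_84_row_table_gives_84_by_14(self, scenario):
        from burnhsi.synthetic import generate_sample_table
        table, _ = generate_sample_table(scenario, seed=1)
        pm = expand_predictors(table)
        assert pm.data.shape == (84, 14)
        assert np.allclose(pm.data.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(pm.data.std(axis=0), 1.0, atol=1e-12)

    def test_stored_standardization_is_idempotent(self, cluster_table):
        pm = expand_predictors(cluster_table)
        again = pm.transform(cluster_table.features)
        assert np.array_equal(again, pm.data)

    def test_zero_variance_column_dropped_with_warning(self):
        rng = np.random.default_rng(0)
        feats = rng.normal(10, 2, (12, 4))
        feats[:, 0] = 300.0            # constant T: t_s, t_s^2 and products with T degenerate
        table = make_table(feats, [1] * 6 + [2] * 6)
        with pytest.warns(UserWarning, match="zero-variance"):
            pm = expand_predictors(table)
        assert "t_s" in pm.dropped and "t_s^2" in pm.dropped
        assert pm.data.shape[1] == 14 - len(pm.dropped)

    def test_squares_only_gives_8_columns(self, cluster_table):
        pm = expand_predictors(cluster_table, squares_only=True)
        assert pm.data.shape[1] == 8


class TestFitCDA:
    def test_two_separated_clouds_single_axis(self):
        rng = np.random.default_rng(1)
        feats = np.column_stack([
            np.r_[rng.normal(300, 10, 20), rng.normal(5000, 10, 20)],
            rng.normal(10, 1, 40), rng.normal(50, 1, 40), rng.normal(5, 1, 40)])
        table = make_table(feats, [1] * 20 + [2] * 20)
        pm = expand_predictors(table)
        model = fit_cda(pm, table.labels)
        assert model.axes.shape[1] == 1
        c1, c2 = model.centroids[1][0], model.centroids[2][0]
        assert np.sign(c1) != np.sign(c2)

    def test_three_class_model_has_two_axes_sorted(self, cluster_model):
        assert cluster_model.axes.shape[1] == 2
        assert cluster_model.eigenvalues[0] >= cluster_model.eigenvalues[1] >= 0

    def test_leading_axis_beats_1000_random_directions(self, cluster_table):
        """Rayleigh-quotient oracle: no random unit direction exceeds the
        leading canonical eigenvalue's between/within ratio."""
        pm = expand_predictors(cluster_table)
        model = fit_cda(pm, cluster_table.labels)
        from burnhsi.cda import _scatter_matrices
        w, b, _, _ = _scatter_matrices(pm.data, cluster_table.labels)
        rng = np.random.default_rng(9)
        best = 0.0
        for _ in range(1000):
            v = rng.normal(size=pm.data.shape[1])
            best = max(best, (v @ b @ v) / (v @ w @ v))
        assert model.eigenvalues[0] >= best - 1e-9

    def test_duplicating_samples_leaves_axes_unchanged(self, cluster_table):
        pm1 = expand_predictors(cluster_table)
        m1 = fit_cda(pm1, cluster_table.labels)
        doubled = SampleTable(pd.concat([cluster_table.frame] * 2, ignore_index=True))
        pm2 = expand_predictors(doubled)
        m2 = fit_cda(pm2, doubled.labels)
        # doubling data doubles both scatter matrices: directions and
        # eigenvalues unchanged; the axis norm rescales by
        # sqrt((2n - g) / (2 (n - g))) through the unit-within-variance scaling
        assert np.allclose(m2.eigenvalues, m1.eigenvalues, rtol=1e-9)
        scale = np.sqrt((m2.n_samples - 3) / (2 * (m1.n_samples - 3)))
        assert np.allclose(m2.axes, m1.axes * scale, rtol=1e-8)

    def test_eigenvalue_equals_score_variance_ratio(self, cluster_model, cluster_table):
        """lambda_1 equals the between/within scatter ratio of axis-1 scores."""
        pm = cluster_model.predictor
        scores = canonical_scores(cluster_model, pm.data)[:, 0]
        labels = cluster_table.labels
        grand = scores.mean()
        within = sum(((scores[labels == c] - scores[labels == c].mean()) ** 2).sum()
                     for c in (1, 2, 3))
        between = sum((labels == c).sum() * (scores[labels == c].mean() - grand) ** 2
                      for c in (1, 2, 3))
        assert cluster_model.eigenvalues[0] == pytest.approx(between / within, rel=1e-9)


class TestScores:
    def test_class_mean_maps_to_centroid(self, cluster_model, cluster_table):
        pm = cluster_model.predictor
        feats = cluster_table.features[cluster_table.labels == 2]
        z = pm.transform(feats).mean(axis=0)
        assert np.allclose(canonical_scores(cluster_model, z),
                           cluster_model.centroids[2], atol=1e-10)

    def test_grand_mean_maps_to_origin(self, cluster_model, cluster_table):
        z = cluster_model.predictor.transform(cluster_table.features).mean(axis=0)
        assert np.allclose(canonical_scores(cluster_model, z), 0.0, atol=1e-10)

    def test_projection_is_affine(self, cluster_model):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, (2, cluster_model.n_features))
        mid = canonical_scores(cluster_model, (a + b) / 2)
        assert np.allclose(mid, (canonical_scores(cluster_model, a)
                                 + canonical_scores(cluster_model, b)) / 2)

    def test_dimension_mismatch_raises(self, cluster_model):
        with pytest.raises(ValueError, match="predictor columns"):
            canonical_scores(cluster_model, np.zeros(3))


class TestWilksLambda:
    def test_single_eigenvalue_closed_form(self, cluster_model):
        import dataclasses
        m = dataclasses.replace(cluster_model, eigenvalues=np.array([3.0]))
        assert wilks_lambda(m)["lambda"] == pytest.approx(0.25)

    def test_zero_eigenvalues_mean_no_separation(self, cluster_model):
        import dataclasses
        m = dataclasses.replace(cluster_model, eigenvalues=np.zeros(2))
        out = wilks_lambda(m)
        assert out["lambda"] == 1.0 and out["chi2"] == pytest.approx(0.0)

    def test_matches_determinant_ratio_oracle(self):
        """Lambda = det(W) / det(W + B) computed independently."""
        rng = np.random.default_rng(5)
        feats = rng.normal(0, 1, (60, 4)) + np.repeat(rng.normal(0, 2, (3, 4)), 20, axis=0)
        feats[:, 0] = np.abs(feats[:, 0]) * 1000
        table = make_table(feats, [1] * 20 + [2] * 20 + [3] * 20)
        pm = expand_predictors(table)
        model = fit_cda(pm, table.labels)
        lam = wilks_lambda(model)["lambda"]
        from burnhsi.cda import _scatter_matrices
        w, b, _, _ = _scatter_matrices(pm.data, table.labels)
        oracle = np.linalg.det(w) / np.linalg.det(w + b)
        assert lam == pytest.approx(oracle, abs=1e-8)


class TestClassify:
    def test_centroid_row_classified_as_its_class(self, cluster_model):
        for c in (1, 2, 3):
            z = cluster_model.centroids[c]
            # invert the projection is unnecessary: classify in score space via
            # a row whose scores equal the centroid
            row = np.linalg.lstsq(cluster_model.axes.T, z, rcond=None)[0]
            assert classify(cluster_model, row)[()] == c

    def test_equidistant_tie_breaks_to_lowest_code(self, cluster_model):
        import dataclasses
        m = dataclasses.replace(cluster_model,
                                centroids={1: np.array([-1.0, 0.0]),
                                           2: np.array([1.0, 0.0]),
                                           3: np.array([50.0, 0.0])})
        row = np.zeros(m.n_features)   # scores (0, 0): equidistant from 1 and 2
        assert classify(m, row)[()] == 1

    def test_training_accuracy_100_on_separable_clusters(self, cluster_model, cluster_table):
        pred = classify_features(cluster_model, cluster_table.features)
        assert np.array_equal(pred, cluster_table.labels)

    def test_classification_invariant_to_affine_feature_rescaling(self, cluster_table):
        pm = expand_predictors(cluster_table)
        model = fit_cda(pm, cluster_table.labels)
        base = classify_features(model, cluster_table.features)
        scaled = cluster_table.frame.copy()
        for col, (a, b) in {"t_s": (2.0, 100.0), "chbt": (0.5, 3.0),
                            "sto2": (10.0, -20.0), "stmet": (0.1, 1.0)}.items():
            scaled[col] = a * scaled[col] + b
        t2 = SampleTable(scaled)
        pm2 = expand_predictors(t2)
        m2 = fit_cda(pm2, t2.labels)
        assert np.array_equal(classify_features(m2, t2.features), base)


class TestLOOCV:
    def test_perfect_clusters_give_100_percent(self, cluster_table):
        out = loocv(cluster_table)
        assert out["overall_pct"] == 100.0
        assert all(v == 100.0 for v in out["per_class_pct"].values())
        assert not out["failed_folds"]

    def test_loocv_not_above_training_accuracy(self, cluster_table, cluster_model):
        train = np.mean(classify_features(cluster_model, cluster_table.features)
                        == cluster_table.labels) * 100
        assert loocv(cluster_table)["overall_pct"] <= train

    def test_group_by_subject_variant(self, scenario):
        """Leaving out whole subjects (4 rows each) is at most as optimistic
        as leaving out single observations on the same table."""
        from burnhsi.synthetic import generate_sample_table
        table, _ = generate_sample_table(scenario, seed=13)
        by_obs = loocv(table)
        by_subj = loocv(table, group_by_subject=True)
        assert by_subj["confusion"].sum() == by_obs["confusion"].sum() == 84
        assert by_subj["overall_pct"] <= by_obs["overall_pct"] + 15.0

    def test_deterministic_across_runs(self, cluster_table):
        a = loocv(cluster_table)
        b = loocv(cluster_table)
        assert np.array_equal(a["confusion"], b["confusion"])

    def test_permutation_null_near_chance_for_3_classes(self, scenario):
        """Random labels on 3 balanced classes: LOOCV accuracy ~ 33.3%."""
        from burnhsi.synthetic import generate_sample_table
        table, _ = generate_sample_table(scenario, seed=11)
        rng = np.random.default_rng(0)
        accs = []
        for _ in range(40):
            shuffled = table.frame.copy()
            shuffled["class"] = rng.permutation(shuffled["class"].to_numpy())
            accs.append(loocv(SampleTable(shuffled))["overall_pct"])
        mean = np.mean(accs)
        se = np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert mean == pytest.approx(100 / 3, abs=max(4 * se, 2.5))


class TestROC:
    def test_perfectly_separated_scores_auc_1(self, cluster_model, cluster_table):
        roc = one_vs_rest_roc(cluster_model, cluster_table, positive_class=3)
        assert roc.auc == pytest.approx(1.0)
        assert roc.fpr[0] == 0.0 and roc.tpr[-1] == 1.0
        assert np.all(np.diff(roc.fpr) >= 0) and np.all(np.diff(roc.tpr) >= 0)

    def test_identical_scores_auc_half(self, cluster_model, cluster_table):
        import dataclasses
        # centroids coincide: every sample gets the same margin score
        m = dataclasses.replace(cluster_model,
                                centroids={c: np.zeros(2) for c in (1, 2, 3)})
        roc = one_vs_rest_roc(m, cluster_table, positive_class=1)
        assert roc.auc == pytest.approx(0.5)

    def test_auc_equals_mann_whitney_oracle(self, cluster_model, cluster_table):
        """Trapezoid AUC = U / (n+ n-) with tie correction, to 1e-10."""
        rng = np.random.default_rng(3)
        noisy = cluster_table.frame.copy()
        for col in ("chbt", "sto2", "stmet"):
            noisy[col] = np.abs(noisy[col] + rng.normal(0, 15, len(noisy)))
        table = SampleTable(noisy)
        pm = expand_predictors(table)
        model = fit_cda(pm, table.labels)
        for pos in (1, 2, 3):
            roc = one_vs_rest_roc(model, table, positive_class=pos)
            s = centroid_margin_scores(model, pm.transform(table.features), pos)
            y = table.labels == pos
            from scipy.stats import rankdata
            ranks = rankdata(s)        # midranks handle ties
            n_pos, n_neg = y.sum(), (~y).sum()
            u = ranks[y].sum() - n_pos * (n_pos + 1) / 2
            assert roc.auc == pytest.approx(u / (n_pos * n_neg), abs=1e-10)

    def test_auc_matches_scikit_learn(self, cluster_model, cluster_table):
        """Independent cross-check of the hand-rolled ROC against sklearn."""
        from sklearn.metrics import roc_auc_score
        pm = cluster_model.predictor
        rng = np.random.default_rng(6)
        noisy = cluster_table.frame.copy()
        for col in ("chbt", "sto2", "stmet"):
            noisy[col] = np.abs(noisy[col] + rng.normal(0, 10, len(noisy)))
        table = SampleTable(noisy)
        pm2 = expand_predictors(table)
        model = fit_cda(pm2, table.labels)
        for pos in (1, 2, 3):
            roc = one_vs_rest_roc(model, table, positive_class=pos)
            s = centroid_margin_scores(model, pm2.transform(table.features), pos)
            ref = roc_auc_score(table.labels == pos, s)
            assert roc.auc == pytest.approx(ref, abs=1e-12)

    def test_nearest_centroid_agrees_with_scikit_lda(self, cluster_table):
        """On separable clusters the canonical nearest-centroid rule matches
        scikit-learn's LDA predictions (uniform priors)."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        pm = expand_predictors(cluster_table)
        model = fit_cda(pm, cluster_table.labels)
        mine = classify(model, pm.data)
        lda = LinearDiscriminantAnalysis(priors=[1 / 3] * 3).fit(pm.data, cluster_table.labels)
        assert np.array_equal(mine, lda.predict(pm.data))

    def test_single_class_rejected(self, cluster_model, cluster_table):
        sub = SampleTable(cluster_table.frame[cluster_table.frame["class"] == 1]
                          .reset_index(drop=True))
        with pytest.raises(ValueError):
            one_vs_rest_roc(cluster_model, sub, positive_class=1)


def test_time_points_match_protocol():
    assert TIME_POINTS_S == (300.0, 86400.0, 172800.0, 259200.0)
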