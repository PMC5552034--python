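"""z-scoring, overall-score regression, and comment selection."""

import itertools

import numpy as np
import pandas as pd
import pytest

import sstcoach as sc
from sstcoach.config import ASD5_FEATURES, SCORE_FEATURES


class TestZscores:
    def test_user_at_cohort_mean_is_zero(self, cohort):
        user = {f: cohort.mean(f) for f in cohort.features}
        z = sc.zscores(user, cohort)
        assert all(v == pytest.approx(0.0) for v in z.values())

    def test_one_sd_above_mean_is_one(self, cohort):
        f = "words_per_minute"
        user = {f: cohort.mean(f) + cohort.sd(f)}
        z = sc.zscores(user, cohort, features=[f])
        assert z[f] == pytest.approx(1.0)

    def test_zero_sd_errors_naming_feature(self):
        coh = sc.ModelCohort(pd.DataFrame({"amplitude": [1.0, 1.0, 1.0]}))
        with pytest.raises(ValueError, match="amplitude"):
            sc.zscores({"amplitude": 2.0}, coh)

    def test_missing_user_feature_errors(self, cohort):
        with pytest.raises(KeyError):
            sc.zscores({}, cohort, features=["amplitude"])

    def test_cohort_self_zscores_standardized(self, cohort):
        zs = [sc.zscores(row._asdict() if hasattr(row, "_asdict") else dict(row), cohort)
              for _, row in cohort.table.iterrows()]
        mat = pd.DataFrame(zs)
        assert np.allclose(mat.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(mat.std(axis=0, ddof=1), 1.0, atol=1e-12)


class TestPredictScore:
    def test_zero_coefficients_return_intercept(self):
        sm = sc.ScoreModel(intercept=50.0, coef={f: 0.0 for f in SCORE_FEATURES})
        user = {f: 999.0 for f in SCORE_FEATURES}
        assert sc.predict_overall_score(user, sm) == 50.0

    @pytest.mark.parametrize("intercept,expect", [(137.2, 100.0), (-4.0, 0.0)])
    def test_clipping(self, intercept, expect):
        sm = sc.ScoreModel(intercept=intercept, coef={})
        assert sc.predict_overall_score({}, sm) == expect

    def test_missing_required_feature_errors(self):
        sm = sc.ScoreModel(intercept=0.0, coef={"amplitude": 1.0})
        with pytest.raises(KeyError):
            sc.predict_overall_score({"smiling_ratio": 0.5}, sm)

    def test_monotone_in_positive_coefficient(self):
        sm = sc.ScoreModel(intercept=40.0, coef={"smiling_ratio": 20.0})
        scores = [sc.predict_overall_score({"smiling_ratio": v}, sm)
                  for v in np.linspace(0, 1, 11)]
        assert all(b >= a for a, b in zip(scores, scores[1:]))


def normal_equations(X, y):
    """Independent OLS oracle: explicit normal-equations solve."""
    A = np.column_stack([np.ones(len(X)), X])
    return np.linalg.solve(A.T @ A, A.T @ y)


class TestFitScoreModel:
    def test_linear_in_one_feature_recovers_slope(self, rng):
        # ratings depend only on words_per_minute; other columns vary freely
        n = 20
        rows = pd.DataFrame({f: rng.normal(10, 3, n) for f in SCORE_FEATURES})
        y = 5.0 + 2.5 * rows["words_per_minute"].to_numpy()
        sm = sc.fit_score_model(rows, y)
        assert sm.coef["words_per_minute"] == pytest.approx(2.5, abs=1e-8)
        for f in SCORE_FEATURES:
            if f != "words_per_minute":
                assert sm.coef[f] == pytest.approx(0.0, abs=1e-8)
        assert sm.loo_r == pytest.approx(1.0, abs=1e-9)

    def test_constant_ratings_give_zero_coefficients(self, rng):
        rows = pd.DataFrame({f: rng.normal(0, 1, 15) for f in SCORE_FEATURES})
        sm = sc.fit_score_model(rows, np.full(15, 42.0))
        assert all(abs(c) < 1e-8 for c in sm.coef.values())
        assert sm.intercept == pytest.approx(42.0, abs=1e-8)

    def test_noisy_recovery_matches_normal_equations_oracle(self, rng):
        n = 30
        rows = pd.DataFrame({f: rng.normal(0, 2, n) for f in SCORE_FEATURES})
        truth = np.array([1.5, -0.7, 0.3, 2.0])
        y = 10.0 + rows.to_numpy()[:, :4] @ truth + rng.normal(0, 1.0, n)
        sm = sc.fit_score_model(rows, y)
        beta = normal_equations(rows[list(SCORE_FEATURES)].to_numpy(), y)
        assert sm.intercept == pytest.approx(beta[0], abs=1e-8)
        got = np.array([sm.coef[f] for f in SCORE_FEATURES])
        assert np.allclose(got, beta[1:], atol=1e-8)
        # coefficients within 3 standard errors of the generating weights
        A = np.column_stack([np.ones(n), rows.to_numpy()])
        resid = y - A @ beta
        sigma2 = resid @ resid / (n - 5)
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(A.T @ A)))[1:]
        assert np.all(np.abs(got - truth) <= 3 * se)

    def test_fitted_values_match_oracle(self, rng):
        rows = pd.DataFrame({f: rng.normal(0, 1, 25) for f in SCORE_FEATURES})
        y = rng.normal(50, 10, 25)
        sm = sc.fit_score_model(rows, y)
        beta = normal_equations(rows[list(SCORE_FEATURES)].to_numpy(), y)
        for i in range(len(rows)):
            pred = sm.intercept + sum(sm.coef[f] * rows[f].iloc[i] for f in SCORE_FEATURES)
            oracle = beta[0] + rows.iloc[i][list(SCORE_FEATURES)].to_numpy() @ beta[1:]
            assert pred == pytest.approx(oracle, abs=1e-8)

    def test_standardized_fit_predicts_identically(self, rng):
        rows = pd.DataFrame({f: rng.normal(5, 2, 20) for f in SCORE_FEATURES})
        y = rng.normal(50, 10, 20)
        sm_raw = sc.fit_score_model(rows, y, standardize=False)
        sm_std = sc.fit_score_model(rows, y, standardize=True)
        user = {f: float(rows[f].iloc[3]) for f in SCORE_FEATURES}
        assert sc.predict_overall_score(user, sm_raw) == pytest.approx(
            sc.predict_overall_score(user, sm_std), abs=1e-8
        )
        assert sm_std.standardized and not sm_raw.standardized

    def test_rating_rescale_to_0_100(self, rng):
        rows = pd.DataFrame({f: rng.normal(0, 1, 8) for f in SCORE_FEATURES})
        sm = sc.fit_score_model(rows, [1, 7, 4, 4, 2, 6, 3, 5], rating_scale=(1, 7))
        preds = [sc.predict_overall_score(dict(r), sm) for _, r in rows.iterrows()]
        assert min(preds) >= 0.0 and max(preds) <= 100.0

    def test_rank_deficient_design_errors(self):
        rows = pd.DataFrame({f: [1.0, 1.0, 1.0] for f in SCORE_FEATURES})
        rows["words_per_minute"] = [1.0, 2.0, 3.0]
        with pytest.raises(ValueError, match="rank"):
            sc.fit_score_model(rows, [1.0, 2.0, 3.0])

    def test_json_roundtrip(self, tmp_path, rng):
        rows = pd.DataFrame({f: rng.normal(0, 1, 10) for f in SCORE_FEATURES})
        sm = sc.fit_score_model(rows, rng.normal(50, 5, 10))
        p = tmp_path / "sm.json"
        sm.to_json(p)
        back = sc.ScoreModel.from_json(p)
        assert back.coef == sm.coef and back.intercept == sm.intercept
        assert back.loo_r == pytest.approx(sm.loo_r)


def brute_force_selection(z, order):
    """Oracle: full sort by (|z|, canonical position)."""
    rank = {f: i for i, f in enumerate(order)}
    ranked = sorted(z, key=lambda f: (abs(z[f]), rank[f]))
    med = (len(ranked) - 1) // 2
    return ranked[0], ranked[med if med > 0 else 1]


class TestSelectComments:
    def test_three_feature_rule(self):
        z = {"A": 0.1, "B": 0.5, "C": 2.0}
        assert sc.select_comments(z, ["A", "B", "C"]) == ("A", "B")

    def test_odd_count_median(self):
        names = list("ABCDE")
        z = dict(zip(names, [0.2, 0.4, 0.6, 0.8, 1.0]))
        assert sc.select_comments(z, names) == ("A", "C")

    def test_even_count_lower_middle(self):
        names = list("ABCD")
        z = dict(zip(names, [0.1, 0.3, 0.7, 0.9]))
        assert sc.select_comments(z, names) == ("A", "B")

    def test_magnitude_not_sign(self):
        z = {"A": -0.1, "B": 0.5, "C": -2.0}
        assert sc.select_comments(z, ["A", "B", "C"]) == ("A", "B")

    def test_single_feature_errors(self):
        with pytest.raises(ValueError):
            sc.select_comments({"A": 0.1})

    def test_invariant_to_input_ordering(self):
        names = list("ABCDE")
        z = dict(zip(names, [0.9, 0.2, 0.5, 0.4, 0.7]))
        expected = sc.select_comments(z, names)
        for perm in itertools.permutations(names):
            permuted = {f: z[f] for f in perm}
            assert sc.select_comments(permuted, names) == expected

    def test_matches_bruteforce_on_exhaustive_small_cases(self):
        values = [0.15, 0.4, 0.85, 1.3, 2.2]
        for k in (3, 4, 5):
            names = [f"f{i}" for i in range(k)]
            for perm in itertools.permutations(values[:k]):
                z = dict(zip(names, perm))
                assert sc.select_comments(z, names) == brute_force_selection(z, names)

    def test_distance_ties_break_by_canonical_order(self):
        z = {"B": 0.5, "A": 0.5, "C": 0.5}
        pos, imp = sc.select_comments(z, ["A", "B", "C"])
        assert (pos, imp) == ("A", "B")


class TestBuildReport:
    def test_identity_composition(self, cohort):
        user = {f: cohort.mean(f) for f in cohort.features}
        sm = sc.ScoreModel(intercept=50.0, coef={f: 0.0 for f in SCORE_FEATURES})
        rep = sc.build_report(user, cohort, sm)
        assert rep.overall_score == 50.0
        assert np.allclose(rep.radar_user, 0.0)
        assert np.allclose(rep.radar_model, 0.0)
        # ties at |z| = 0 resolve along the preset order
        assert rep.positive_feature == ASD5_FEATURES[0]
        assert rep.improve_feature == ASD5_FEATURES[2]

    def test_asd5_preset_has_five_radar_axes(self, cohort):
        user = {f: cohort.mean(f) + 0.1 * cohort.sd(f) for f in cohort.features}
        sm = sc.ScoreModel(intercept=60.0, coef={f: 0.0 for f in SCORE_FEATURES})
        rep = sc.build_report(user, cohort, sm, features=ASD5_FEATURES)
        assert len(rep.radar_features) == 5
        assert rep.radar_features == ASD5_FEATURES

    def test_positive_never_equals_improve(self, cohort, rng):
        sm = sc.ScoreModel(intercept=55.0, coef={f: 0.0 for f in SCORE_FEATURES})
        for _ in range(25):
            user = {f: cohort.mean(f) + rng.normal(0, 2) * cohort.sd(f)
                    for f in cohort.features}
            rep = sc.build_report(user, cohort, sm)
            assert rep.positive_feature != rep.improve_feature
            assert 0.0 <= rep.overall_score <= 100.0

    def test_comment_direction_follows_z_sign(self, cohort):
        from sstcoach.config import COMMENT_TEMPLATES_EN

        user = {f: cohort.mean(f) for f in cohort.features}
        # push one median-rank feature far high so it becomes the improvement
        user["amplitude"] = cohort.mean("amplitude") + 0.5 * cohort.sd("amplitude")
        user["words_per_minute"] = cohort.mean("words_per_minute") + 2 * cohort.sd("words_per_minute")
        sm = sc.ScoreModel(intercept=50.0, coef={})
        rep = sc.build_report(user, cohort, sm)
        assert rep.improve_comment == COMMENT_TEMPLATES_EN[rep.improve_feature]["high"]

    def test_report_json_roundtrip(self, cohort, tmp_path):
        import json

        user = {f: cohort.mean(f) + 0.3 * cohort.sd(f) for f in cohort.features}
        sm = sc.ScoreModel(intercept=70.0, coef={})
        rep = sc.build_report(user, cohort, sm)
        p = tmp_path / "rep.json"
        rep.to_json(p)
        d = json.loads(p.read_text())
        assert d["overall_score"] == rep.overall_score
        assert d["radar"]["features"] == list(rep.radar_features)
        assert d["positive"]["feature"] == rep.positive_feature

    def test_radar_plot_written(self, cohort, tmp_path):
        from sstcoach.feedback import plot_radar

        user = {f: cohort.mean(f) for f in cohort.features}
        sm = sc.ScoreModel(intercept=50.0, coef={})
        rep = sc.build_report(user, cohort, sm)
        p = tmp_path / "radar.png"
        plot_radar(rep, p)
        assert p.stat().st_size > 0
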