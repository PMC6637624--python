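"""Case assembly, classifiers, Youden/DeLong, morphometric modes."""

import numpy as np
import pandas as pd
import pytest

from bivatlas.risk import (
    assemble_cases,
    delong_test,
    fit_elasticnet_cv,
    fit_morphometric_modes,
    morphometric_zscore,
    youden_cutoff,
)


def _cohort(n=40, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(n)],
            "high_cholesterol": rng.integers(0, 2, n),
            "previous_mi": rng.integers(0, 2, n),
            "angina": rng.integers(0, 2, n),
        }
    )
    df["reference"] = (
        (df[["high_cholesterol", "previous_mi", "angina"]].sum(axis=1) == 0)
    ).astype(int)
    return df


class TestAssembleCases:
    def test_previous_mi_removes_nobody(self):
        df = _cohort()
        out = assemble_cases(df, "previous_mi")
        assert (out["label"] == 1).sum() == int(df["previous_mi"].sum())

    def test_angina_removes_only_mi_positives(self):
        df = _cohort()
        out = assemble_cases(df, "angina")
        expected = int(((df["angina"] == 1) & (df["previous_mi"] == 0)).sum())
        assert (out["label"] == 1).sum() == expected

    def test_other_factors_remove_mi_and_angina(self):
        df = _cohort()
        out = assemble_cases(df, "high_cholesterol")
        expected = int(
            (
                (df["high_cholesterol"] == 1)
                & (df["previous_mi"] == 0)
                & (df["angina"] == 0)
            ).sum()
        )
        assert (out["label"] == 1).sum() == expected

    def test_reference_group_never_positive(self):
        df = _cohort()
        out = assemble_cases(df, "high_cholesterol")
        pos = out[out["label"] == 1]
        assert (pos["reference"] == 0).all()

    def test_unknown_factor(self):
        with pytest.raises(KeyError, match="smoking"):
            assemble_cases(_cohort(), "smoking")

    def test_empty_class_errors(self):
        df = _cohort()
        df["rare"] = 0
        df["reference"] = 1
        with pytest.raises(ValueError, match="empty class"):
            assemble_cases(df, "rare")


class TestYouden:
    def test_fully_separated_j_is_one(self):
        y = np.r_[np.zeros(30), np.ones(30)]
        s = np.r_[np.linspace(0, 0.4, 30), np.linspace(0.6, 1.0, 30)]
        cut = youden_cutoff(y, s)
        assert 0.4 < cut <= 0.6
        sens = np.mean(s[y == 1] >= cut)
        spec = np.mean(s[y == 0] < cut)
        assert sens + spec - 1 == pytest.approx(1.0)

    def test_identical_distributions_j_zero(self):
        rng = np.random.default_rng(0)
        s = np.tile(rng.normal(0, 1, 200), 2)
        y = np.r_[np.zeros(200), np.ones(200)]
        cut = youden_cutoff(y, s)
        j = np.mean(s[y == 1] >= cut) + np.mean(s[y == 0] < cut) - 1
        assert abs(j) < 1e-9

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(7)
        for trial in range(10):
            y = rng.integers(0, 2, 60)
            if len(np.unique(y)) < 2:
                continue
            s = rng.normal(y, 1.2)
            cut = youden_cutoff(y, s)
            j_impl = np.mean(s[y == 1] >= cut) + np.mean(s[y == 0] < cut) - 1
            j_best = max(
                np.mean(s[y == 1] >= c) + np.mean(s[y == 0] < c) - 1
                for c in np.unique(s)
            )
            assert j_impl == pytest.approx(j_best, abs=1e-12)


class TestDeLong:
    def test_model_vs_itself(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 100)
        s = rng.normal(y, 1.0)
        diff, p = delong_test(s, s, y)
        assert diff == 0.0
        assert p == 1.0

    def test_auc_equals_mann_whitney_u(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 80)
        s = rng.normal(y * 0.8, 1.0)
        from bivatlas.risk import _placements

        _, _, auc = _placements(s[y == 1], s[y == 0])
        pos, neg = s[y == 1], s[y == 0]
        u = sum(
            1.0 if a > b else (0.5 if a == b else 0.0) for a in pos for b in neg
        )
        assert auc == pytest.approx(u / (len(pos) * len(neg)), abs=1e-12)

    def test_strong_vs_noise_model_significant(self):
        rng = np.random.default_rng(3)
        n = 400
        y = rng.integers(0, 2, n)
        strong = y * 1.5 + rng.normal(0, 1, n)
        noise = rng.normal(0, 1, n)
        diff, p = delong_test(strong, noise, y)
        assert diff > 0.15
        assert p < 0.005

    def test_single_class_error(self):
        with pytest.raises(ValueError, match="both classes"):
            delong_test(np.ones(5), np.ones(5), np.ones(5))


class TestElasticNetCV:
    def test_separable_case_perfect(self):
        rng = np.random.default_rng(4)
        n = 100
        y = np.r_[np.zeros(n // 2), np.ones(n // 2)].astype(int)
        X = np.c_[y * 10.0 + rng.normal(0, 0.1, n), rng.normal(0, 1, (n, 3))]
        res = fit_elasticnet_cv(X, y, n_folds=5, seed=0)
        assert res.auc == pytest.approx(1.0, abs=1e-6)
        assert res.sensitivity == pytest.approx(1.0)
        assert res.specificity == pytest.approx(1.0)

    def test_permuted_labels_auc_near_half(self):
        rng = np.random.default_rng(5)
        n = 600
        X = rng.normal(0, 1, (n, 10))
        y = rng.permutation(np.r_[np.zeros(n // 2), np.ones(n // 2)]).astype(int)
        res = fit_elasticnet_cv(X, y, seed=1)
        assert 0.42 <= res.auc <= 0.58

    def test_pure_noise_sparsity(self):
        rng = np.random.default_rng(6)
        n, p = 300, 30
        X = rng.normal(0, 1, (n, p))
        y = rng.integers(0, 2, n)
        res = fit_elasticnet_cv(X, y, n_folds=5, seed=2)
        assert np.median(res.n_nonzero_coef) <= p / 5

    def test_metrics_recomputable_from_fold_predictions(self):
        rng = np.random.default_rng(8)
        n = 200
        y = rng.integers(0, 2, n)
        X = np.c_[y + rng.normal(0, 1, n), rng.normal(0, 1, (n, 2))]
        res = fit_elasticnet_cv(X, y, n_folds=5, seed=3)
        from sklearn.metrics import roc_auc_score

        aucs = [roc_auc_score(t, s) for t, s in res.fold_predictions]
        np.testing.assert_allclose(aucs, res.fold_aucs)

    def test_fold_seed_stability(self):
        rng = np.random.default_rng(9)
        n = 300
        y = rng.integers(0, 2, n)
        X = np.c_[y * 1.2 + rng.normal(0, 1, n), rng.normal(0, 1, (n, 4))]
        aucs = [fit_elasticnet_cv(X, y, n_folds=5, seed=s).auc for s in range(5)]
        assert max(aucs) - min(aucs) < 0.03

    def test_small_minority_reduces_folds_with_warning(self):
        rng = np.random.default_rng(10)
        y = np.r_[np.ones(4), np.zeros(60)].astype(int)
        X = np.c_[y + rng.normal(0, 0.5, 64)]
        with pytest.warns(UserWarning, match="folds"):
            fit_elasticnet_cv(X, y, n_folds=10, seed=0)


def _score_cohort(n=500, seed=0, delta=None, M=8, age_effect=None,
                  factor_age_coupling=0.0):
    """Synthetic score-space cohort with one factor shifting scores."""
    rng = np.random.default_rng(seed)
    age = rng.normal(62, 7.5, n)
    sex = (rng.random(n) < 0.5).astype(float)
    height = rng.normal(170, 9, n)
    p = 1.0 / (1.0 + np.exp(-(-1.0 + factor_age_coupling * (age - 62) / 7.5)))
    factor = (rng.random(n) < p).astype(int)
    S = rng.normal(0, 1, (n, M))
    if age_effect is not None:
        S += np.outer((age - 62) / 7.5, age_effect)
    if delta is not None:
        S += np.outer(factor, delta)
    df = pd.DataFrame(S, columns=[f"score_{j}" for j in range(M)])
    df["age_yr"], df["sex"], df["height_cm"] = age, sex, height
    df["factor"] = factor
    df["reference"] = (factor == 0).astype(int)
    return df


class TestMorphometricModes:
    def test_planted_direction_recovered(self):
        rng = np.random.default_rng(11)
        delta = rng.normal(0, 1, 8)
        delta *= 3.0 / np.linalg.norm(delta)
        df = _score_cohort(n=500, seed=12, delta=delta)
        modes = fit_morphometric_modes(df, ["factor"])
        cos = abs(
            float(modes[0].unit_direction @ (delta / np.linalg.norm(delta)))
        )
        assert cos > 0.99

    def test_null_factor_coefficients_within_noise(self):
        df = _score_cohort(n=500, seed=13, delta=None)
        modes = fit_morphometric_modes(df, ["factor"])
        m = modes[0]
        # every coefficient within 3 standard errors, most within 2
        assert np.all(np.abs(m.direction) < 3 * m.coef_se)
        assert np.mean(np.abs(m.direction) < 2 * m.coef_se) >= 0.75

    def test_confounded_factor_shrinks_after_adjustment(self):
        # the factor is age-correlated but has no direct shape effect;
        # adjusting for age must shrink the mode direction relative to the
        # raw two-group mean difference
        rng = np.random.default_rng(14)
        age_effect = rng.normal(0, 1, 8)
        age_effect *= 2.0 / np.linalg.norm(age_effect)
        df = _score_cohort(
            n=800, seed=15, delta=None, age_effect=age_effect,
            factor_age_coupling=2.0,
        )
        modes = fit_morphometric_modes(df, ["factor"])
        S = df[[c for c in df.columns if c.startswith("score_")]].to_numpy()
        raw = S[df["factor"] == 1].mean(axis=0) - S[df["factor"] == 0].mean(axis=0)
        assert np.linalg.norm(modes[0].direction) < 0.5 * np.linalg.norm(raw)

    def test_rank_deficiency_names_columns(self):
        df = _score_cohort(n=100, seed=16)
        df["factor_copy"] = df["factor"]
        with pytest.raises(ValueError, match="factor"):
            fit_morphometric_modes(df, ["factor", "factor_copy"])


class TestZScores:
    def test_reference_group_standardized(self):
        df = _score_cohort(n=400, seed=17, delta=np.ones(8))
        modes = fit_morphometric_modes(df, ["factor"])
        S = df[[c for c in df.columns if c.startswith("score_")]].to_numpy()
        z_ref = morphometric_zscore(S[df["reference"] == 1], modes[0])
        assert float(np.mean(z_ref)) == pytest.approx(0.0, abs=1e-9)
        assert float(np.std(z_ref)) == pytest.approx(1.0, abs=1e-9)

    def test_subject_at_reference_mean_is_zero(self):
        df = _score_cohort(n=300, seed=18, delta=np.ones(8))
        modes = fit_morphometric_modes(df, ["factor"])
        m = modes[0]
        S = df[[c for c in df.columns if c.startswith("score_")]].to_numpy()
        ref_mean_scores = S[df["reference"] == 1].mean(axis=0)
        assert morphometric_zscore(ref_mean_scores, m) == pytest.approx(0.0, abs=1e-9)

    def test_planted_one_sd_effect(self):
        # positives displaced by exactly one reference-SD along a direction
        rng = np.random.default_rng(19)
        u = rng.normal(0, 1, 8)
        u /= np.linalg.norm(u)
        df = _score_cohort(n=300, seed=20, delta=None)
        S = df[[c for c in df.columns if c.startswith("score_")]].to_numpy()
        ref_sd = float((S[df["reference"] == 1] @ u).std(ddof=0))
        df.loc[df["factor"] == 1, [f"score_{j}" for j in range(8)]] += ref_sd * u
        modes = fit_morphometric_modes(df, ["factor"])
        S = df[[c for c in df.columns if c.startswith("score_")]].to_numpy()
        z_pos = morphometric_zscore(S[df["factor"] == 1], modes[0])
        assert 0.8 <= float(np.mean(z_pos)) <= 1.2

    def test_zero_reference_sd_errors(self):
        df = _score_cohort(n=100, seed=21, delta=np.ones(8))
        for c in [c for c in df.columns if c.startswith("score_")]:
            df.loc[df["reference"] == 1, c] = 0.0
        with pytest.raises(ValueError, match="zero reference SD|zero morphometric"):
            fit_morphometric_modes(df, ["factor"])
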