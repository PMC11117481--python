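"""Subject-level statistics: normalization, LOSO, tests, matching.

Each statistical routine is checked against an independent brute-force
oracle (exhaustive pair counting for U and AUC, rank-then-Pearson for
Spearman, exhaustive pairings for matching).
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pdwear.cohort import (empirical_cdf, loso_logistic, mann_whitney_cohen_d,
                           match_subgroups, normalize_features, spearman,
                           summarize_subject)
from pdwear.pipeline import DayResult


def _day(subject="s", dys_spans=(), fog_eps=(), n_dys=0, walking=600.0,
         duration=3600.0, gait_minutes=None):
    return DayResult(subject_id=subject, day=0, duration_s=duration,
                     dys_spans=list(dys_spans), dys_windows=pd.DataFrame(),
                     n_dys_periods=n_dys, fog_episodes=list(fog_eps),
                     fog_minutes=pd.DataFrame(), gait_minutes=gait_minutes,
                     walking_time_s=walking, n_bouts=0, n_strides=0)


class TestSummaries:
    def test_empty_outputs_all_zero(self):
        s = summarize_subject("s", [_day()])
        assert s.n_dys_periods == 0 and s.time_with_dys_s == 0.0
        assert s.n_fog_episodes == 0 and s.pct_time_fog == 0.0

    def test_days_are_additive(self):
        d1 = _day(fog_eps=[(0, 10)] * 3, n_dys=1)
        d2 = _day(fog_eps=[(0, 10)] * 4, n_dys=2)
        s = summarize_subject("s", [d1, d2])
        assert s.n_fog_episodes == 7
        assert s.n_dys_periods == 3
        assert s.monitoring_days == 2

    def test_pct_fog_uses_walking_time(self):
        s = summarize_subject("s", [_day(fog_eps=[(0.0, 30.0)], walking=600.0)])
        assert s.pct_time_fog == pytest.approx(100 * 30 / 600)

    def test_gait_means_over_retained_minutes_only(self):
        gm = pd.DataFrame({
            "minute_index": [0, 1], "n_steps": [6, 12],
            "cadence_mean": [100.0, 110.0],
            "step_length_mean": [0.9, 0.5], "step_length_var": [0.0, 0.0],
            "stride_speed_mean": [1.0, 1.0], "stride_speed_var": [0.0, 0.0],
            "fluidity_mean": [0.1, 0.2], "fluidity_var": [0.0, 0.0],
            "retained": [False, True],
        })
        s = summarize_subject("s", [_day(gait_minutes=gm)])
        assert s.gait_means["step_length"] == pytest.approx(0.5)


class TestNormalization:
    def test_minmax_endpoints(self):
        df = pd.DataFrame({"a": [2.0, 4.0, 6.0]})
        out, bounds = normalize_features(df)
        np.testing.assert_allclose(out["a"], [0.0, 0.5, 1.0])
        assert bounds.loc["a", "fmin"] == 2.0 and bounds.loc["a", "fmax"] == 6.0

    def test_constant_column_maps_to_zero(self):
        out, _ = normalize_features(pd.DataFrame({"a": [5.0, 5.0]}))
        np.testing.assert_allclose(out["a"], [0.0, 0.0])

    def test_idempotent_on_unit_range(self):
        df = pd.DataFrame({"a": [0.0, 0.3, 1.0]})
        out, _ = normalize_features(df)
        np.testing.assert_allclose(out["a"], df["a"])


class TestLogisticSolver:
    def test_matches_sklearn_oracle(self):
        """The IRLS fit reproduces sklearn's balanced ridge logistic."""
        from sklearn.linear_model import LogisticRegression

        from pdwear.cohort import fit_logistic
        rng = np.random.default_rng(30)
        Z = rng.normal(size=(38, 3))
        y = (rng.random(38) < 0.4).astype(int)
        beta = fit_logistic(Z, y, C=1.0)
        sk = LogisticRegression(C=1.0, class_weight="balanced",
                                solver="lbfgs", max_iter=5000, tol=1e-12)
        sk.fit(Z, y)
        np.testing.assert_allclose(beta[:-1], sk.coef_.ravel(), atol=1e-6)
        np.testing.assert_allclose(beta[-1], sk.intercept_[0], atol=1e-6)


class TestLoso:
    def test_perfect_separation(self):
        X = pd.DataFrame({"f": np.r_[np.zeros(8), np.ones(8)]})
        y = np.r_[np.zeros(8), np.ones(8)].astype(int)
        rep = loso_logistic(X, y)
        assert rep.auc == 1.0 and rep.accuracy == 1.0
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0
        assert rep.pooled_auc == 1.0

    def test_pooled_auc_equals_concordance_oracle(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame({"a": rng.normal(size=24), "b": rng.normal(size=24)})
        y = (rng.random(24) < 0.5).astype(int)
        if y.sum() in (0, len(y)):
            y[0] = 1 - y[0]
        rep = loso_logistic(X, y)
        p, yy = rep.probabilities, rep.y_true
        conc = ties = 0
        pairs = 0
        for i in np.flatnonzero(yy == 1):
            for j in np.flatnonzero(yy == 0):
                pairs += 1
                if p[i] > p[j]:
                    conc += 1
                elif p[i] == p[j]:
                    ties += 1
        assert rep.pooled_auc == pytest.approx((conc + 0.5 * ties) / pairs)

    def test_metrics_consistent_with_confusion(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame({"a": rng.normal(size=20)})
        y = np.r_[np.zeros(10), np.ones(10)].astype(int)
        rep = loso_logistic(X, y)
        c = rep.confusion
        n = sum(c.values())
        assert rep.accuracy == pytest.approx((c["tp"] + c["tn"]) / n)
        assert rep.sensitivity == pytest.approx(c["tp"] / (c["tp"] + c["fn"]))
        assert rep.specificity == pytest.approx(c["tn"] / (c["tn"] + c["fp"]))

    def test_null_labels_mean_auc_near_half(self):
        """Shuffled labels over repeated draws give chance-level AUC."""
        rng = np.random.default_rng(12)
        n = 20
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        aucs = []
        for _ in range(60):
            y = np.r_[np.zeros(n // 2), np.ones(n // 2)].astype(int)
            rng.shuffle(y)
            aucs.append(loso_logistic(X, y).auc)
        assert 0.4 < np.mean(aucs) < 0.6

    def test_no_leakage_from_held_out_subject(self):
        """Changing a held-out subject's features leaves its own fold's
        coefficients bit-identical (the fold never saw that subject)."""
        rng = np.random.default_rng(13)
        X = pd.DataFrame(rng.normal(size=(12, 2)), columns=["a", "b"])
        y = np.r_[np.zeros(6), np.ones(6)].astype(int)
        X2 = X.copy()
        X2.iloc[3] = [99.0, -99.0]
        r1 = loso_logistic(X, y)
        r2 = loso_logistic(X2, y)
        np.testing.assert_array_equal(r1.fold_coefs[3], r2.fold_coefs[3])


class TestEcdf:
    def test_counting(self):
        cdf = empirical_cdf([0, 0, 1, 3])
        assert cdf(0) == 0.5 and cdf(1) == 0.75 and cdf(3) == 1.0

    def test_single_value(self):
        assert empirical_cdf([4.2])(4.2) == 1.0

    def test_monotone(self):
        vals = np.random.default_rng(1).normal(size=50)
        cdf = empirical_cdf(vals)
        xs = np.linspace(vals.min() - 1, vals.max() + 1, 200)
        assert (np.diff(cdf(xs)) >= 0).all()


class TestMannWhitney:
    def test_disjoint_groups_u_zero(self):
        u, p, d = mann_whitney_cohen_d([1, 2, 3], [4, 5, 6])
        # brute force over the 9 pairs: no a > b
        assert u == 0.0
        assert d < 0

    def test_u_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(14)
        a, b = rng.normal(size=12), rng.normal(0.5, 1, size=9)
        u, _, _ = mann_whitney_cohen_d(a, b)
        gt = sum(x > y for x in a for y in b) + 0.5 * sum(x == y for x in a for y in b)
        assert u == pytest.approx(min(gt, len(a) * len(b) - gt))

    def test_identical_groups_zero_effect(self):
        x = [1.0, 2.0, 3.0, 4.0]
        _, _, d = mann_whitney_cohen_d(x, x)
        assert d == 0.0

    def test_exact_close_to_normal_approximation(self):
        rng = np.random.default_rng(15)
        a, b = rng.normal(size=10), rng.normal(size=10)
        _, p_exact, _ = mann_whitney_cohen_d(a, b)
        p_norm = stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method="asymptotic").pvalue
        assert abs(p_exact - p_norm) < 0.02

    def test_zero_pooled_sd_not_available(self):
        _, _, d = mann_whitney_cohen_d([2.0, 2.0], [2.0, 2.0])
        assert np.isnan(d)


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        rho, _ = spearman(x, x ** 2)
        assert rho == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        x = np.arange(8.0)
        rho, _ = spearman(x, x[::-1])
        assert rho == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(16)
        x, y = rng.normal(size=20), rng.normal(size=20)
        rho, _ = spearman(x, y)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        assert rho == pytest.approx(np.corrcoef(rx, ry)[0, 1])

    def test_constant_input_not_available(self):
        rho, p = spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(rho)


def _cov_frame(ids, rows):
    df = pd.DataFrame(rows, columns=["age", "disease_duration", "hy_stage",
                                     "updrs3", "moca"])
    df.insert(0, "subject_id", ids)
    return df


class TestMatching:
    COVS = ["age", "disease_duration", "hy_stage", "updrs3", "moca"]

    def test_matches_exhaustive_minimal_pairing(self):
        cases = _cov_frame(["c1", "c2"], [[70, 10, 2.5, 40, 24],
                                          [55, 4, 2.0, 25, 28]])
        controls = _cov_frame(["k1", "k2"], [[69, 11, 2.5, 41, 23],
                                             [56, 5, 2.0, 26, 27]])
        m = match_subgroups(cases, controls, self.COVS)
        # brute force both possible pairings on z-scored distances
        pooled = pd.concat([cases[self.COVS], controls[self.COVS]])
        mu, sd = pooled.mean(), pooled.std(ddof=1)
        zc = ((cases[self.COVS] - mu) / sd).to_numpy()
        zk = ((controls[self.COVS] - mu) / sd).to_numpy()

        def d(i, j):
            return float(np.linalg.norm(zc[i] - zk[j]))

        expected = ({("c1", "k1"), ("c2", "k2")}
                    if d(0, 0) + d(1, 1) <= d(0, 1) + d(1, 0)
                    else {("c1", "k2"), ("c2", "k1")})
        assert set(m.pairs) == expected

    def test_identical_covariates_zero_distance(self):
        cases = _cov_frame(["c1"], [[70, 10, 2.5, 40, 24]])
        controls = _cov_frame(["k1", "k2"], [[70, 10, 2.5, 40, 24],
                                             [50, 2, 1.5, 10, 30]])
        m = match_subgroups(cases, controls, self.COVS)
        assert m.pairs == [("c1", "k1")]

    def test_matching_improves_balance(self):
        rng = np.random.default_rng(17)
        n_cases, n_controls = 8, 20
        cases = _cov_frame([f"c{i}" for i in range(n_cases)],
                           np.column_stack([
                               rng.normal(70, 5, n_cases),
                               rng.normal(12, 3, n_cases),
                               rng.choice([2.0, 2.5, 3.0], n_cases),
                               rng.normal(40, 8, n_cases),
                               rng.normal(23, 2, n_cases)]))
        controls = _cov_frame([f"k{i}" for i in range(n_controls)],
                              np.column_stack([
                                  rng.normal(64, 6, n_controls),
                                  rng.normal(7, 3, n_controls),
                                  rng.choice([1.5, 2.0, 2.5], n_controls),
                                  rng.normal(32, 8, n_controls),
                                  rng.normal(25, 2, n_controls)]))
        m = match_subgroups(cases, controls, self.COVS)
        assert len(m.pairs) == n_cases
        assert len(set(k for _, k in m.pairs)) == n_cases  # no replacement
        bal = m.balance.set_index("covariate")
        assert (bal["smd_after"].abs() <= bal["smd_before"].abs() + 1e-9).all()

    def test_surplus_cases_reported_unmatched(self):
        cases = _cov_frame(["c1", "c2", "c3"],
                           [[70, 10, 2.5, 40, 24]] * 3)
        controls = _cov_frame(["k1"], [[70, 10, 2.5, 40, 24]])
        m = match_subgroups(cases, controls, self.COVS)
        assert len(m.pairs) == 1 and len(m.unmatched_cases) == 2
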