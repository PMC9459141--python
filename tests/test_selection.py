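"""Selection chain: ICC, univariate screen, variance filter, LASSO."""

import numpy as np
import pandas as pd
import pytest

from trusrad.selection import (
    compute_icc,
    icc_filter,
    lasso_select,
    select_features,
    spearman_matrix,
    univariate_screen,
    variance_filter,
)
from trusrad.synthetic import CohortConfig, RaterNoiseConfig, gen_feature_table, gen_rater_pairs


class TestICC:
    def test_identical_tables_give_one(self, rng):
        a = pd.DataFrame(rng.standard_normal((20, 4)), columns=list("abcd"))
        icc = compute_icc(a, a.copy())
        assert all(v == pytest.approx(1.0) for v in icc.values())

    def test_half_noise_recovers_half_icc(self):
        a, b = gen_rater_pairs(RaterNoiseConfig(1.0, 1.0, seed=7), 500, 30)
        icc = np.array(list(compute_icc(a, b).values()))
        assert abs(icc.mean() - 0.5) < 0.05
        # per-feature sampling SD at n=500 is ~0.045; allow ~3 SD
        assert (np.abs(icc - 0.5) < 0.15).all()

    def test_permuted_subjects_give_zero(self, rng):
        a = pd.DataFrame(rng.standard_normal((400, 3)), columns=list("xyz"))
        b = a.sample(frac=1.0, random_state=1).reset_index(drop=True)
        icc = np.array(list(compute_icc(a, b).values()))
        assert (np.abs(icc) < 0.15).all()

    def test_matches_pingouin_reference(self, rng):
        """ICC(2,1) against the independent ANOVA implementation."""
        pingouin = pytest.importorskip("pingouin")
        vals_a = rng.standard_normal(25) * 2
        vals_b = vals_a + rng.standard_normal(25)
        a = pd.DataFrame({"f": vals_a})
        b = pd.DataFrame({"f": vals_b})
        mine = compute_icc(a, b)["f"]
        long = pd.DataFrame({
            "subject": np.r_[np.arange(25), np.arange(25)],
            "rater": ["A"] * 25 + ["B"] * 25,
            "score": np.r_[vals_a, vals_b],
        })
        ref = pingouin.intraclass_corr(long, targets="subject", raters="rater",
                                       ratings="score")
        icc2 = float(ref.loc[ref.Type == "ICC(A,1)", "ICC"].iloc[0])
        assert mine == pytest.approx(icc2, abs=1e-8)

    def test_constant_feature_reported_missing_and_filtered(self):
        a = pd.DataFrame({"c": np.ones(10), "v": np.arange(10.0)})
        b = pd.DataFrame({"c": np.ones(10), "v": np.arange(10.0)})
        icc = compute_icc(a, b)
        assert np.isnan(icc["c"]) and icc["v"] == pytest.approx(1.0)
        assert icc_filter(icc) == ["v"]

    def test_filter_boundary_inclusive(self):
        icc = {"at": 0.80, "below": 0.79, "above": 0.93}
        assert sorted(icc_filter(icc, 0.8)) == ["above", "at"]
        with pytest.raises(ValueError, match="no feature"):
            icc_filter({"x": 0.5}, 0.8)


class TestScreen:
    def _table(self, seed=0, effect=2.0):
        t, _ = gen_feature_table(CohortConfig(
            n_benign=100, n_malignant=100, p_features=20, k_informative=5,
            effect_size=effect, block_rho=0.0, seed=seed))
        return t

    def test_informative_survive_null_mostly_dropped(self):
        keep_rates = np.zeros(20)
        for seed in range(10):
            survivors, pvals = univariate_screen(self._table(seed))
            for f in survivors:
                keep_rates[int(f.split("_")[1])] += 1
        assert (keep_rates[:5] == 10).all()          # every informative, every seed
        assert keep_rates[5:].mean() / 10 < 0.15     # null features ~alpha

    def test_identical_groups_feature_dropped(self):
        t = self._table()
        t["same"] = np.tile([1.0, 2.0], 100)
        t.loc[t.label == 1, "same"] = t.loc[t.label == 0, "same"].to_numpy()
        survivors, _ = univariate_screen(t)
        assert "same" not in survivors

    def test_alpha_one_keeps_all_nonconstant(self):
        t = self._table()
        survivors, _ = univariate_screen(t, alpha=1.0)
        assert len(survivors) == 20

    def test_require_both_is_stricter(self):
        t = self._table(effect=0.5)
        lenient, _ = univariate_screen(t, require_both=False)
        strict, _ = univariate_screen(t, require_both=True)
        assert set(strict) <= set(lenient)


class TestVarianceFilter:
    def test_constant_and_near_constant_removed(self):
        t = pd.DataFrame({
            "const": np.ones(50),
            "tiny": 5.0 + np.r_[1e-9, np.zeros(49)],
            "ok": np.r_[np.zeros(49), 1.0],
            "label": np.r_[np.zeros(25), np.ones(25)],
        })
        kept = variance_filter(t)
        assert kept == ["ok"]

    def test_all_constant_raises(self):
        t = pd.DataFrame({"a": np.ones(10), "label": np.r_[np.zeros(5), np.ones(5)]})
        with pytest.raises(ValueError, match="every feature"):
            variance_filter(t)


class TestLasso:
    def _cohort(self, seed=0):
        return gen_feature_table(CohortConfig(
            n_benign=100, n_malignant=100, p_features=50, k_informative=8,
            effect_size=1.0, block_rho=0.3, seed=seed))

    def test_full_shrinkage_at_lambda_max(self):
        table, _ = self._cohort()
        rep = lasso_select(table, n_folds=5, n_repeats=1, n_lambda=12, seed=0)
        lam_max = rep.lambda_grid[0]
        assert (np.abs(rep.lasso_path[float(lam_max)]) == 0).all()

    def test_recovery_of_informative_features(self):
        hits = 0
        for seed in range(4):
            table, informative = self._cohort(seed)
            rep = lasso_select(table, n_folds=10, n_repeats=1, n_lambda=25,
                               lambda_min_ratio=1e-2, seed=seed)
            chosen = {int(f.split("_")[1]) for f in rep.selected}
            hits += len(chosen & set(informative))
        assert hits / (4 * 8) >= 0.7

    def test_unpenalized_limit_matches_logistic_regression(self, rng):
        """At lambda -> 0 on a well-conditioned n >> p problem the LASSO fit
        approaches the unpenalised logistic solution."""
        from sklearn.linear_model import LogisticRegression

        n, p = 600, 4
        x = rng.standard_normal((n, p))
        eta = x @ np.array([0.8, -0.5, 0.3, 0.0])
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        table = pd.DataFrame(x, columns=[f"f{j}" for j in range(p)])
        table["label"] = y
        rep = lasso_select(table, n_folds=5, n_repeats=1, n_lambda=30,
                           lambda_min_ratio=1e-6, seed=0)
        xs = (x - x.mean(0)) / x.std(0)
        ref = LogisticRegression(C=1e8, max_iter=5000, tol=1e-10).fit(xs, y)
        smallest = float(rep.lambda_grid[-1])
        np.testing.assert_allclose(rep.lasso_path[smallest], ref.coef_[0],
                                   atol=1e-3)

    def test_path_sparsity_non_increasing_in_lambda(self):
        table, _ = gen_feature_table(CohortConfig(
            n_benign=150, n_malignant=150, p_features=20, k_informative=5,
            effect_size=1.0, block_rho=0.2, seed=9))
        rep = lasso_select(table, n_folds=5, n_repeats=1, n_lambda=25,
                           lambda_min_ratio=1e-2, seed=9)
        nz = [int((np.abs(rep.lasso_path[float(l)]) > 0).sum())
              for l in rep.lambda_grid]   # grid is decreasing in lambda
        assert all(nz[i] <= nz[i + 1] for i in range(len(nz) - 1))

    def test_lambda_stabilizes_across_repeats(self):
        """The CV-chosen penalty varies by less than half a grid step
        between independent runs once repeats are moderate."""
        table, _ = gen_feature_table(CohortConfig(
            n_benign=100, n_malignant=100, p_features=20, k_informative=5,
            effect_size=1.0, block_rho=0.2, seed=2))
        reps = [lasso_select(table, n_folds=10, n_repeats=20, n_lambda=25,
                             lambda_min_ratio=1e-2, seed=100 + r) for r in range(3)]
        lams = [r.lasso_lambda for r in reps]
        step = abs(float(np.diff(np.log(reps[0].lambda_grid))[0]))
        assert np.std(np.log(lams)) < 0.5 * step

    def test_nfolds_exceeding_class_count_rejected(self):
        table, _ = gen_feature_table(CohortConfig(
            n_benign=5, n_malignant=40, p_features=5, k_informative=2, seed=0))
        with pytest.raises(ValueError, match="n_folds"):
            lasso_select(table, n_folds=10, n_repeats=1, n_lambda=5)

    def test_linear_loss_flag(self):
        table, informative = self._cohort(1)
        rep = lasso_select(table, n_folds=5, n_repeats=1, n_lambda=20,
                           seed=1, loss="linear")
        chosen = {int(f.split("_")[1]) for f in rep.selected}
        assert len(chosen & set(informative)) >= 5


class TestSpearman:
    def test_self_and_monotone_transform(self, rng):
        x = rng.standard_normal(30)
        t = pd.DataFrame({"x": x, "ex": np.exp(x), "label": np.zeros(30)})
        m = spearman_matrix(t)
        assert m.loc["x", "x"] == 1.0
        assert m.loc["x", "ex"] == pytest.approx(1.0)

    def test_three_point_hand_case(self):
        t = pd.DataFrame({"x": [1.0, 2, 3], "y": [3.0, 1, 2], "label": [0, 0, 1]})
        assert spearman_matrix(t).loc["x", "y"] == pytest.approx(-0.5)

    def test_constant_feature_reported_missing(self, rng):
        t = pd.DataFrame({"x": rng.standard_normal(10), "c": np.ones(10),
                          "label": np.zeros(10)})
        m = spearman_matrix(t)
        assert np.isnan(m.loc["c", "x"]) and np.isnan(m.loc["c", "c"])
        assert m.loc["x", "x"] == 1.0


class TestFullChain:
    def test_stagewise_subsets_and_recovery(self):
        table, informative = gen_feature_table(CohortConfig(
            n_benign=100, n_malignant=100, p_features=40, k_informative=6,
            effect_size=1.2, block_rho=0.2, seed=4))
        a, b = gen_rater_pairs(RaterNoiseConfig(1.0, 0.2, seed=4), 30, 40)
        a.columns = b.columns = [c for c in table.columns if c != "label"]
        rep = select_features(table, a, b, n_repeats=1, n_lambda=20, seed=4)
        assert set(rep.screen_survivors) <= set(rep.icc_survivors)
        assert set(rep.variance_survivors) <= set(rep.screen_survivors)
        assert set(rep.selected) <= set(rep.variance_survivors)
        chosen = {int(f.split("_")[1]) for f in rep.selected}
        assert len(chosen & set(informative)) >= 4

    def test_selection_sensitivity_monotone_in_effect_size(self):
        """Recovery of informative features does not degrade as the class
        separation grows."""
        rates = []
        for effect in (0.25, 0.5, 1.0, 2.0):
            hits = 0
            for seed in (0, 1, 2):
                table, informative = gen_feature_table(CohortConfig(
                    n_benign=80, n_malignant=80, p_features=30, k_informative=5,
                    effect_size=effect, block_rho=0.2, seed=seed))
                rep = lasso_select(table, n_folds=5, n_repeats=1, n_lambda=20,
                                   seed=seed)
                chosen = {int(f.split("_")[1]) for f in rep.selected}
                hits += len(chosen & set(informative))
            rates.append(hits / 15)
        assert all(rates[i] <= rates[i + 1] + 0.15 for i in range(3))
        assert rates[-1] > rates[0]
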