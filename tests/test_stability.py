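import numpy as np
import pandas as pd
import pytest

import maizegxe as m
from maizegxe.stability import (PerfectFitError, StabilityReport,
                                ZeroVarianceError, aicc_compare, kang_ysi,
                                two_way_anova)

from conftest import make_trial_from_cell_means


# ---------------------------------------------------------------------------
# brute-force oracles: explicit loops over the textbook definitions

def brute_anova_ss(y):
    p, q, r = y.shape
    grand = y.mean()
    ss = {"Total": 0.0, "G": 0.0, "E": 0.0, "GEI": 0.0, "Rep": 0.0}
    for i in range(p):
        ss["G"] += q * r * (y[i].mean() - grand) ** 2
    for j in range(q):
        ss["E"] += p * r * (y[:, j].mean() - grand) ** 2
    for k in range(r):
        ss["Rep"] += p * q * (y[:, :, k].mean() - grand) ** 2
    for i in range(p):
        for j in range(q):
            ss["GEI"] += r * (y[i, j].mean() - y[i].mean() - y[:, j].mean()
                              + grand) ** 2
    for i in range(p):
        for j in range(q):
            for k in range(r):
                ss["Total"] += (y[i, j, k] - grand) ** 2
    ss["Error"] = ss["Total"] - ss["G"] - ss["E"] - ss["GEI"] - ss["Rep"]
    return ss


def brute_ecovalence(cell):
    p, q = cell.shape
    grand = cell.mean()
    w = np.zeros(p)
    for i in range(p):
        for j in range(q):
            w[i] += (cell[i, j] - cell[i].mean() - cell[:, j].mean() + grand) ** 2
    return w


def brute_fw_slopes(cell):
    p, q = cell.shape
    idx = np.array([cell[:, j].mean() - cell.mean() for j in range(q)])
    slopes = np.zeros(p)
    for i in range(p):
        num = sum((cell[i, j] - cell[i].mean()) * idx[j] for j in range(q))
        slopes[i] = num / sum(v ** 2 for v in idx)
    return slopes


def brute_gei_ss_of_means(cell):
    return float(brute_ecovalence(cell).sum())


def random_trial(rng, p=None, q=None, r=2):
    p = p or rng.integers(4, 7)
    q = q or rng.integers(3, 6)
    y = 4.0 + rng.normal(0, 1.0, size=(int(p), int(q), r))
    return m.YieldTrial(y, tuple(f"G{i}" for i in range(int(p))),
                        tuple(f"E{j}" for j in range(int(q))),
                        tuple(f"R{k}" for k in range(r)))


class TestAnova:
    def test_matches_bruteforce_on_random_trials(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            t = random_trial(rng)
            table = two_way_anova(t)
            oracle = brute_anova_ss(t.yields)
            for src, val in oracle.items():
                assert table.ss[src] == pytest.approx(val, rel=1e-9, abs=1e-12)

    def test_all_equal_trial_raises_zero_variance(self):
        t = make_trial_from_cell_means(np.full((4, 4), 3.0))
        with pytest.raises(ZeroVarianceError):
            two_way_anova(t)

    def test_percent_shares_sum_to_hundred(self):
        t = random_trial(np.random.default_rng(5))
        pct = two_way_anova(t).pct_ss
        assert sum(pct.values()) == pytest.approx(100.0)


class TestEnvironmentIndex:
    def test_two_environment_example(self):
        t = make_trial_from_cell_means(np.array([[3.0, 5.0], [3.0, 5.0],
                                                 [3.0, 5.0]]))
        np.testing.assert_allclose(m.environment_index(t), [-1.0, 1.0])

    def test_centering_identity(self):
        t = random_trial(np.random.default_rng(1))
        assert m.environment_index(t).sum() == pytest.approx(0.0, abs=1e-12)


class TestFinlayWilkinson:
    def test_average_genotype_has_unit_slope_zero_deviation(self):
        env = np.array([2.0, 4.0, 6.0, 3.0])
        cell = np.vstack([env, env + 1.0, env - 1.0])
        t = make_trial_from_cell_means(cell)
        bi, s2d = m.finlay_wilkinson(t)
        np.testing.assert_allclose(bi, 1.0, atol=1e-12)
        np.testing.assert_allclose(s2d, 0.0, atol=1e-12)

    def test_hand_regression_slope_two(self):
        # rows respond 2x / 1x / 0x to the environment index (-1, 0, +1)
        e = np.array([-1.0, 0.0, 1.0])
        cell = np.vstack([4 + 2 * e, 1 + e, np.full(3, 4.0)])
        t = make_trial_from_cell_means(cell)
        bi, s2d = m.finlay_wilkinson(t)
        np.testing.assert_allclose(bi, [2.0, 1.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(s2d, 0.0, atol=1e-12)
        assert bi.mean() == pytest.approx(1.0)

    def test_slopes_average_one_on_random_trials(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            bi, _ = m.finlay_wilkinson(random_trial(rng))
            assert bi.mean() == pytest.approx(1.0, abs=1e-9)

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(3)
        t = random_trial(rng)
        bi, _ = m.finlay_wilkinson(t)
        np.testing.assert_allclose(bi, brute_fw_slopes(t.cell_means()),
                                   rtol=1e-9)

    def test_flat_environments_rejected(self):
        t = make_trial_from_cell_means(np.array([[1.0, 1, 1], [2, 2, 2],
                                                 [3, 3, 3]]))
        with pytest.raises(ZeroVarianceError):
            m.finlay_wilkinson(t)


class TestEcovalenceAndShukla:
    def test_additive_table_has_zero_ecovalence(self):
        cell = np.add.outer(np.array([1.0, 2, 3]), np.array([0.0, 1, 2, 4]))
        t = make_trial_from_cell_means(cell)
        np.testing.assert_allclose(m.wricke_ecovalence(t), 0.0, atol=1e-12)

    def test_single_interaction_cell_pattern_matches_bruteforce(self):
        cell = np.full((3, 3), 5.0)
        cell[0, 0] += 0.6
        cell[0, 1] -= 0.6
        t = make_trial_from_cell_means(cell)
        np.testing.assert_allclose(m.wricke_ecovalence(t),
                                   brute_ecovalence(cell), rtol=1e-12)

    def test_ecovalence_sums_to_gei_ss_of_means(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            t = random_trial(rng)
            w = m.wricke_ecovalence(t)
            assert w.sum() == pytest.approx(brute_gei_ss_of_means(t.cell_means()),
                                            rel=1e-9)

    def test_equal_ecovalences_give_equal_sigma2(self):
        s = m.shukla_sigma2(np.full(5, 2.0), 5, 4)
        assert np.allclose(s, s[0])

    def test_permutation_equivariance(self):
        w = np.array([1.0, 5.0, 2.0, 9.0])
        perm = [3, 0, 2, 1]
        s = m.shukla_sigma2(w, 4, 5)
        np.testing.assert_allclose(m.shukla_sigma2(w[perm], 4, 5), s[perm])

    def test_affine_increasing_in_w_preserves_ranks(self):
        rng = np.random.default_rng(6)
        w = rng.uniform(0, 10, size=8)
        s = m.shukla_sigma2(w, 8, 5)
        assert list(np.argsort(w)) == list(np.argsort(s))

    def test_too_few_genotypes_rejected(self):
        with pytest.raises(ValueError):
            m.shukla_sigma2(np.ones(2), 2, 5)


class TestAmmi:
    def test_additive_table_yields_zero_axes(self):
        cell = np.add.outer(np.array([1.0, 2, 3, 5]), np.array([0.0, 1, 2]))
        dec = m.ammi(make_trial_from_cell_means(cell))
        assert dec.singular_values.size == 0
        assert dec.gei_ss == pytest.approx(0.0)

    def test_rank_one_interaction_fully_on_first_axis(self):
        u = np.array([1.0, -1.0, 0.5, -0.5]);  u -= u.mean()
        v = np.array([2.0, -1.0, -1.0]);       v -= v.mean()
        cell = 5.0 + 0.8 * np.outer(u, v)
        dec = m.ammi(make_trial_from_cell_means(cell))
        assert dec.axis_ss[0] / dec.gei_ss == pytest.approx(1.0)

    def test_axis_ss_sum_equals_bruteforce_gei_ss(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            t = random_trial(rng, p=5, q=4)
            dec = m.ammi(t)
            assert dec.gei_ss == pytest.approx(
                brute_gei_ss_of_means(t.cell_means()), rel=1e-9)

    def test_genotype_scores_orthogonal_across_axes(self):
        t = random_trial(np.random.default_rng(8), p=6, q=5)
        g = m.ammi(t).genotype_scores
        gram = g.T @ g
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-9 * max(1.0, np.abs(gram).max())


class TestAsv:
    def test_zero_scores_give_zero(self):
        assert m.asv(np.zeros(3), np.zeros(3), 2.0, 1.0)[0] == 0.0

    def test_three_four_five_triangle_when_axes_equal(self):
        out = m.asv(np.array([3.0]), np.array([4.0]), 1.0, 1.0)
        assert out[0] == pytest.approx(5.0)

    def test_weight_ratio_two(self):
        out = m.asv(np.array([1.0]), np.array([1.0]), 2.0, 1.0)
        assert out[0] == pytest.approx(np.sqrt(5.0))

    def test_degenerate_second_axis_falls_back_to_abs_ipca1(self):
        out = m.asv(np.array([-2.0, 1.0]), np.array([9.0, 9.0]), 1.0, 0.0)
        np.testing.assert_allclose(out, [2.0, 1.0])


class TestKangYsi:
    def test_identical_genotypes_yield_no_stable_flags(self):
        t = make_trial_from_cell_means(np.full((4, 4), 3.0))
        ysi, stable = kang_ysi(t, np.zeros(4), error_ms=0.0, error_df=15)
        assert np.allclose(ysi, ysi[0])
        assert not stable.any()

    def test_unstable_genotype_penalised_below_mean(self):
        rng = np.random.default_rng(9)
        cell = 4.0 + rng.normal(0, 0.05, size=(6, 5))
        cell[0] += np.array([2.0, -2.0, 1.5, -1.5, 0.0])  # huge interaction
        t = make_trial_from_cell_means(cell, noise=rng.normal(0, 0.05, (6, 5, 2)))
        w = m.wricke_ecovalence(t)
        s2 = m.shukla_sigma2(w, 6, 5)
        anova = two_way_anova(t)
        ysi, stable = kang_ysi(t, s2, anova.ms["Error"], anova.df["Error"])
        assert ysi[0] < ysi.mean()
        assert not stable[0]


class TestAicc:
    def test_slope_structured_gei_selects_finlay_wilkinson(self):
        spec = m.TrialSpec(n_genotypes=16, n_environments=8, n_reps=2,
                           gei_structure="slope",
                           betas=tuple(np.linspace(0.4, 1.6, 16)),
                           var_fractions={"E": .67, "G": .19, "GEI": .13,
                                          "rep": 0.0, "error": .01}, seed=3)
        aicc = aicc_compare(m.generate_trial(spec))
        assert min(aicc, key=aicc.get) == "FW"

    def test_perfect_fit_is_flagged_not_silent(self):
        cell = np.add.outer(np.array([1.0, 2, 3, 4]), np.array([0.0, 1, 2]))
        t = make_trial_from_cell_means(cell)
        with pytest.raises(PerfectFitError):
            aicc_compare(t, models=("additive",))

    def test_unknown_model_rejected(self):
        t = random_trial(np.random.default_rng(10))
        with pytest.raises(ValueError, match="unknown stability model"):
            aicc_compare(t, models=("GGE",))


def _report_from_stats(values):
    table = pd.DataFrame({
        "mean_yield": values, "bi": 1 + 0.1 * values, "S2d": values ** 2,
        "ecovalence": values ** 2, "sigma2": values ** 2, "asv": np.abs(values),
        "ysi": values, "stable": values > values.mean(),
    }, index=pd.Index([f"G{i}" for i in range(len(values))], name="genotype"))
    return StabilityReport(source="x", table=table, aicc={}, n_stable=0)


class TestRankConcordance:
    def test_identical_reports_give_perfect_correlation(self):
        t = m.generate_trial(m.TrialSpec(seed=21))
        rep = m.build_stability_report(t, "a")
        conc = m.rank_concordance(rep, rep)
        assert np.allclose(conc["spearman_rho"].dropna(), 1.0)
        assert (conc["top3_overlap"] == 1.0).all()

    def test_reversed_statistics_give_negative_one(self):
        v = np.arange(1.0, 7.0)
        conc = m.rank_concordance(_report_from_stats(v), _report_from_stats(v[::-1]))
        for stat in ("mean_yield", "ecovalence", "sigma2", "asv", "ysi"):
            assert conc.loc[stat, "spearman_rho"] == pytest.approx(-1.0)

    def test_label_mismatch_rejected(self):
        a = m.build_stability_report(m.generate_trial(m.TrialSpec(seed=1)), "a")
        b = m.build_stability_report(
            m.generate_trial(m.TrialSpec(seed=1, n_genotypes=15)), "b")
        with pytest.raises(ValueError, match="genotype sets"):
            m.rank_concordance(a, b)

    def test_random_rankings_average_to_zero_correlation(self):
        rng = np.random.default_rng(11)
        base = _report_from_stats(np.arange(1.0, 11.0))
        rhos = []
        for _ in range(300):
            perm = rng.permutation(10).astype(float) + 1.0
            rhos.append(m.rank_concordance(base, _report_from_stats(perm))
                        .loc["mean_yield", "spearman_rho"])
        assert abs(np.mean(rhos)) < 0.06
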