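import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from pbbsoil.stats import (
    bh_fdr,
    differential_abundance,
    dunn_posthoc,
    holm_sidak,
    kruskal_wallis,
    mann_whitney_u,
    welch_t,
)

from conftest import rpm_profile


class TestMannWhitney:
    def test_exact_enumeration_fixture(self):
        # U = 0; all 3 low ranks in x: 2 of C(6,3)=20 arrangements as extreme
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0
        assert res.p_value == pytest.approx(0.1)
        assert "exact" in res.method

    def test_perfect_symmetry(self):
        res = mann_whitney_u([1, 2], [1, 2])
        assert res.statistic == pytest.approx(2.0)  # n_x n_y / 2

    def test_tie_corrected_normal_approximation(self, rng):
        x = np.round(rng.normal(0, 1, 30), 1)
        y = np.round(rng.normal(0.5, 1, 30), 1)
        res = mann_whitney_u(x, y)
        assert "asymptotic" in res.method
        # independent reference: explicit z with tie correction + continuity
        nx, ny = 30, 30
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        U = ranks[:nx].sum() - nx * (nx + 1) / 2
        U = max(U, nx * ny - U)
        _, t = np.unique(pooled, return_counts=True)
        N = nx + ny
        sigma = np.sqrt(
            nx * ny / 12 * ((N + 1) - (t**3 - t).sum() / (N * (N - 1)))
        )
        z = (U - nx * ny / 2 - 0.5) / sigma
        p_ref = 2 * sps.norm.sf(z)
        assert res.p_value == pytest.approx(p_ref, abs=1e-8)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_swap_invariance(self, rng):
        x, y = rng.normal(0, 1, 10), rng.normal(1, 1, 10)
        assert mann_whitney_u(x, y).p_value == pytest.approx(
            mann_whitney_u(y, x).p_value
        )


class TestWelch:
    def test_identical_samples(self):
        res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_welch_satterthwaite_df_fixture(self):
        # nx = ny = 10, s2x = 1, s2y = 4 -> df = 13.235
        x = np.arange(10.0)
        x = (x - x.mean()) / x.std(ddof=1)
        y = 2.0 * x + 5.0
        res = welch_t(x, y)
        assert res.df == pytest.approx(13.235, abs=5e-4)

    def test_matches_formula_oracle(self, rng):
        x, y = rng.normal(0, 1, 8), rng.normal(1, 2, 8)
        res = welch_t(x, y)
        se2 = x.var(ddof=1) / 8 + y.var(ddof=1) / 8
        t = (x.mean() - y.mean()) / np.sqrt(se2)
        df = se2**2 / ((x.var(ddof=1) / 8) ** 2 / 7 + (y.var(ddof=1) / 8) ** 2 / 7)
        p = 2 * sps.t.sf(abs(t), df)
        assert res.statistic == pytest.approx(t, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_degenerate_zero_variance(self):
        res = welch_t([2.0, 2.0], [2.0, 2.0])
        assert (res.statistic, res.p_value) == (0.0, 1.0)
        with pytest.warns(UserWarning):
            res = welch_t([2.0, 2.0], [3.0, 3.0])
        assert res.p_value == 0.0

    def test_swap_flips_sign_only(self, rng):
        x, y = rng.normal(0, 1, 12), rng.normal(1, 1, 12)
        a, b = welch_t(x, y), welch_t(y, x)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p_value == pytest.approx(b.p_value)


class TestMultipleTesting:
    def test_bh_step_up_fixture(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04], atol=1e-12
        )

    def test_bh_trivial_cases(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0]), [1.0, 1.0])
        np.testing.assert_allclose(bh_fdr([0.3]), [0.3])

    def test_bh_rejects_invalid_p(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        ps=st.lists(st.floats(0, 1), min_size=2, max_size=12),
        idx=st.integers(0, 11),
        bump=st.floats(0.0, 0.5),
    )
    def test_bh_monotone_in_each_input(self, ps, idx, bump):
        # increasing one input p never decreases any output q
        idx = idx % len(ps)
        q1 = bh_fdr(ps)
        ps2 = list(ps)
        ps2[idx] = min(1.0, ps2[idx] + bump)
        q2 = bh_fdr(ps2)
        assert (q2 >= q1 - 1e-12).all()

    def test_holm_sidak_fixture(self):
        # adj1 = 1 - (1 - 0.01)^2 = 0.0199; adj2 = max(adj1, 0.04)
        np.testing.assert_allclose(
            holm_sidak([0.01, 0.04]), [0.0199, 0.04], atol=1e-10
        )

    def test_holm_sidak_dominates_raw_and_sorted_nondecreasing(self, rng):
        p = rng.uniform(0, 1, 15)
        adj = holm_sidak(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestKruskalDunn:
    def test_identical_groups(self):
        res = kruskal_wallis([[1.0, 1.0], [1.0, 1.0], [1.0, 1.0]])
        assert (res.statistic, res.p_value) == (0.0, 1.0)

    def test_matches_rank_sum_oracle(self, rng):
        groups = [rng.normal(i, 1, 7) for i in range(3)]
        res = kruskal_wallis(groups)
        # explicit ranking oracle (no ties with continuous data)
        pooled = np.concatenate(groups)
        ranks = sps.rankdata(pooled)
        N = pooled.size
        start, H = 0, 0.0
        for g in groups:
            r = ranks[start:start + g.size]
            H += r.sum() ** 2 / g.size
            start += g.size
        H = 12 / (N * (N + 1)) * H - 3 * (N + 1)
        assert res.statistic == pytest.approx(H, abs=1e-10)

    def test_invariant_under_monotone_transform(self, rng):
        groups = [rng.uniform(0, 1, 6) for _ in range(3)]
        h1 = kruskal_wallis(groups).statistic
        h2 = kruskal_wallis([np.exp(5 * g) for g in groups]).statistic
        assert h1 == pytest.approx(h2, abs=1e-10)

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0, 2.0]])

    def test_dunn_matches_hand_computed_fixture(self):
        # groups [1,2],[3,4],[5,6]: mean ranks 1.5, 3.5, 5.5; no ties
        # var_base = 6*7/12 = 3.5; denom = sqrt(3.5 * (1/2 + 1/2))
        res = dunn_posthoc([[1, 2], [3, 4], [5, 6]], labels=["a", "b", "c"])
        denom = np.sqrt(3.5)
        z_expect = {
            ("a", "b"): -2.0 / denom,
            ("a", "c"): -4.0 / denom,
            ("b", "c"): -2.0 / denom,
        }
        p_raw = {k: 2 * sps.norm.sf(abs(v)) for k, v in z_expect.items()}
        # Holm-Sidak by hand: sorted raw [p_ac, p_ab, p_bc]
        adj_ac = 1 - (1 - p_raw[("a", "c")]) ** 3
        adj_rest = max(adj_ac, 1 - (1 - p_raw[("a", "b")]) ** 2)
        for r in res:
            pair = r.extra["pair"]
            assert r.statistic == pytest.approx(z_expect[pair], abs=1e-8)
            assert r.p_value == pytest.approx(p_raw[pair], abs=1e-8)
            expected_q = adj_ac if pair == ("a", "c") else adj_rest
            assert r.q_value == pytest.approx(expected_q, abs=1e-8)

    def test_dunn_identical_groups_all_adjusted_one(self):
        res = dunn_posthoc([[2.0, 2.0], [2.0, 2.0], [2.0, 2.0]])
        assert all(r.q_value == 1.0 for r in res)


class TestDifferentialAbundance:
    def _profile(self, rng, n_genera=30, n=25, shift_rows=(), shift=0.0):
        low = rng.lognormal(2, 1, size=(n_genera, n))
        high = rng.lognormal(2, 1, size=(n_genera, n))
        for r in shift_rows:
            high[r] *= np.exp(shift)
        matrix = pd.DataFrame(
            np.hstack([low, high]),
            index=[f"g{i}" for i in range(n_genera)],
            columns=[f"L{i}" for i in range(n)] + [f"H{i}" for i in range(n)],
        )
        groups = pd.Series(["low"] * n + ["high"] * n, index=matrix.columns)
        return rpm_profile(matrix), groups

    def test_identical_samples_all_none(self):
        matrix = pd.DataFrame(
            np.ones((5, 8)), index=[f"g{i}" for i in range(5)],
            columns=[f"s{i}" for i in range(8)],
        )
        groups = pd.Series(["low"] * 4 + ["high"] * 4, index=matrix.columns)
        out = differential_abundance(rpm_profile(matrix), groups)
        assert (out["direction"] == "none").all()
        assert (out.loc[out["tested"], "p"] == 1.0).all()

    def test_planted_suppression_called_down(self, rng):
        prof, groups = self._profile(rng, shift_rows=range(5), shift=-3.0)
        out = differential_abundance(prof, groups)
        called_down = set(out.index[out["direction"] == "down"])
        planted = {f"g{i}" for i in range(5)}
        assert len(planted & called_down) >= 4
        assert not planted & set(out.index[out["direction"] == "up"])

    def test_q_dominates_p_and_direction_respects_threshold(self, rng):
        prof, groups = self._profile(rng, shift_rows=range(3), shift=-2.0)
        out = differential_abundance(prof, groups)
        tested = out[out["tested"]]
        assert (tested["q"] >= tested["p"] - 1e-12).all()
        assert (out.loc[out["q"] >= 0.05, "direction"] == "none").all()

    def test_rare_genera_reported_untested(self, rng):
        prof, groups = self._profile(rng, n_genera=10)
        m = prof.matrix.copy()
        m.loc["rare"] = 0.0
        m.loc["rare", m.columns[0]] = 1.0  # present in 1/20 samples < 5%... keep 0.05
        out = differential_abundance(rpm_profile(m), groups, prevalence_min=0.25)
        assert not out.loc["rare", "tested"]
        assert out.loc["rare", "direction"] == "none"
        assert "rare" in out.index  # reported, not dropped

    def test_requires_rpm_and_two_per_group(self, toy_profile):
        groups = pd.Series({"s1": "low", "s2": "high"})
        with pytest.raises(ValueError, match="RPM"):
            differential_abundance(toy_profile, groups)
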