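import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from octamorph import (
    compare_types,
    dunn_posthoc,
    kruskal_wallis,
    levene_test,
    one_way_anova,
    shapiro_wilk,
)
from octamorph.synth import sample_cohort


def brute_force_midranks(pooled):
    """Independent mid-rank oracle by direct enumeration."""
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    return ranks


class TestLevene:
    def test_identical_groups_zero_statistic(self):
        w, p = levene_test([1, 2, 3], [1, 2, 3])
        assert w == 0.0
        assert p == 1.0

    def test_detects_variance_inhomogeneity(self):
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(100):
            a = rng.normal(0, 1, 50)
            b = rng.normal(0, 3, 50)
            hits += levene_test(a, b)[1] < 0.05
        assert hits >= 90

    def test_constant_groups_degenerate(self):
        with pytest.warns(UserWarning):
            w, p = levene_test([5.0, 5.0], [5.0, 5.0])
        assert (w, p) == (0.0, 1.0)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            levene_test([1.0], [1.0, 2.0])

    def test_matches_scipy_on_generic_data(self):
        rng = np.random.default_rng(0)
        gs = [rng.normal(0, s, 30) for s in (1, 2, 3)]
        w, p = levene_test(*gs)
        w2, p2 = sps.levene(*gs, center="mean")
        assert (w, p) == pytest.approx((w2, p2))


class TestShapiroWilk:
    def test_normal_quantile_sample_clearly_normal(self):
        n = 50
        x = sps.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        w, p = shapiro_wilk(x)
        assert p > 0.5
        assert 0 < w <= 1

    def test_lognormal_sample_rejected(self):
        rng = np.random.default_rng(1)
        x = rng.lognormal(0.0, 1.0, 90)
        assert shapiro_wilk(x)[1] < 0.01

    @pytest.mark.parametrize("n", [2, 5001])
    def test_out_of_range_n_rejected(self, n):
        with pytest.raises(ValueError):
            shapiro_wilk(np.zeros(n) + np.arange(n))


class TestKruskalWallis:
    def test_identical_groups_h_zero(self):
        h, p = kruskal_wallis([1, 2, 3], [1, 2, 3], [1, 2, 3])
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_worked_example_h(self, worked_groups):
        h, p = kruskal_wallis(*worked_groups)
        assert h == pytest.approx(7.2, abs=1e-12)
        assert p == pytest.approx(sps.chi2.sf(7.2, 2))

    def test_tied_data_matches_brute_force_ranks(self):
        gs = [[1.0, 2.0, 2.0, 3.0], [2.0, 4.0, 4.0], [4.0, 5.0, 5.0, 5.0]]
        pooled = [x for g in gs for x in g]
        ranks = brute_force_midranks(pooled)
        n = len(pooled)
        sizes = [len(g) for g in gs]
        means, i = [], 0
        for s in sizes:
            means.append(sum(ranks[i:i + s]) / s)
            i += s
        from collections import Counter
        ties = sum(t**3 - t for t in Counter(pooled).values())
        h_oracle = (12 / (n * (n + 1))) * sum(
            s * m * m for s, m in zip(sizes, means)
        ) - 3 * (n + 1)
        h_oracle /= 1 - ties / (n**3 - n)
        h, _ = kruskal_wallis(*gs)
        assert h == pytest.approx(h_oracle, abs=1e-12)

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(2)
        gs = [np.round(rng.normal(size=20), 1) for _ in range(3)]
        h, p = kruskal_wallis(*gs)
        h2, p2 = sps.kruskal(*gs)
        assert h == pytest.approx(h2, abs=1e-10)
        assert p == pytest.approx(p2, abs=1e-10)

    def test_all_identical_defined_degenerate(self):
        with pytest.warns(UserWarning):
            h, p = kruskal_wallis([2.0, 2.0], [2.0, 2.0], [2.0])
        assert (h, p) == (0.0, 1.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(0.1, 100), min_size=3, max_size=12))
    def test_h_invariant_under_monotone_transform(self, values):
        k = len(values) // 3
        gs = [values[:k] or [1.0], values[k:2 * k] or [2.0], values[2 * k:]]
        h1, _ = kruskal_wallis(*gs)
        gs_t = [[np.log1p(x) ** 3 for x in g] for g in gs]
        h2, _ = kruskal_wallis(*gs_t)
        assert h1 == pytest.approx(h2, abs=1e-9)


class TestDunn:
    def test_worked_example_pair_1_3(self, worked_groups):
        pw = dunn_posthoc(*worked_groups)
        p13 = next(p for p in pw if p.pair == (1, 3))
        assert abs(p13.statistic) == pytest.approx(2.683, abs=1e-3)
        assert p13.p_adj == pytest.approx(0.0219, abs=1e-4)

    def test_identical_groups_all_null(self):
        pw = dunn_posthoc([1, 2, 3], [1, 2, 3], [1, 2, 3])
        for p in pw:
            assert p.statistic == pytest.approx(0.0, abs=1e-12)
            assert p.p_adj == 1.0

    def test_adjusted_p_capped_at_one(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            gs = [rng.normal(size=5) for _ in range(3)]
            assert all(p.p_adj <= 1.0 for p in dunn_posthoc(*gs))

    def test_z_matches_brute_force_rank_computation(self):
        gs = [[3.0, 1.0, 4.0], [1.0, 5.0], [9.0, 2.0, 6.0, 5.0]]
        pooled = [x for g in gs for x in g]
        ranks = brute_force_midranks(pooled)
        n = len(pooled)
        sizes = [len(g) for g in gs]
        means, i = [], 0
        for s in sizes:
            means.append(sum(ranks[i:i + s]) / s)
            i += s
        from collections import Counter
        ties = sum(t**3 - t for t in Counter(pooled).values())
        var = n * (n + 1) / 12 - ties / (12 * (n - 1))
        z_oracle = (means[0] - means[2]) / np.sqrt(var * (1 / sizes[0] + 1 / sizes[2]))
        pw = dunn_posthoc(*gs)
        z13 = next(p for p in pw if p.pair == (1, 3)).statistic
        assert z13 == pytest.approx(z_oracle, abs=1e-12)


class TestAnova:
    def test_identical_groups(self):
        f, p = one_way_anova([1, 2, 3], [1, 2, 3])
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_worked_example_matches_scipy(self, worked_groups):
        # hand ANOVA table: SSB = 54 (df 2), SSW = 6 (df 6) → F = 27
        f, p = one_way_anova(*worked_groups)
        assert f == pytest.approx(27.0, abs=1e-10)
        assert p == pytest.approx(sps.f_oneway(*worked_groups)[1])

    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(11)
        hits = 0
        n_sim = 1000
        for _ in range(n_sim):
            gs = [rng.normal(size=12) for _ in range(3)]
            hits += one_way_anova(*gs)[1] < 0.05
        assert 0.03 <= hits / n_sim <= 0.07

    def test_zero_within_variance_warns(self):
        with pytest.warns(UserWarning):
            f, p = one_way_anova([1.0, 1.0], [2.0, 2.0])
        assert f == np.inf and p == 0.0


class TestCompareTypes:
    def test_calibrated_cohort_selects_kruskal_for_skewed_params(self):
        cohort = sample_cohort(seed=11)
        results = {r.parameter: r for r in compare_types(cohort)}
        assert results["area_mm2"].omnibus_method == "kruskal_wallis"
        assert results["sumL_mm"].omnibus_method == "kruskal_wallis"
        for r in results.values():
            assert len(r.pairwise) == 3
            for p in r.pairwise:
                assert p.p_adj == pytest.approx(min(1.0, 3 * p.p_raw))

    def test_null_cohort_type_i_control(self):
        rng = np.random.default_rng(5)
        import pandas as pd
        n_rep = 100
        any_sig = np.zeros(6)
        params = ["area_mm2", "fd", "numN_per_mm2", "flow_pct", "sumL_mm", "avgW_um"]
        for _ in range(n_rep):
            cohort = pd.DataFrame({
                "id": [str(i) for i in range(90)],
                "mnv_type": [1] * 39 + [2] * 32 + [3] * 19,
            })
            for c in params:
                cohort[c] = rng.normal(10, 2, 90)
            for j, r in enumerate(compare_types(cohort)):
                any_sig[j] += any(p.p_adj < 0.05 for p in r.pairwise)
        # per parameter, >= 93 % of replicates show no significant pair
        assert np.all(n_rep - any_sig >= 93)

    def test_identical_cohort_degenerate(self):
        import pandas as pd
        cohort = pd.DataFrame({
            "id": [str(i) for i in range(12)],
            "mnv_type": [1, 1, 1, 1, 2, 2, 2, 2, 3, 3, 3, 3],
            "area_mm2": [2.0] * 12,
        })
        (r,) = compare_types(cohort, parameters=["area_mm2"])
        assert r.degenerate
        assert r.omnibus_p == 1.0
        assert all(p.p_adj == 1.0 for p in r.pairwise)

    def test_missing_values_dropped_and_counted(self):
        import pandas as pd
        rng = np.random.default_rng(0)
        cohort = pd.DataFrame({
            "id": [str(i) for i in range(30)],
            "mnv_type": [1] * 10 + [2] * 10 + [3] * 10,
            "fd": rng.normal(1.3, 0.1, 30),
        })
        cohort.loc[3, "fd"] = np.nan
        (r,) = compare_types(cohort, parameters=["fd"])
        assert r.n_dropped == 1
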