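import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from chromatex import compare_texture_groups, mann_whitney_u, t_test
from conftest import mwu_exact_bruteforce


class TestMannWhitney:
    def test_worked_example_complete_separation(self):
        r = mann_whitney_u([1, 2, 3], [10, 20, 30])
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(0.1, abs=1e-12)
        assert r.method == "mann_whitney_exact"

    def test_identical_groups_p_one(self):
        r = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert r.p_value == 1.0

    def test_single_observation_groups(self):
        r = mann_whitney_u([5.0], [7.0])
        assert r.method == "mann_whitney_exact"
        assert r.p_value == 1.0  # only 2 assignments, both tails full

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(60):
            n_a = int(rng.integers(1, 9))
            n_b = int(rng.integers(1, 9))
            a = rng.normal(size=n_a)
            b = rng.normal(size=n_b)
            r = mann_whitney_u(a, b)
            assert r.method == "mann_whitney_exact"
            assert r.p_value == pytest.approx(mwu_exact_bruteforce(a, b), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        a, b = rng.normal(size=6), rng.normal(size=7)
        r1 = mann_whitney_u(a, b)
        r2 = mann_whitney_u(np.exp(a), np.exp(b))
        assert r1.p_value == r2.p_value and r1.statistic == r2.statistic

    def test_normal_approximation_close_to_exact(self, rng, monkeypatch):
        # tie-free 10 vs 10 draws: the asymptotic path tracks exact enumeration
        import chromatex.stats as stats_mod
        deltas = []
        for _ in range(100):
            a, b = rng.normal(size=10), rng.normal(size=10)
            exact = mann_whitney_u(a, b)  # combined n = 20 -> exact mode
            assert exact.method == "mann_whitney_exact"
            with monkeypatch.context() as m:
                m.setattr(stats_mod, "EXACT_MAX_COMBINED_N", 0)
                approx = mann_whitney_u(a, b)
            assert approx.method == "mann_whitney_normal"
            deltas.append(abs(exact.p_value - approx.p_value))
        assert max(deltas) < 0.01

    def test_normal_path_matches_scipy_asymptotic(self, rng):
        a, b = rng.normal(size=15), rng.normal(size=15)
        ours = mann_whitney_u(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert ours.method == "mann_whitney_normal"
        assert ours.p_value == pytest.approx(float(ref.pvalue), abs=1e-9)

    def test_exact_matches_scipy_exact(self, rng):
        a, b = rng.normal(size=6), rng.normal(size=5)
        ours = mann_whitney_u(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert ours.p_value == pytest.approx(float(ref.pvalue), abs=1e-12)


class TestTTest:
    def test_identical_groups(self):
        r = t_test([1, 2, 3], [1, 2, 3])
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_worked_example_matches_scipy(self):
        r = t_test([1, 2, 3], [4, 5, 6])
        ref = sps.ttest_ind([1, 2, 3], [4, 5, 6], equal_var=True)
        assert r.statistic == pytest.approx(float(ref.statistic), abs=1e-12)
        assert r.p_value == pytest.approx(float(ref.pvalue), abs=1e-12)
        assert r.p_value == pytest.approx(0.0214, abs=5e-4)

    def test_swap_negates_t_keeps_p(self):
        r1 = t_test([1, 2, 3], [4, 5, 7])
        r2 = t_test([4, 5, 7], [1, 2, 3])
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_zero_variance_conventions(self):
        same = t_test([2, 2], [2, 2])
        assert same.p_value == 1.0
        diff = t_test([2, 2], [3, 3])
        assert diff.p_value == 0.0 and diff.notes


class TestCompareTextureGroups:
    def _table(self, values):
        return pd.DataFrame({"sample_id": range(len(values)), "asm": values,
                             "contrast": values, "correlation": values,
                             "idm": values, "entropy": values})

    def test_identical_tables_p_one(self):
        t = self._table([0.1, 0.2, 0.3])
        for cmp_ in compare_texture_groups(t, t.copy()):
            assert cmp_.p_value == 1.0

    def test_undefined_correlations_dropped_with_note(self):
        a = self._table([0.1, 0.2, 0.3])
        b = self._table([0.4, 0.5, 0.6])
        a.loc[0, "correlation"] = np.nan
        out = {c.parameter: c for c in compare_texture_groups(a, b)}
        assert out["correlation"].n_a == 2
        assert "dropped 1" in out["correlation"].notes

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            compare_texture_groups(self._table([]), self._table([0.1]))

    def test_separated_groups_significant(self):
        a = self._table([0.1, 0.11, 0.12, 0.13, 0.14])
        b = self._table([0.5, 0.51, 0.52, 0.53, 0.54])
        for cmp_ in compare_texture_groups(a, b):
            assert cmp_.p_value < 0.05
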