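import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mutspectra.demography import build_basic_model
from mutspectra.mutation_model import MutationType
from mutspectra.power import (
    BinomialCount,
    analytic_power,
    min_scenario_power,
    pooled_proportion,
    power_surface,
    scenario_power,
    z_statistic,
)

TCC_T = MutationType("TCC", "T")


class TestPooledProportion:
    def test_hand_example(self):
        assert pooled_proportion(BinomialCount(10, 100), BinomialCount(20, 100)) == pytest.approx(0.15)

    def test_equal_proportions(self):
        assert pooled_proportion(BinomialCount(5, 50), BinomialCount(10, 100)) == pytest.approx(0.1)

    def test_zero_successes(self):
        assert pooled_proportion(BinomialCount(0, 50), BinomialCount(0, 50)) == 0.0

    def test_zero_trials_everywhere(self):
        with pytest.raises(ValueError):
            pooled_proportion(BinomialCount(0, 0), BinomialCount(0, 0))

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            pooled_proportion(BinomialCount(5, 3), BinomialCount(0, 1))


class TestZStatistic:
    def test_null_is_exactly_zero(self):
        assert z_statistic(BinomialCount(5, 100), BinomialCount(5, 100)) == 0.0

    def test_hand_value(self):
        """(10/100, 20/100): p*=0.15, Z = 0.1/sqrt(0.15*0.85*0.02)."""
        z = z_statistic(BinomialCount(10, 100), BinomialCount(20, 100))
        assert z == pytest.approx(0.1 / np.sqrt(0.15 * 0.85 * 0.02))
        assert z == pytest.approx(1.9803, abs=1e-4)

    def test_degenerate_pooled_proportion(self):
        with pytest.raises(ValueError):
            z_statistic(BinomialCount(0, 10), BinomialCount(0, 10))
        with pytest.raises(ValueError):
            z_statistic(BinomialCount(10, 10), BinomialCount(10, 10))

    @settings(deadline=None, max_examples=80)
    @given(
        x1=st.tuples(st.integers(0, 50), st.integers(1, 50)),
        x2=st.tuples(st.integers(0, 50), st.integers(1, 50)),
    )
    def test_antisymmetry(self, x1, x2):
        s1, n1 = x1
        s2, n2 = x2
        a = BinomialCount(min(s1, n1), n1)
        b = BinomialCount(min(s2, n2), n2)
        p = (a.successes + b.successes) / (a.trials + b.trials)
        if p in (0.0, 1.0):
            return
        assert z_statistic(a, b) == pytest.approx(-z_statistic(b, a))


class TestAnalyticPower:
    def test_size_under_the_null(self):
        assert analytic_power(0.1, 0.1, 500, 500, alpha=0.05) == pytest.approx(0.05, abs=1e-6)

    def test_consistency_limit(self):
        assert analytic_power(0.01, 0.02, 2_000_000, 2_000_000) > 0.9999

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            analytic_power(0.1, 0.2, 100, 100, alpha=0.0)
        with pytest.raises(ValueError):
            analytic_power(0.0, 0.2, 100, 100)

    def test_matches_statsmodels(self):
        """Independent cross-check of the closed form."""
        sm = pytest.importorskip("statsmodels.stats.proportion")
        for p1, p2, n1, n2 in [(0.01, 0.02, 800, 1200), (0.1, 0.15, 200, 300)]:
            mine = analytic_power(p1, p2, n1, n2, alpha=0.05)
            theirs = sm.power_proportions_2indep(
                diff=p1 - p2, prop2=p2, nobs1=n1, ratio=n2 / n1,
                alpha=0.05, alternative="two-sided",
            ).power
            assert mine == pytest.approx(theirs, abs=0.01)

    def test_matches_monte_carlo_rejection_rate(self):
        """Power formula vs direct simulation of the pooled Z test."""
        rng = np.random.default_rng(97)
        p1, p2, n1, n2, R = 0.010, 0.018, 1500, 2500, 100_000
        x1 = rng.binomial(n1, p1, R)
        x2 = rng.binomial(n2, p2, R)
        ps = (x1 + x2) / (n1 + n2)
        ok = (ps > 0) & (ps < 1)
        z = (x2[ok] / n2 - x1[ok] / n1) / np.sqrt(ps[ok] * (1 - ps[ok]) * (1 / n1 + 1 / n2))
        mc = np.mean(np.abs(z) > stats.norm.ppf(0.975))
        se = np.sqrt(mc * (1 - mc) / R)
        assert abs(analytic_power(p1, p2, n1, n2) - mc) < 4 * se + 0.005

    def test_monotone_in_fold_and_sample_size(self):
        c = 96
        powers_fold = [
            analytic_power(1 / c, f / (c - 1 + f), 1000, 1000) for f in (1.2, 1.5, 2.0)
        ]
        assert powers_fold == sorted(powers_fold)
        powers_n = [analytic_power(1 / c, 2 / (c + 1), n, n) for n in (200, 800, 3200)]
        assert powers_n == sorted(powers_n)


@pytest.fixture(scope="module")
def model():
    return build_basic_model("constant")


class TestScenarioPower:
    def test_null_fold_power_is_alpha(self, model):
        """fold = 1: expected-mode power equals alpha exactly (both
        populations share the baseline proportions)."""
        res = scenario_power(
            model, ("ancestral", "derived"), TCC_T, 1.0, 10, 10,
            region_length=100_000, window_length=50_000, replicates=3,
            seed=1, mode="expected",
        )
        for r in res:
            assert r.power == pytest.approx(0.05, abs=1e-9)

    def test_power_increases_with_fold(self, model):
        powers = {}
        for fold in (1.2, 2.0):
            res = scenario_power(
                model, ("ancestral", "derived"), TCC_T, fold, 20, 20,
                region_length=400_000, window_length=50_000, replicates=4,
                seed=3, mode="expected",
            )
            powers[fold] = min_scenario_power(res)
        assert powers[2.0] > powers[1.2]

    def test_result_metadata(self, model):
        res = scenario_power(
            model, ("ancestral", "derived"), TCC_T, 1.5, 5, 8,
            region_length=100_000, window_length=50_000, replicates=2, seed=5,
        )
        assert [r.scenario for r in res] == ["shift_in_pop1", "shift_in_pop2"]
        assert all(r.n1 == 5 and r.n2 == 8 and 0 <= r.power <= 1 for r in res)


class TestPowerSurface:
    def test_grid_shape(self):
        model = build_basic_model("constant")
        df = power_surface(
            model, ("ancestral", "derived"), TCC_T,
            folds=[1.0, 1.5, 2.0], sizes=[2, 10], replicates=2,
            region_length=100_000, window_length=50_000, seed=7,
        )
        assert len(df) == 3 * 2 * 2  # folds x sizes x scenarios
        assert df["power"].between(0, 1).all()

    def test_minimum_size_is_two(self):
        model = build_basic_model("constant")
        with pytest.raises(ValueError):
            power_surface(model, ("ancestral", "derived"), TCC_T, [1.5], [1], seed=0)

    def test_shared_baseline_matches_per_fold_simulation(self):
        """The expected-mode fast path (baseline simulations shared across
        folds) agrees with fully per-fold simulation: with a renormalized
        shift, trial counts are distributionally fold-invariant."""
        model = build_basic_model("constant")
        surf = power_surface(
            model, ("ancestral", "derived"), TCC_T,
            folds=[2.0], sizes=[20], replicates=12,
            region_length=400_000, window_length=50_000, seed=11,
        )
        res = scenario_power(
            model, ("ancestral", "derived"), TCC_T, 2.0, 20, 20,
            region_length=400_000, window_length=50_000, replicates=12,
            seed=13, mode="expected",
        )
        direct = {r.scenario: r.power for r in res}
        for _, row in surf.iterrows():
            assert row["power"] == pytest.approx(direct[row["scenario"]], abs=0.12)
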