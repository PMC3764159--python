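import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from smallholder.experiments import (
    DEFAULT_DENSITIES,
    DEFAULT_MI_LEVELS,
    ExperimentGrid,
    cropping_frequency,
    detect_transitions,
    enumerate_grid,
    evenness_index,
    kruskal_wallis_pair,
    run_metrics,
    scheffe_rank_comparison,
)


class TestEnumerateGrid:
    def test_default_axes_give_100_combinations(self):
        assert len(enumerate_grid(ExperimentGrid())) == 100

    def test_single_point_grid(self):
        g = ExperimentGrid(densities=(64.0,), mi_levels=(0.5,), landscapes=("baseline",))
        assert len(enumerate_grid(g)) == 1

    def test_product_of_axis_lengths_no_duplicates(self):
        g = ExperimentGrid(densities=(16.0, 64.0), mi_levels=(0.2, 0.5, 0.8),
                           landscapes=("baseline", "neutral", "slope_only", "precip_only"))
        configs = enumerate_grid(g)
        assert len(configs) == 24
        keys = {(c.population_density, c.mi, c.landscape.slope_constraint_on,
                 c.landscape.precip_constraint_on) for c in configs}
        assert len(keys) == 24

    def test_empty_axis_rejected(self):
        with pytest.raises(ValueError):
            ExperimentGrid(densities=())

    def test_defaults_span_printed_ranges(self):
        assert DEFAULT_DENSITIES[0] == 16.0 and DEFAULT_DENSITIES[-1] == 144.0
        assert DEFAULT_MI_LEVELS == (0.20, 0.35, 0.50, 0.65, 0.80)


class TestCroppingFrequency:
    def test_always_and_never_cultivated(self):
        hist = np.zeros((10, 2, 1), dtype=bool)
        hist[:, 0, 0] = True
        freq = cropping_frequency(hist)
        assert freq[0, 0] == 100.0
        assert freq[1, 0] == 0.0

    def test_partial_window(self):
        hist = np.zeros((10, 1, 1), dtype=bool)
        hist[:5, 0, 0] = True
        assert cropping_frequency(hist)[0, 0] == 50.0

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            cropping_frequency(np.zeros((10, 1, 1), dtype=bool), slice(10, None))


class TestEvenness:
    def test_equal_shares_maximal(self):
        assert evenness_index([1, 1, 1, 1]) == pytest.approx(1.0)

    def test_single_activity_minimal(self):
        assert evenness_index([5, 0, 0, 0]) == 0.0

    def test_closed_form_value(self):
        assert evenness_index([0.7, 0.1, 0.1, 0.1]) == pytest.approx(0.6783, abs=1e-4)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            evenness_index([0, 0, 0, 0])

    @given(st.lists(st.floats(min_value=0.01, max_value=10), min_size=4, max_size=4))
    def test_permutation_invariant_and_bounded(self, shares):
        e = evenness_index(shares)
        assert 0.0 <= e <= 1.0 + 1e-12
        rng = np.random.default_rng(0)
        assert evenness_index(rng.permutation(shares)) == pytest.approx(e)

    @given(st.lists(st.floats(min_value=0.01, max_value=10), min_size=4, max_size=4))
    def test_uniquely_maximized_at_equal_shares(self, shares):
        if np.ptp(shares) > 1e-6:
            assert evenness_index(shares) < 1.0


class TestKruskalWallis:
    def test_identical_groups_give_zero(self):
        h, p = kruskal_wallis_pair([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_separated_groups(self):
        # ranks 1-3 vs 4-6: H = 12/(6*7) * (3*1.5^2 + 3*1.5^2) = 27/7
        h, p = kruskal_wallis_pair([1, 2, 3], [10, 11, 12])
        assert h == pytest.approx(27.0 / 7.0)

    def test_degenerate_all_identical(self):
        h, p = kruskal_wallis_pair([5.0, 5.0], [5.0, 5.0])
        assert (h, p) == (0.0, 1.0)

    def test_matches_reference_implementation_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            na, nb = rng.integers(2, 15, 2)
            # integer draws create ties, exercising the tie correction
            a = rng.integers(0, 8, na).astype(float)
            b = (rng.integers(0, 8, nb) + rng.integers(0, 3)).astype(float)
            if np.ptp(np.concatenate([a, b])) == 0:
                continue
            h, p = kruskal_wallis_pair(a, b)
            ref = stats.kruskal(a, b)
            assert h == pytest.approx(ref.statistic, abs=1e-8)
            assert p == pytest.approx(ref.pvalue, abs=1e-8)


class TestScheffe:
    def test_null_case_no_significance(self):
        rng = np.random.default_rng(1)
        levels = {mi: rng.normal(0, 1, 20) for mi in (0.2, 0.35, 0.5, 0.65)}
        res = scheffe_rank_comparison(levels, alpha=0.01)
        assert all(not c.significant for c in res.comparisons)
        assert all(c.ci_lo <= 0.0 <= c.ci_hi for c in res.comparisons)

    def test_antisymmetry_under_group_swap(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 15), rng.normal(1, 1, 15)
        r1 = scheffe_rank_comparison({0.2: a, 0.35: b})
        r2 = scheffe_rank_comparison({0.2: b, 0.35: a})
        c1, c2 = r1.comparisons[0], r2.comparisons[0]
        assert c1.estimate == pytest.approx(-c2.estimate)
        assert c1.ci_lo == pytest.approx(-c2.ci_hi)

    def test_single_shift_detected_against_permutation_oracle(self):
        """A level shift at one boundary is flagged there and only there, in
        agreement with a permutation test of the mean-rank difference."""
        rng = np.random.default_rng(3)
        levels = {
            0.20: rng.normal(0.0, 1.0, 20),
            0.35: rng.normal(0.0, 1.0, 20),
            0.50: rng.normal(4.0, 1.0, 20),
            0.65: rng.normal(4.0, 1.0, 20),
        }
        res = scheffe_rank_comparison(levels, alpha=0.01)
        flags = [c.significant for c in res.comparisons]
        assert flags == [False, True, False]

        # permutation oracle on the flagged boundary
        a, b = levels[0.35], levels[0.50]
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        obs = ranks[len(a):].mean() - ranks[:len(a)].mean()
        perm_rng = np.random.default_rng(4)
        count = 0
        n_perm = 10000
        for _ in range(n_perm):
            perm = perm_rng.permutation(ranks)
            count += abs(perm[len(a):].mean() - perm[:len(a)].mean()) >= abs(obs)
        assert count / n_perm < 0.01

    def test_degenerate_level_rejected(self):
        with pytest.raises(ValueError):
            scheffe_rank_comparison({0.2: np.array([1.0]), 0.35: np.array([1.0, 2.0])})


class TestDetectTransitions:
    @staticmethod
    def _metrics(shifts):
        """Metrics table over 5 MI levels with staged level shifts per variable."""
        rng = np.random.default_rng(5)
        rows = []
        for mi in DEFAULT_MI_LEVELS:
            for _ in range(20):
                row = {"mi": mi}
                for var, (boundary, size) in shifts.items():
                    base = size if mi >= boundary else 0.0
                    row[var] = base + rng.normal(0, 0.5)
                rows.append(row)
        return pd.DataFrame(rows)

    def test_no_shift_gives_empty_transition_list(self):
        table = self._metrics({v: (2.0, 0.0) for v in
                               ("pct_farm_labor", "pct_market_labor",
                                "surplus_ratio", "evenness")})
        out = detect_transitions(table)
        assert not out["significant"].any()

    def test_three_staged_shifts_recovered(self):
        table = self._metrics(
            {
                "pct_market_labor": (0.35, 8.0),
                "pct_farm_labor": (0.65, -8.0),
                "evenness": (0.50, 8.0),
                "surplus_ratio": (2.0, 0.0),
            }
        )
        out = detect_transitions(table)
        sig = out[out["significant"]]
        found = {(r.variable, r.mi_to) for r in sig.itertuples()}
        assert ("pct_market_labor", 0.35) in found
        assert ("pct_farm_labor", 0.65) in found
        assert ("evenness", 0.50) in found
        assert len(sig) == 3

    def test_direction_labels_follow_medians(self):
        table = self._metrics({"pct_market_labor": (0.35, 8.0),
                               "pct_farm_labor": (0.65, -8.0),
                               "evenness": (2.0, 0.0),
                               "surplus_ratio": (2.0, 0.0)})
        out = detect_transitions(table)
        sig = out[out["significant"]].set_index("variable")
        assert sig.loc["pct_market_labor", "direction"] == "increase"
        assert sig.loc["pct_farm_labor", "direction"] == "decrease"


class TestRunMetrics:
    def test_percentages_and_bounds(self, hill_result):
        m = run_metrics(hill_result)
        assert 0.0 <= m.cropping_frequency_mean <= 100.0
        assert 0.0 <= m.pct_farm_labor <= 100.0
        assert m.pct_farm_labor + m.pct_nonfarm_labor == pytest.approx(100.0)
        assert m.pct_market_labor <= m.pct_farm_labor
        assert 0.0 <= m.evenness <= 1.0
        assert m.total_production_kg > 0
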