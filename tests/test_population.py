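"""Population statistics against definition-level oracles: exact binomial
tail, Benjamini-Hochberg step-up, Fisher's exact test, one-way ANOVA, and
tuning-breadth histograms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from math import comb

import spikesel as ss
from spikesel.population import round_half_up_percent
from spikesel.types import CATEGORIES
from tests.conftest import counts_from_arrays


def binomial_tail_oracle(k, n, p):
    """Brute-force summation of the upper binomial tail."""
    return sum(comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1))


def bh_oracle(pvals):
    """Direct application of the step-up definition."""
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, m / rank * p[i])
        adj[i] = running_min
    return adj


class TestBinomialVsChance:
    def test_zero_significant_gives_one(self):
        assert ss.binomial_vs_chance(0, 100) == pytest.approx(1.0)

    def test_all_significant_closed_form(self):
        assert ss.binomial_vs_chance(3, 3) == pytest.approx(0.05**3)

    def test_matches_summation_oracle_to_12_decimals(self):
        assert ss.binomial_vs_chance(10, 100, 0.05) == pytest.approx(
            binomial_tail_oracle(10, 100, 0.05), abs=1e-12
        )

    def test_monotone_decreasing_in_n_significant(self):
        ps = [ss.binomial_vs_chance(k, 50) for k in range(0, 51)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_invalid_chance_rejected(self):
        with pytest.raises(ValueError):
            ss.binomial_vs_chance(1, 10, chance=0.0)


class TestBenjaminiHochberg:
    def test_hand_computed_stepup(self):
        np.testing.assert_allclose(
            ss.benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04] * 4
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(ss.benjamini_hochberg([0.3]), [0.3])

    def test_empty_input_empty_output(self):
        assert ss.benjamini_hochberg([]).size == 0

    def test_matches_definition_oracle_on_1000_random_vectors(self):
        rng = np.random.default_rng(8)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 11))
            np.testing.assert_allclose(
                ss.benjamini_hochberg(p), bh_oracle(p), atol=1e-12
            )

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=8)
    )
    def test_adjusted_never_below_raw_and_capped(self, pvals):
        adj = ss.benjamini_hochberg(pvals)
        assert (adj >= np.asarray(pvals) - 1e-12).all()
        assert (adj <= 1.0).all()


class TestAnovaRaceEffect:
    def test_separated_group_means_detected(self):
        c = counts_from_arrays(
            ["White"] * 2 + ["AmbiguousWhite"] * 2 + ["AmbiguousBlack"] * 2 + ["Black"] * 2,
            [2, 2, 2, 2, 2, 2, 8, 8],
            [0] * 8,
        )
        # zero within-group variance everywhere but distinct means: F infinite
        p, degenerate = ss.anova_race_effect(c)
        assert not degenerate
        assert p < 0.01

    def test_matches_direct_f_computation(self, selective_counts):
        p, degenerate = ss.anova_race_effect(selective_counts)
        from scipy import stats as sps

        groups = [
            selective_counts.loc[
                selective_counts["category"] == c, "response_count"
            ].to_numpy(float)
            for c in CATEGORIES
        ]
        assert p == pytest.approx(sps.f_oneway(*groups).pvalue)
        assert p < 1e-10

    def test_all_equal_observations_degenerate(self):
        c = counts_from_arrays(
            [c for c in CATEGORIES for _ in range(2)], [3] * 8, [3] * 8
        )
        p, degenerate = ss.anova_race_effect(c)
        assert degenerate and np.isnan(p)


class TestFisherCompare:
    def test_identical_fractions_give_one(self):
        assert ss.fisher_fraction_compare(5, 50, 5, 50) == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration(self):
        # Full enumeration oracle for the 2x2 table [[k1, n1-k1],[k2, n2-k2]]
        def fisher_oracle(k1, n1, k2, n2):
            total_k = k1 + k2
            denom = comb(n1 + n2, total_k)
            probs = {
                j: comb(n1, j) * comb(n2, total_k - j) / denom
                for j in range(max(0, total_k - n2), min(n1, total_k) + 1)
            }
            p_obs = probs[k1]
            return sum(p for p in probs.values() if p <= p_obs + 1e-12)

        for args in [(0, 10, 10, 10), (3, 12, 7, 15), (2, 8, 2, 8), (1, 30, 9, 25)]:
            assert ss.fisher_fraction_compare(*args) == pytest.approx(
                fisher_oracle(*args), abs=1e-10
            )

    def test_symmetric_in_group_order(self):
        assert ss.fisher_fraction_compare(3, 12, 7, 15) == pytest.approx(
            ss.fisher_fraction_compare(7, 15, 3, 12)
        )

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            ss.fisher_fraction_compare(5, 3, 1, 10)


class TestSummaries:
    def _selectivity_frame(self, breadths, area="A"):
        rows = []
        for i, b in enumerate(breadths):
            for j, cat in enumerate(CATEGORIES):
                rows.append(
                    {
                        "neuron_id": f"{area}{i}",
                        "area": area,
                        "category": cat,
                        "p": 0.01 if j < b else 0.9,
                        "significant": j < b,
                        "n_categories_coded": b,
                    }
                )
        return pd.DataFrame(rows)

    def test_breadth_histogram_all_nonselective(self):
        out = ss.tuning_breadth(self._selectivity_frame([0] * 12))
        zero = out[out["n_categories"] == 0]
        assert zero["percent"].iloc[0] == 100
        assert out["n_neurons"].sum() == 12

    def test_breadth_percentages_sum_to_100(self):
        out = ss.tuning_breadth(self._selectivity_frame([0, 0, 1, 1, 2, 4]))
        assert abs(out.groupby("area")["percent"].sum().iloc[0] - 100) <= 2

    def test_area_summary_counts_and_fdr(self):
        frame = pd.concat(
            [
                self._selectivity_frame([1] * 4 + [0] * 16, area="A"),
                self._selectivity_frame([0] * 20, area="H"),
            ]
        )
        out = ss.area_category_summary(frame, alpha=0.05, fdr_family="categories")
        assert len(out) == 8
        a_white = out[(out["area"] == "A") & (out["category"] == "White")].iloc[0]
        assert a_white["n_total"] == 20
        assert a_white["n_significant"] == 4
        assert a_white["percent"] == 20
        assert (out["adjusted_p"] >= out["binomial_p"] - 1e-12).all()

    def test_nan_pvalues_stay_in_denominator_not_numerator(self):
        frame = self._selectivity_frame([1, 0, 0])
        frame["significant"] = frame["significant"].astype(object)
        frame.loc[frame["neuron_id"] == "A2", "p"] = np.nan
        frame.loc[frame["neuron_id"] == "A2", "significant"] = np.nan
        out = ss.area_category_summary(frame)
        assert (out["n_total"] == 3).all()

    @pytest.mark.parametrize(
        "k,n,expected", [(28, 168, 17), (14, 164, 9), (1, 105, 1), (0, 105, 0), (1, 8, 13)]
    )
    def test_percent_rounding_half_up(self, k, n, expected):
        assert round_half_up_percent(k, n) == expected
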