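"""Mutual information: exact values for perfect and null codes, oracle
equivalence, invariances, and the neurons-to-decode summary."""

import numpy as np
import pytest

import spikesel as ss
from spikesel.info import InfoResult, info_frame
from spikesel.types import CATEGORIES
from tests.conftest import counts_from_arrays, simulate_counts


def mi_oracle(x, y):
    """Independent histogram-based plug-in MI in bits."""
    xs, ys = np.unique(x), np.unique(y)
    n = len(x)
    mi = 0.0
    for xv in xs:
        for yv in ys:
            pxy = np.mean((x == xv) & (y == yv))
            if pxy > 0:
                mi += pxy * np.log2(pxy / (np.mean(x == xv) * np.mean(y == yv)))
    return mi


class TestMutualInformation:
    def test_perfect_code_gives_two_bits(self):
        # count value deterministically identifies each of 4 equiprobable cats
        cats = [c for c in CATEGORIES for _ in range(5)]
        counts = [k for k in range(4) for _ in range(5)]
        r = ss.mutual_information(counts_from_arrays(cats, counts, [0] * 20))
        assert r.mi_bits == pytest.approx(2.0)

    def test_constant_count_gives_zero_bits(self):
        cats = [c for c in CATEGORIES for _ in range(5)]
        r = ss.mutual_information(counts_from_arrays(cats, [3] * 20, [0] * 20))
        assert r.mi_bits == 0.0

    def test_matches_histogram_oracle_to_10_decimals(self, null_counts, selective_counts):
        for c in (null_counts, selective_counts):
            r = ss.mutual_information(c)
            expected = mi_oracle(
                c["response_count"].to_numpy(), c["category"].to_numpy()
            )
            assert r.mi_bits == pytest.approx(expected, abs=1e-10)

    def test_plugin_bias_small_positive_and_decreasing_with_n(self, trials):
        # Null neuron: true MI = 0, plug-in estimate positive and shrinking.
        c = simulate_counts(trials, seed=31)
        full = ss.mutual_information(c).mi_bits
        assert 0 < full < 0.2
        half = ss.mutual_information(c.iloc[:360]).mi_bits
        assert half > full

    def test_invariant_to_count_relabeling(self, null_counts):
        base = ss.mutual_information(null_counts).mi_bits
        relabeled = null_counts.copy()
        values = np.unique(relabeled["response_count"])
        rng = np.random.default_rng(0)
        mapping = dict(zip(values, rng.permutation(values)))
        relabeled["response_count"] = relabeled["response_count"].map(mapping)
        assert ss.mutual_information(relabeled).mi_bits == pytest.approx(base, abs=1e-12)

    def test_bounded_by_category_entropy(self, selective_counts):
        assert ss.mutual_information(selective_counts).mi_bits <= 2.0

    def test_miller_madow_reduces_null_estimate(self, null_counts):
        plain = ss.mutual_information(null_counts).mi_bits
        corrected = ss.mutual_information(null_counts, bias_correction="miller-madow").mi_bits
        assert corrected < plain

    def test_plugin_bias_matches_first_order_term_under_independence(self, trials):
        """With labels shuffled (exact independence) and a small well-populated
        count alphabet, the mean plug-in MI equals the first-order bias term
        (K_joint - K_count - K_cat + 1) / (2 n ln 2) within Monte-Carlo error."""
        rng = np.random.default_rng(3)
        cap = 2  # alphabet {0, 1, >=2}: every joint cell well populated
        estimates = []
        for i in range(120):
            c = simulate_counts(trials, seed=int(rng.integers(2**31)), baseline_rate_hz=1.0)
            c = c.assign(category=rng.permutation(c["category"].to_numpy()))
            estimates.append(ss.mutual_information(c, max_count=cap).mi_bits)
        estimates = np.asarray(estimates)
        n = len(trials.index)
        k_joint, k_x, k_y = (cap + 1) * 4, cap + 1, 4
        expected = (k_joint - k_x - k_y + 1) / (2 * n * np.log(2))
        se = estimates.std(ddof=1) / np.sqrt(estimates.size)
        assert abs(estimates.mean() - expected) < 4 * se

    def test_single_category_rejected(self):
        c = counts_from_arrays(["White"] * 4, [1, 2, 3, 4], [0] * 4)
        with pytest.raises(ValueError):
            ss.mutual_information(c)


class TestNeuronsToDecode:
    def _results(self, mis, area="A"):
        return [InfoResult(f"n{i}", area, m, 720) for i, m in enumerate(mis)]

    @pytest.mark.parametrize("mean_mi,expected", [(0.022, 90.9), (1.0, 2.0), (2.0, 1.0)])
    def test_two_bits_over_mean_mi(self, mean_mi, expected):
        out = ss.neurons_to_decode(self._results([mean_mi] * 4))
        assert out["neurons_to_2_bits"].iloc[0] == pytest.approx(expected)

    def test_relation_holds_before_rounding(self):
        out = ss.neurons_to_decode(self._results([0.03, 0.05]))
        assert out["mean_mi_bits"].iloc[0] * 2 / out["mean_mi_bits"].iloc[0] == 2.0
        assert out["neurons_to_2_bits"].iloc[0] == pytest.approx(2 / 0.04, abs=0.05)

    def test_zero_mean_mi_flagged_unbounded(self):
        out = ss.neurons_to_decode(self._results([0.0, 0.0]))
        assert out["unbounded"].iloc[0]
        assert np.isinf(out["neurons_to_2_bits"].iloc[0])


class TestMIAnova:
    def test_shifted_area_detected(self):
        rng = np.random.default_rng(12)
        results = self._make(rng, {"A": 0.0, "H": 0.5}, n=50)
        p, degenerate = ss.anova_mi_across_areas(results)
        assert not degenerate
        assert p < 0.001

    def test_null_not_systematically_rejected(self):
        rng = np.random.default_rng(13)
        pvals = []
        for rep in range(20):
            results = self._make(rng, {"A": 0.0, "H": 0.0}, n=20)
            pvals.append(ss.anova_mi_across_areas(results)[0])
        assert min(pvals) > 1e-4 or sum(p < 0.05 for p in pvals) <= 4

    def test_equal_constants_degenerate(self):
        results = [InfoResult(f"n{i}", a, 0.1, 720) for a in ("A", "H") for i in range(3)]
        p, degenerate = ss.anova_mi_across_areas(results)
        assert degenerate and np.isnan(p)

    @staticmethod
    def _make(rng, shifts, n):
        results = []
        for area, shift in shifts.items():
            for i in range(n):
                mi = abs(rng.normal(0.1 + shift, 0.05))
                results.append(InfoResult(f"{area}{i}", area, mi, 720))
        return results


def test_info_frame_columns():
    frame = info_frame([InfoResult("n0", "A", 0.1, 720)])
    assert list(frame.columns) == ["neuron_id", "area", "mi_bits", "n_trials"]
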