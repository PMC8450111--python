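"""Focus/axis summaries, the in-paper arithmetic helpers, tetrad scoring,
and the two significance tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from meicoc.metrics import (
    conditional_fraction,
    expected_under_independence,
    missegregation_frequency,
    overlap_fraction,
    significance_stars,
    summarize_nuclei,
    two_proportion_z,
    welch_t,
    zero_focus_frequencies,
)
from meicoc.simulate import SimulationConfig, TetradPattern, simulate_focus_dataset

from conftest import SEED, make_chrom


def tetrad(colors, tid="t0"):
    return TetradPattern(tetrad_id=tid, spore_colors=tuple(colors))


class TestNucleusSummaries:
    def test_hand_arithmetic(self):
        chroms = [
            make_chrom([0.2, 0.9, 1.7], axis_length=2.0, chrom="c0"),
            make_chrom([], axis_length=1.0, chrom="c1"),
        ]
        (s,) = summarize_nuclei(chroms)
        assert s.total_foci == 3
        assert s.total_axis_length == 3.0
        assert s.foci_per_micron == 1.0
        assert s.has_focusless_chromosome

    def test_zero_focus_single_chromosome(self):
        (s,) = summarize_nuclei([make_chrom([], axis_length=2.0)])
        assert s.foci_per_micron == 0.0
        assert s.has_focusless_chromosome

    def test_totals_conserve_focus_count(self):
        cfg = SimulationConfig(
            shape=1.0, mean_spacing=0.5, axis_length_mean=3.0,
            n_nuclei=50, chromosomes_per_nucleus=3, seed=SEED,
        )
        chroms = simulate_focus_dataset(cfg)
        summaries = summarize_nuclei(chroms)
        assert sum(s.total_foci for s in summaries) == sum(c.n_foci for c in chroms)

    def test_density_invariant_under_proportional_rescale(self):
        chroms = [make_chrom([0.5, 1.5], axis_length=2.0)]
        scaled = [make_chrom([1.0, 3.0], axis_length=4.0)]
        a = summarize_nuclei(chroms)[0].foci_per_micron
        b = summarize_nuclei(scaled)[0].foci_per_micron
        assert b == a / 2  # density scales inversely; counts unchanged
        assert summarize_nuclei(chroms)[0].total_foci == summarize_nuclei(scaled)[0].total_foci

    def test_duplicate_chromosome_rejected(self):
        chroms = [make_chrom([0.5]), make_chrom([1.0])]
        with pytest.raises(ValueError, match="duplicate"):
            summarize_nuclei(chroms)


class TestZeroFocusFrequencies:
    def test_enumerated_example(self):
        chroms = [
            make_chrom([0.5], chrom="c0"),
            make_chrom([], chrom="c1"),
        ]
        per_chrom, per_nucleus = zero_focus_frequencies(chroms)
        assert per_chrom == 0.5
        assert per_nucleus == 1.0

    def test_no_empty_chromosomes(self):
        chroms = [make_chrom([0.5], nucleus=f"n{i}") for i in range(4)]
        assert zero_focus_frequencies(chroms) == (0.0, 0.0)

    def test_poisson_zero_class_matches_analytic_value(self):
        cfg = SimulationConfig(
            shape=1.0, mean_spacing=1.0, axis_length_mean=3.0, n_nuclei=20_000, seed=SEED
        )
        per_chrom, _ = zero_focus_frequencies(simulate_focus_dataset(cfg))
        p0 = np.exp(-3.0)
        assert per_chrom == pytest.approx(p0, abs=3 * np.sqrt(p0 * (1 - p0) / 20_000))


class TestSmallArithmetic:
    def test_independence_expectations(self):
        assert expected_under_independence(0.82, 0.58) == pytest.approx(0.4756)
        assert expected_under_independence(0.90, 0.57) == pytest.approx(0.513)
        assert expected_under_independence(1.0, 0.37) == 0.37

    @settings(derandomize=True, max_examples=50)
    @given(a=st.floats(0, 1), b=st.floats(0, 1))
    def test_independence_commutative_and_bounded(self, a, b):
        assert expected_under_independence(a, b) == expected_under_independence(b, a)
        assert expected_under_independence(a, b) <= min(a, b) + 1e-15

    def test_independence_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            expected_under_independence(1.2, 0.5)

    def test_conditional_fraction(self):
        assert conditional_fraction(26, 75) == pytest.approx(34.6667, abs=1e-3)
        assert round(conditional_fraction(26, 75)) == 35
        assert conditional_fraction(42.0, 42.0) == 100.0
        assert conditional_fraction(0.0, 10.0) == 0.0
        with pytest.raises(ValueError):
            conditional_fraction(5.0, 0.0)

    def test_overlap_fraction(self):
        assert overlap_fraction(112, 3281) == pytest.approx(3.41, abs=0.005)
        assert overlap_fraction(4948, 5100) == pytest.approx(97.02, abs=0.005)
        assert overlap_fraction(0, 50) == 0.0
        with pytest.raises(ValueError):
            overlap_fraction(5, 4)


class TestMissegregation:
    def test_enumerated_frequency(self):
        tetrads = [tetrad("YYRR", f"t{i}") for i in range(99)]
        tetrads.append(tetrad("YRRR", "t99"))
        freq, n_scored, n_excluded = missegregation_frequency(tetrads)
        assert freq == pytest.approx(0.01)
        assert (n_scored, n_excluded) == (100, 0)

    def test_all_dark_is_an_error(self):
        with pytest.raises(ValueError, match="scoreable"):
            missegregation_frequency([tetrad("NNNN")])

    def test_dark_tetrads_never_enter_denominator(self):
        base = [tetrad("YYRR", f"t{i}") for i in range(9)] + [tetrad("YYYR", "t9")]
        with_dark = base + [tetrad("NNNN", f"d{i}") for i in range(5)]
        f1, n1, e1 = missegregation_frequency(base)
        f2, n2, e2 = missegregation_frequency(with_dark)
        assert (f1, n1) == (f2, n2)
        assert (e1, e2) == (0, 5)

    def test_partial_fluorescence_counts_as_missegregated(self):
        tetrads = [tetrad("YYRR"), tetrad("YRNN", "t1")]
        freq, n_scored, _ = missegregation_frequency(tetrads)
        assert freq == 0.5
        assert n_scored == 2


class TestTwoProportionZ:
    def test_equal_proportions_give_z_zero(self):
        res = two_proportion_z(5, 50, 10, 100)
        assert res.test_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_pooled_formula_oracle(self):
        x1, n1, x2, n2 = 15, 815, 39, 777
        res = two_proportion_z(x1, n1, x2, n2)
        p1, p2, pp = x1 / n1, x2 / n2, (x1 + x2) / (n1 + n2)
        z = (p1 - p2) / np.sqrt(pp * (1 - pp) * (1 / n1 + 1 / n2))
        assert res.test_statistic == pytest.approx(z, rel=1e-10)
        assert res.p_value == pytest.approx(2 * norm.sf(abs(z)), rel=1e-10)
        assert res.p_value < 0.001
        assert significance_stars(res.p_value) == "***"

    def test_single_observation_no_crash(self):
        res = two_proportion_z(0, 1, 1, 1)
        assert res.p_value > 0.15
        assert np.isfinite(res.test_statistic)

    def test_degenerate_pooled_proportion_flagged(self):
        res = two_proportion_z(0, 10, 0, 20)
        assert res.flagged
        assert np.isnan(res.test_statistic)


class TestWelchT:
    def test_identical_samples(self):
        res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.test_statistic == 0.0
        assert res.p_value == 1.0

    def test_shifted_gaussians_highly_significant(self):
        rng = np.random.default_rng(SEED)
        a = rng.normal(0.0, 1.0, 200)
        b = rng.normal(1.0, 1.0, 200)
        res = welch_t(a, b)
        assert res.p_value < 1e-10
        assert significance_stars(res.p_value) == "***"
        assert res.ratio_b_over_a == pytest.approx(b.mean() / a.mean())

    def test_zero_variance_equal_means_by_convention(self):
        res = welch_t([2.0, 2.0], [2.0, 2.0])
        assert res.flagged
        assert res.p_value == 1.0

    def test_size_one_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])


def test_significance_star_thresholds():
    assert significance_stars(0.05) == "n.s."
    assert significance_stars(0.049) == "*"
    assert significance_stars(0.009) == "**"
    assert significance_stars(0.0009) == "***"
    with pytest.raises(ValueError):
        significance_stars(1.5)
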