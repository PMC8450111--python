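"""Unit and property tests of the CoC machinery and the gamma fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from meicoc.interference import (
    EstimationError,
    IntervalSpec,
    assign_foci_to_intervals,
    coc_curve,
    coc_pairs,
    fit_gamma,
    gamma_shape_mle,
    inter_focus_distances,
    interval_profile,
)
from meicoc.simulate import SimulationConfig, simulate_focus_dataset

from conftest import SEED, make_chrom


def brute_force_coc_pairs(chroms, n_intervals):
    """Direct enumeration over chromosomes and interval pairs (test oracle)."""
    spec = IntervalSpec(n_intervals)
    sets = [set(assign_foci_to_intervals(ch, spec).tolist()) for ch in chroms]
    N = len(chroms)
    rows = {}
    for i in range(n_intervals):
        for j in range(i + 1, n_intervals):
            obs = sum(1 for s in sets if i in s and j in s) / N
            fi = sum(1 for s in sets if i in s) / N
            fj = sum(1 for s in sets if j in s) / N
            pred = fi * fj
            rows[(i, j)] = (obs, pred, obs / pred if pred > 0 else None)
    return rows


class TestIntervalAssignment:
    @pytest.mark.parametrize(
        "pos,axis,n,expected",
        [
            (0.0, 3.0, 30, 0),      # lower boundary
            (3.0, 3.0, 30, 29),     # closed top edge
            (1.0, 2.0, 30, 15),     # normalized 0.5 -> bin 15
            (0.099, 3.0, 30, 0),
            (0.1, 1.0, 10, 1),      # exact internal boundary goes right
        ],
    )
    def test_bin_arithmetic(self, pos, axis, n, expected):
        ch = make_chrom([pos], axis_length=axis)
        assert assign_foci_to_intervals(ch, IntervalSpec(n)).tolist() == [expected]

    def test_output_length_conserves_focus_count(self):
        cfg = SimulationConfig(
            shape=2.0, mean_spacing=0.5, axis_length_mean=3.0, n_nuclei=100, seed=SEED
        )
        chroms = simulate_focus_dataset(cfg)
        spec = IntervalSpec(30)
        total = sum(assign_foci_to_intervals(c, spec).size for c in chroms)
        assert total == sum(c.n_foci for c in chroms)


class TestIntervalProfile:
    def test_hand_enumerated_frequencies(self, four_chromosomes):
        prof = interval_profile(four_chromosomes, IntervalSpec(6))
        expected = np.zeros(6)
        expected[1] = expected[5] = 0.5
        assert np.allclose(prof.frequency, expected)
        assert prof.n_chromosomes == 4

    def test_presence_not_focus_count(self):
        ch = make_chrom([1.55, 1.7], axis_length=3.0)  # both foci in bin 3 of 6
        prof = interval_profile([ch], IntervalSpec(6))
        assert prof.frequency[3] == 1.0
        assert prof.frequency.sum() == 1.0

    def test_all_empty_chromosomes_give_zero_profile(self):
        chroms = [make_chrom([], nucleus=f"n{i}") for i in range(3)]
        assert interval_profile(chroms, IntervalSpec(6)).frequency.sum() == 0.0

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            interval_profile([], IntervalSpec(6))


class TestCoCPairs:
    def test_hand_enumerated_pair(self, four_chromosomes):
        pairs = coc_pairs(four_chromosomes, IntervalSpec(6)).set_index(
            ["interval_i", "interval_j"]
        )
        row = pairs.loc[(1, 5)]
        assert row["obs_dco"] == 0.25
        assert row["pred_dco"] == 0.25
        assert row["coc"] == 1.0
        assert row["distance"] == pytest.approx(4 / 6)

    def test_zero_observed_with_nonzero_marginals(self):
        chroms = [make_chrom([0.25], nucleus="n0"), make_chrom([2.75], nucleus="n1")]
        pairs = coc_pairs(chroms, IntervalSpec(6)).set_index(["interval_i", "interval_j"])
        assert pairs.loc[(0, 5), "coc"] == 0.0

    def test_zero_marginal_flagged_undefined(self, four_chromosomes):
        pairs = coc_pairs(four_chromosomes, IntervalSpec(6))
        undef = pairs[~pairs["defined"]]
        assert len(undef) > 0
        assert undef["coc"].isna().all()
        assert (undef["pred_dco"] == 0).all()

    def test_pair_count_is_n_choose_2(self, four_chromosomes):
        assert len(coc_pairs(four_chromosomes, IntervalSpec(6))) == 15

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        data=st.lists(
            st.lists(st.floats(0.0, 1.0, width=32), max_size=5),
            min_size=1,
            max_size=10,
        ),
        n_intervals=st.integers(2, 6),
    )
    def test_matches_brute_force_enumeration(self, data, n_intervals):
        chroms = [
            make_chrom(np.sort(np.array(p)) * 2.0, axis_length=2.0, nucleus=f"n{i}")
            for i, p in enumerate(data)
        ]
        got = coc_pairs(chroms, IntervalSpec(n_intervals))
        oracle = brute_force_coc_pairs(chroms, n_intervals)
        for row in got.itertuples():
            obs, pred, coc = oracle[(row.interval_i, row.interval_j)]
            assert row.obs_dco == obs
            assert row.pred_dco == pred
            if coc is None:
                assert not row.defined
            else:
                assert row.coc == coc

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        data=st.lists(
            st.lists(st.floats(0.0, 1.0, width=32), max_size=5), min_size=1, max_size=8
        ),
        scale=st.sampled_from([0.25, 0.5, 2.0, 4.0]),
    )
    def test_scale_invariance(self, data, scale):
        # rescaling positions and axis by a power of two changes nothing
        base = [
            make_chrom(np.sort(np.array(p)), axis_length=1.0, nucleus=f"n{i}")
            for i, p in enumerate(data)
        ]
        scaled = [
            make_chrom(c.focus_positions * scale, axis_length=scale, nucleus=c.nucleus_id)
            for c in base
        ]
        a = coc_pairs(base, IntervalSpec(5))
        b = coc_pairs(scaled, IntervalSpec(5))
        assert a.equals(b)


class TestCoCCurve:
    def test_single_pair_curve(self):
        chroms = [
            make_chrom([0.25, 2.75], nucleus="n0"),
            make_chrom([0.25], nucleus="n1"),
            make_chrom([2.75], nucleus="n2"),
        ]
        pairs = coc_pairs(chroms, IntervalSpec(6))
        curve = coc_curve(pairs)
        one = curve[np.isclose(curve["distance"], 5 / 6)]
        assert len(one) == 1
        assert one["n_pairs"].iloc[0] == 1

    def test_replicates_produce_se(self):
        frames = []
        for rep in range(3):
            cfg = SimulationConfig(
                shape=1.0, mean_spacing=0.5, axis_length_mean=3.0,
                n_nuclei=300, seed=SEED + rep,
            )
            p = coc_pairs(simulate_focus_dataset(cfg), IntervalSpec(10))
            p["replicate"] = rep
            frames.append(p)
        import pandas as pd

        curve = coc_curve(pd.concat(frames, ignore_index=True))
        assert curve["se"].notna().all()
        assert (curve["se"] >= 0).all()

    def test_all_undefined_is_an_error(self):
        chroms = [make_chrom([], nucleus=f"n{i}") for i in range(3)]
        with pytest.raises(EstimationError):
            coc_curve(coc_pairs(chroms, IntervalSpec(6)))


class TestGammaFit:
    def test_exponential_distances_give_shape_one(self):
        rng = np.random.default_rng(SEED)
        x = rng.exponential(1.0, size=5000)
        k, theta = gamma_shape_mle(x)
        assert k == pytest.approx(1.0, rel=0.05)
        assert k * theta == pytest.approx(x.mean(), rel=1e-9)

    def test_mle_matches_scipy_reference(self):
        rng = np.random.default_rng(SEED + 1)
        x = rng.gamma(3.5, 0.4, size=2000)
        k, theta = gamma_shape_mle(x)
        k_ref, _, theta_ref = stats.gamma.fit(x, floc=0)
        assert k == pytest.approx(k_ref, rel=1e-4)
        assert theta == pytest.approx(theta_ref, rel=1e-4)

    def test_renewal_simulation_recovers_shape_within_ten_percent(self):
        cfg = SimulationConfig(
            shape=5.0, mean_spacing=0.5, axis_length_mean=3.0, n_nuclei=2000, seed=SEED
        )
        fit = fit_gamma(simulate_focus_dataset(cfg), n_boot=200, seed=SEED)
        assert fit.shape == pytest.approx(5.0, rel=0.10)
        assert fit.shape_ci[0] <= fit.shape <= fit.shape_ci[1]

    def test_two_distances_fit_with_warning_matches_grid_oracle(self):
        chroms = [make_chrom([0.5, 1.0, 2.5], axis_length=3.0)]
        x = inter_focus_distances(chroms, normalized=False)
        assert x.tolist() == [0.5, 1.5]
        grid = np.geomspace(0.01, 100.0, 200_001)
        loglik = [stats.gamma.logpdf(x, g, scale=x.mean() / g).sum() for g in grid]
        k_grid = grid[int(np.argmax(loglik))]
        with pytest.warns(UserWarning, match="wide"):
            fit = fit_gamma(chroms, normalized=False, n_boot=50, seed=SEED)
        assert fit.shape == pytest.approx(k_grid, rel=1e-3)
        assert fit.n_distances == 2

    def test_normalized_and_micron_units_agree_for_fixed_axis(self):
        # with a constant axis length, normalization is a pure rescale:
        # the shape is identical and the scale differs by the axis length
        cfg = SimulationConfig(
            shape=2.0, mean_spacing=0.5, axis_length_mean=3.0, n_nuclei=500, seed=SEED
        )
        ds = simulate_focus_dataset(cfg)
        a = fit_gamma(ds, normalized=True, n_boot=10, seed=0)
        b = fit_gamma(ds, normalized=False, n_boot=10, seed=0)
        assert a.shape == pytest.approx(b.shape, rel=1e-9)
        assert b.scale == pytest.approx(a.scale * 3.0, rel=1e-9)

    def test_no_distances_is_an_error(self):
        with pytest.raises(EstimationError):
            fit_gamma([make_chrom([1.0])])

    def test_identical_distances_is_an_error(self):
        with pytest.raises(EstimationError):
            gamma_shape_mle(np.array([0.5, 0.5, 0.5]))


class TestMonotoneInterference:
    def test_short_distance_coc_decreases_and_shape_increases_with_true_shape(self):
        short_cocs, shapes = [], []
        for nu in (1.0, 2.0, 5.0, 10.0):
            cfg = SimulationConfig(
                shape=nu, mean_spacing=0.5, axis_length_mean=3.0,
                n_nuclei=2000, seed=SEED,
            )
            ds = simulate_focus_dataset(cfg)
            curve = coc_curve(coc_pairs(ds, IntervalSpec(30)))
            short_cocs.append(curve["mean_coc"].iloc[0])
            shapes.append(fit_gamma(ds, n_boot=10, seed=0).shape)
        assert all(a > b for a, b in zip(short_cocs, short_cocs[1:]))
        assert all(a < b for a, b in zip(shapes, shapes[1:]))
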