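"""Reweighted profiles, comparison statistics, and their hand-computed oracles."""

import math

import numpy as np
import pandas as pd
import pytest

import fisstkit as fk
from fisstkit.analysis import (
    Profile2D,
    block_standard_error,
    kish_effective_sample_size,
    moving_average,
    profile_from_probabilities,
    rmse_convergence,
)
from fisstkit.fisst import FisstState, ForceGrid
from fisstkit.trajectory import TrajectoryStore


def make_traj(q, beta=1.0, log_denom=None, extra=None):
    frame = pd.DataFrame({"step": np.arange(len(q)), "time": np.arange(len(q), dtype=float), "Q": q})
    frame["U"] = 0.0
    frame["bias_energy"] = 0.0
    if log_denom is not None:
        frame["log_denom"] = log_denom
    for k, v in (extra or {}).items():
        frame[k] = v
    return TrajectoryStore(frame, {"beta": beta})


def fisst_harmonic_traj(seed=61, n_steps=50000, f_min=-2.0, f_max=2.0):
    system = fk.make_harmonic_cv_system(1.0, 0.0)
    state = FisstState(ForceGrid(f_min, f_max, 121), beta=1.0, update_interval=500)
    st = fk.IntegratorSettings(timestep=0.2, friction=0.5, beta=1.0, seed=seed, n_steps=n_steps)
    return fk.simulate(system, st, fk.FisstBias(state)), state


class TestReweightedHistogram:
    def test_single_occupied_bin_for_constant_cv(self):
        traj = make_traj(np.full(100, 0.5), log_denom=np.zeros(100))
        prof = fk.reweighted_histogram(traj, 0.0, np.array([0.0, 0.4, 0.6, 1.0]))
        assert prof.probability.tolist() == [0.0, 1.0, 0.0]
        assert prof.free_energy[1] == 0.0
        assert np.isnan(prof.free_energy[0]) and np.isnan(prof.free_energy[2])

    def test_degenerate_grid_is_plain_histogram(self):
        rng = np.random.default_rng(2)
        q = rng.normal(0, 1, 2000)
        state = FisstState(ForceGrid(0.0, 0.0, 1), beta=1.0)
        traj = make_traj(q, log_denom=np.array([state.log_denominator(v) for v in q]))
        edges = np.linspace(-4, 4, 9)
        prof = fk.reweighted_histogram(traj, 0.0, edges, state)
        counts, _ = np.histogram(q, edges)
        assert np.allclose(prof.probability, counts / counts.sum())

    def test_matches_gaussian_closed_form(self, harmonic_oracle):
        """Force-tempered harmonic run reweighted to F=1: histogram of N(1, 1)."""
        traj, state = fisst_harmonic_traj()
        edges = 1.0 + np.array([-8.0, -1.5, -0.6, 0.0, 0.6, 1.5, 8.0])
        prof = fk.reweighted_histogram(traj, 1.0, edges, state)
        exact = harmonic_oracle.bin_probabilities(edges, 1.0)
        assert fk.jensen_shannon_distance(prof.probability, exact) < 0.02
        assert prof.effective_sample_size > 0.25 * len(traj)

    def test_rejects_empty_trajectory_and_bad_edges(self):
        traj = make_traj(np.array([1.0]), log_denom=np.array([0.0]))
        with pytest.raises(ValueError):
            fk.reweighted_histogram(TrajectoryStore(traj.frame.iloc[:0], traj.meta), 0.0, np.array([0, 1, 2.0]))
        with pytest.raises(ValueError):
            fk.reweighted_histogram(traj, 0.0, np.array([1.0, 0.0]))


class TestForceExtension:
    def test_harmonic_curve_is_linear(self):
        """<Q>(F) = F/k across the grid for the harmonic fixture."""
        traj, state = fisst_harmonic_traj(seed=67)
        forces = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        curve = fk.force_extension_curve(traj, forces, state)
        for _, row in curve.iterrows():
            assert abs(row["mean"] - row["force"]) < 3 * row["block_se"]

    def test_mean_extension_nondecreasing_in_force(self):
        traj, state = fisst_harmonic_traj(seed=71)
        curve = fk.force_extension_curve(traj, np.linspace(-2, 2, 9), state)
        means = curve["mean"].to_numpy()
        ses = curve["block_se"].to_numpy()
        assert np.all(np.diff(means) > -3 * (ses[:-1] + ses[1:]))

    def test_spread_column_is_one_third_std(self):
        traj, _ = fisst_harmonic_traj(seed=73, n_steps=2000)
        curve = fk.force_extension_curve(traj, [0.0])
        assert curve.loc[0, "std_over_3"] == pytest.approx(curve.loc[0, "std"] / 3.0)


class TestJensenShannon:
    def test_identical_distributions_have_zero_distance(self):
        p = np.array([0.2, 0.3, 0.5])
        assert fk.jensen_shannon_distance(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_have_distance_one(self):
        assert fk.jensen_shannon_distance(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        """p=(1,0), q=(1/2,1/2): m=(3/4,1/4); JS = 1 - (3/4) log2 3 + ... worked
        by hand: KL(p||m) = log2(4/3), KL(q||m) = 1/2 log2(2/3) + 1/2 log2 2;
        distance = sqrt((KL1+KL2)/2) = 0.5579230452841438."""
        d = fk.jensen_shannon_distance(np.array([1.0, 0.0]), np.array([0.5, 0.5]))
        kl1 = math.log2(4.0 / 3.0)
        kl2 = 0.5 * math.log2(2.0 / 3.0) + 0.5 * 1.0
        assert d == pytest.approx(math.sqrt(0.5 * (kl1 + kl2)), abs=1e-12)
        assert d == pytest.approx(0.5579230452841438, abs=1e-12)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            p = rng.dirichlet(np.ones(6))
            q = rng.dirichlet(np.ones(6))
            d = fk.jensen_shannon_distance(p, q)
            assert 0.0 <= d <= 1.0
            assert d == pytest.approx(fk.jensen_shannon_distance(q, p), abs=1e-12)

    def test_rejects_mismatched_or_unnormalized(self):
        with pytest.raises(ValueError):
            fk.jensen_shannon_distance(np.array([1.0, 0.0]), np.array([1.0, 0.0, 0.0]))
        with pytest.raises(ValueError):
            fk.jensen_shannon_distance(np.array([0.7, 0.7]), np.array([0.5, 0.5]))


class TestSpearman:
    def _profile(self, free_energy, edges=None):
        n = len(free_energy)
        edges = np.arange(n + 1, dtype=float) if edges is None else edges
        p = np.exp(-np.nan_to_num(free_energy, nan=np.inf))
        return fk.ReweightedProfile(edges, p / p.sum(), np.asarray(free_energy, float), 0.0, n, 1.0)

    def test_self_correlation_is_one(self):
        a = self._profile(np.array([0.0, 1.0, 3.0, 2.0, 0.5]))
        assert fk.spearman_free_energy(a, a) == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        base = np.array([0.0, 1.0, 3.0, 2.0, 0.5])
        a = self._profile(base)
        b = self._profile(np.exp(base) - 1.0)
        assert fk.spearman_free_energy(a, b) == pytest.approx(1.0)

    def test_negation_gives_minus_one(self):
        base = np.array([0.0, 1.0, 3.0, 2.0, 0.5])
        a = self._profile(base)
        b = self._profile(base.max() - base)
        assert fk.spearman_free_energy(a, b) == pytest.approx(-1.0)

    def test_missing_bins_dropped_pairwise_and_minimum_enforced(self):
        a = self._profile(np.array([0.0, np.nan, 3.0, 2.0, 0.5]))
        b = self._profile(np.array([0.0, 1.0, np.nan, 2.0, 0.5]))
        assert fk.spearman_free_energy(a, b) == pytest.approx(1.0)
        c = self._profile(np.array([0.0, np.nan, np.nan, np.nan, 0.5]))
        with pytest.raises(ValueError, match="common bins"):
            fk.spearman_free_energy(c, a)

    def test_different_binnings_rejected(self):
        a = self._profile(np.zeros(4))
        b = self._profile(np.zeros(4), edges=np.arange(5, dtype=float) + 0.5)
        with pytest.raises(ValueError, match="binnings"):
            fk.spearman_free_energy(a, b)


class TestRmseBelowThreshold:
    def _profile(self, fe):
        fe = np.asarray(fe, float)
        edges = np.arange(len(fe) + 1, dtype=float)
        p = np.exp(-np.nan_to_num(fe, nan=np.inf))
        return fk.ReweightedProfile(edges, p / p.sum(), fe, 0.0, len(fe), 1.0)

    def test_identical_profiles_give_zero(self):
        a = self._profile([0.0, 1.0, 2.0])
        assert fk.rmse_below_threshold(a, a, 6.0).rmse == 0.0

    def test_hand_computed_value(self):
        a = self._profile([0.0, 1.3, 2.4])
        ref = self._profile([0.0, 1.0, 2.0])
        res = fk.rmse_below_threshold(a, ref, 6.0)
        assert res.rmse == pytest.approx(math.sqrt((0.0 + 0.09 + 0.16) / 3.0))
        assert res.n_missing == 0

    def test_cutoff_restricts_to_reference_region(self):
        a = self._profile([0.0, 1.0, 10.0])
        ref = self._profile([0.0, 1.0, 7.0])
        res = fk.rmse_below_threshold(a, ref, 6.0)
        assert res.n_bins == 2
        assert res.rmse == 0.0

    def test_missing_bins_counted_separately(self):
        a = self._profile([0.0, np.nan, 2.0])
        ref = self._profile([0.0, 1.0, 2.0])
        res = fk.rmse_below_threshold(a, ref, 6.0)
        assert res.n_missing == 1
        assert res.rmse == 0.0

    def test_no_bins_under_cutoff_is_an_error(self):
        a = self._profile([0.0, 1.0])
        ref = self._profile([7.0, 8.0])
        ref.free_energy[:] = [7.0, 8.0]
        with pytest.raises(ValueError, match="cutoff"):
            fk.rmse_below_threshold(a, ref, 6.0)


class TestReweighted2D:
    def test_constant_second_observable_collapses_to_1d(self):
        rng = np.random.default_rng(8)
        q = rng.normal(0, 1, 3000)
        traj = make_traj(q, log_denom=np.zeros_like(q), extra={"obs_y": np.full_like(q, 0.5)})
        ex = np.linspace(-4, 4, 9)
        ey = np.array([0.0, 1.0])
        p2 = fk.reweighted_2d_histogram(traj, "Q", "obs_y", 0.0, ex, ey)
        p1 = fk.reweighted_histogram(traj, 0.0, ex)
        assert np.allclose(p2.probability[:, 0], p1.probability)

    def test_marginalization_consistency(self):
        rng = np.random.default_rng(9)
        q = rng.normal(0, 1, 5000)
        y = rng.normal(0, 1, 5000)
        logd = 0.3 * q  # nontrivial per-frame weights
        traj = make_traj(q, log_denom=logd, extra={"obs_y": y})
        ex = np.linspace(-4, 4, 9)
        ey = np.linspace(-12, 12, 7)  # wide enough that no frame is dropped in y
        p2 = fk.reweighted_2d_histogram(traj, "Q", "obs_y", 1.0, ex, ey)
        p1 = fk.reweighted_histogram(traj, 1.0, ex)
        # frames outside the y-range would break exact agreement; keep all inside
        assert np.allclose(p2.probability.sum(axis=1), p1.probability, atol=1e-9)

    def test_independent_observables_factorize(self):
        rng = np.random.default_rng(10)
        q = rng.normal(0, 1, 60000)
        y = rng.normal(0, 1, 60000)
        traj = make_traj(q, log_denom=np.zeros_like(q), extra={"obs_y": y})
        ex = np.array([-8.0, -0.6, 0.0, 0.6, 8.0])
        p2 = fk.reweighted_2d_histogram(traj, "Q", "obs_y", 0.0, ex, ex)
        joint = p2.probability
        outer = joint.sum(axis=1)[:, None] * joint.sum(axis=0)[None, :]
        assert np.abs(joint - outer).max() < 0.01

    def test_unknown_observable_rejected(self):
        traj = make_traj(np.zeros(5), log_denom=np.zeros(5))
        with pytest.raises(KeyError):
            fk.reweighted_2d_histogram(traj, "Q", "missing", 0.0, np.array([0, 1.0]), np.array([0, 1.0]))


class TestHelpers:
    def test_kish_effective_sample_size(self):
        assert kish_effective_sample_size(np.ones(50)) == pytest.approx(50.0)
        w = np.zeros(10)
        w[0] = 3.0
        assert kish_effective_sample_size(w) == pytest.approx(1.0)

    def test_block_standard_error_uniform_weights(self):
        rng = np.random.default_rng(11)
        v = rng.normal(0, 1, 10000)
        se = block_standard_error(v)
        assert se == pytest.approx(1.0 / math.sqrt(10000), rel=0.8)

    def test_moving_average_smooths_endpoints(self):
        out = moving_average(np.array([4.0, 2.0, 0.0]), window=3)
        assert out == pytest.approx([3.0, 2.0, 1.0])

    def test_profile_free_energy_offset(self):
        prof = profile_from_probabilities(np.array([0.0, 1.0, 2.0]), np.array([0.8, 0.2]), beta=2.0, force=0.0)
        assert prof.free_energy.min() == 0.0
        assert prof.free_energy[1] == pytest.approx(-math.log(0.2 / 0.8) / 2.0)

    def test_rmse_convergence_frame(self):
        traj, state = fisst_harmonic_traj(seed=79, n_steps=5000)
        edges = np.linspace(-3.5, 3.5, 20)
        oracle = fk.oracle_for_system(fk.make_harmonic_cv_system(1.0, 0.0), 1.0, np.linspace(-9, 9, 20001))
        ref = oracle.pmf(edges, 0.0)
        conv = rmse_convergence(traj, ref, cutoff=6.0, n_windows=5)
        assert list(conv.columns) == ["frames", "fraction", "rmse", "n_missing"]
        assert len(conv) == 5
        assert conv["rmse"].iloc[-1] < 1.0
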