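"""Dynamics layer: overlap, locality ratio, force fields, Markov model,
density peaks, coarse graining, Bayesian bootstrap."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from morphodyn.dynamics import (
    MarkovStateModel,
    TransitionMatrix,
    assign_microstates,
    bayesian_bootstrap_ci,
    coarse_grain_states,
    estimate_transition_matrix,
    find_density_peaks,
    fit_microstates,
    force_field,
    histogram_on_grid,
    locality_ratio,
    make_shared_grid,
    mean_pairwise_overlap,
    overlap_coefficient,
    trajectory_log_likelihood,
)


class TestOverlap:
    def test_identical_distributions(self, rng):
        p = rng.random(50)
        p /= p.sum()
        assert overlap_coefficient(p, p) == pytest.approx(1.0)

    def test_disjoint_supports(self):
        p = np.array([0.5, 0.5, 0.0, 0.0])
        q = np.array([0.0, 0.0, 0.25, 0.75])
        assert overlap_coefficient(p, q) == 0.0

    def test_three_bin_hand_case(self):
        assert overlap_coefficient(
            np.array([0.5, 0.5, 0.0]), np.array([0.0, 0.5, 0.5])
        ) == pytest.approx(0.5)

    def test_mismatched_grids_raise(self):
        with pytest.raises(ValueError, match="same grid"):
            overlap_coefficient(np.ones(3) / 3, np.ones(4) / 4)

    @given(
        arrays(np.float64, 12, elements=st.floats(0.01, 10)),
        arrays(np.float64, 12, elements=st.floats(0.01, 10)),
    )
    def test_symmetric_and_bounded(self, a, b):
        p, q = a / a.sum(), b / b.sum()
        o = overlap_coefficient(p, q)
        assert 0.0 <= o <= 1.0 + 1e-12
        assert o == pytest.approx(overlap_coefficient(q, p))

    def test_mean_equals_hand_pair_enumeration(self, rng):
        coords = {
            "A": rng.normal(0, 1, (400, 2)),
            "B": rng.normal(1, 1, (400, 2)),
            "C": rng.normal(5, 1, (400, 2)),
        }
        mean, pairs = mean_pairwise_overlap(coords, bins=20)
        grid = make_shared_grid(np.vstack(list(coords.values())), bins=20)
        hand = []
        names = sorted(coords)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                hand.append(
                    overlap_coefficient(
                        histogram_on_grid(coords[a], grid),
                        histogram_on_grid(coords[b], grid),
                    )
                )
        assert mean == pytest.approx(np.mean(hand))
        assert len(pairs) == 3

    def test_identical_generators_high_overlap(self, rng):
        coords = {k: rng.normal(size=(20_000, 2)) for k in "AB"}
        mean, _ = mean_pairwise_overlap(coords, bins=20)
        assert mean > 0.9

    def test_empty_treatment_excluded_with_warning(self, rng):
        coords = {"A": rng.normal(size=(200, 2)), "B": rng.normal(size=(200, 2)),
                  "C": np.empty((0, 2))}
        with pytest.warns(UserWarning, match="excluded"):
            _, pairs = mean_pairwise_overlap(coords, bins=10)
        assert set(pairs) == {("A", "B")}


class TestLocalityRatio:
    def test_iid_positions_give_one(self, rng):
        trajs = [rng.normal(size=(101, 2)) for _ in range(100)]
        assert locality_ratio(trajs) == pytest.approx(1.0, abs=0.02)

    def test_frozen_trajectories_give_zero(self, rng):
        trajs = [np.tile(rng.normal(size=(1, 2)), (10, 1)) for _ in range(50)]
        assert locality_ratio(trajs) == 0.0

    def test_ar1_closed_form(self, rng):
        """Stationary AR(1): l = sqrt(1 - phi), cross-checked by simulation."""
        phi = 0.5
        trajs = []
        for _ in range(300):
            x = np.empty(200)
            x[0] = rng.normal(0, 1 / np.sqrt(1 - phi**2))
            for t in range(1, 200):
                x[t] = phi * x[t - 1] + rng.normal()
            trajs.append(x[:, None])
        assert locality_ratio(trajs) == pytest.approx(np.sqrt(1 - phi), rel=0.02)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="variance"):
            locality_ratio([np.zeros((5, 2))])


class TestForceField:
    def test_ou_drift_direction(self, rng):
        """Equilibrium OU: bin-mean displacement points toward the attractor
        and agrees with the analytic drift -phi*(x - mu) in >= 90% of bins."""
        a = 0.2
        x = np.zeros((500, 80, 2))
        x[:, 0] = rng.normal(0, 1, (500, 2))
        for t in range(1, 80):
            x[:, t] = x[:, t - 1] - a * x[:, t - 1] + rng.normal(0, np.sqrt(2 * a - a * a), (500, 2))
        grid = make_shared_grid(x.reshape(-1, 2), bins=8, pct=(5, 95))
        ff = force_field(list(x), grid, min_count=50)
        cx = 0.5 * (grid.edges[0][:-1] + grid.edges[0][1:])
        cy = 0.5 * (grid.edges[1][:-1] + grid.edges[1][1:])
        agree = total = 0
        for i in range(8):
            for j in range(8):
                v = ff.mean_displacement[i, j]
                if np.any(np.isnan(v)):
                    continue
                center = np.array([cx[i], cy[j]])
                if np.linalg.norm(center) < 0.3:
                    continue  # drift ~0 near the attractor; direction undefined
                total += 1
                agree += (v @ (-center)) > 0
        assert total > 10 and agree / total >= 0.90

    def test_random_walk_zero_drift(self, rng):
        steps = rng.normal(0, 1, (200, 100, 2))
        x = np.cumsum(steps, axis=1)
        grid = make_shared_grid(x.reshape(-1, 2), bins=5, pct=(10, 90))
        ff = force_field(list(x), grid, min_count=100)
        v = ff.mean_displacement
        occ = ff.occupancy
        ok = ~np.isnan(v[..., 0])
        # mean displacement within 3 SE of zero in nearly all occupied bins
        se = 1.0 / np.sqrt(occ[ok])
        frac_within = np.mean(np.abs(v[ok]) < 3 * se[:, None])
        assert frac_within > 0.9

    def test_low_occupancy_bins_undefined(self, rng):
        x = [rng.normal(size=(3, 2))]
        grid = make_shared_grid(x[0], bins=4, pct=(0, 100))
        ff = force_field(x, grid, min_count=10)
        assert np.all(np.isnan(ff.mean_displacement))


class TestMicrostates:
    def test_k_one_center_is_mean(self, rng):
        X = rng.normal(size=(50, 2))
        centers, labels = fit_microstates(X, k=1, seed=0)
        assert np.allclose(centers[0], X.mean(axis=0), atol=1e-8)
        assert np.all(labels == 0)

    def test_separable_blobs(self, rng):
        blobs = [rng.normal(loc, 0.2, (40, 2)) for loc in ((0, 0), (5, 0), (0, 5))]
        X = np.vstack(blobs)
        centers, labels = fit_microstates(X, k=3, seed=0)
        for i in range(3):
            assert len(np.unique(labels[40 * i : 40 * (i + 1)])) == 1

    def test_seeded_determinism(self, rng):
        X = rng.normal(size=(200, 2))
        c1, _ = fit_microstates(X, k=10, seed=3)
        c2, _ = fit_microstates(X, k=10, seed=3)
        assert np.array_equal(c1, c2)

    def test_too_few_points_raises(self, rng):
        with pytest.raises(ValueError):
            fit_microstates(rng.normal(size=(5, 2)), k=10)


class TestTransitionMatrix:
    def test_hand_counted_chain(self):
        tm = estimate_transition_matrix([np.array([0, 1, 0, 1])], k=2)
        assert np.array_equal(tm.counts, [[0, 2], [1, 0]])
        assert np.array_equal(tm.probabilities, [[0, 1], [1, 0]])

    def test_empty_row_flagged(self):
        tm = estimate_transition_matrix([np.array([0, 1, 1])], k=3)
        assert 2 in tm.empty_rows
        assert np.all(tm.probabilities[2] == 0)

    def test_rows_stochastic(self, rng):
        trajs = [rng.integers(0, 5, 50) for _ in range(10)]
        tm = estimate_transition_matrix(trajs, k=5)
        assert np.allclose(tm.probabilities.sum(axis=1), 1.0, atol=1e-12)

    def test_parameter_recovery_from_simulation(self, two_state_sim):
        """Recover the hidden chain's transition matrix within 0.02 per entry
        from 1e5 simulated transitions, microstates aligned to states."""
        spec, traj, _ = two_state_sim
        centers, _ = fit_microstates(traj.reshape(-1, 1), k=2, seed=0)
        order = np.argsort(centers[:, 0])
        assigns = [assign_microstates(traj[i], centers) for i in range(traj.shape[0])]
        tm = estimate_transition_matrix(assigns, k=2)
        est = tm.probabilities[order][:, order]
        assert np.abs(est - spec.transition_matrix).max() <= 0.02


class TestLikelihood:
    def test_deterministic_cycle_loglik_zero(self):
        cycle = np.array([0, 1, 2, 0, 1, 2, 0])
        tm = estimate_transition_matrix([cycle], k=3)
        assert trajectory_log_likelihood(tm, [cycle], pseudocount=0) == 0.0

    def test_uniform_chain_equals_minus_log_k(self, rng):
        k = 7
        tm = TransitionMatrix(
            counts=np.ones((k, k), dtype=int), probabilities=np.full((k, k), 1 / k)
        )
        val = [rng.integers(0, k, 30) for _ in range(5)]
        assert trajectory_log_likelihood(tm, val) == pytest.approx(-np.log(k), abs=1e-12)

    def test_expected_loglik_two_state_chain(self, two_state_sim):
        """<L> converges to sum_i pi_i sum_j T_ij log T_ij under stationarity."""
        spec, traj, truth = two_state_sim
        n = traj.shape[0] // 2
        centers, _ = fit_microstates(traj[:n].reshape(-1, 1), k=2, seed=0)
        train = [assign_microstates(traj[i], centers) for i in range(n)]
        val = [assign_microstates(traj[i], centers) for i in range(n, traj.shape[0])]
        tm = estimate_transition_matrix(train, k=2)
        T = np.asarray(spec.transition_matrix)
        pi = np.array([T[1, 0], T[0, 1]])
        pi = pi / pi.sum()
        analytic = sum(pi[i] * T[i] @ np.log(T[i]) for i in range(2))
        assert trajectory_log_likelihood(tm, val, pseudocount=0) == pytest.approx(
            analytic, abs=0.02
        )

    def test_strict_mode_raises_on_unseen(self):
        tm = estimate_transition_matrix([np.array([0, 1, 0, 1])], k=2)
        with pytest.raises(ValueError, match="zero training probability"):
            trajectory_log_likelihood(tm, [np.array([0, 0])], pseudocount=0)

    def test_empty_validation_raises(self):
        tm = estimate_transition_matrix([np.array([0, 1])], k=2)
        with pytest.raises(ValueError, match="empty validation"):
            trajectory_log_likelihood(tm, [np.array([0])])

    def test_model_object_fit_score(self, rng):
        trajs = [rng.normal(size=(50, 2)) for _ in range(20)]
        msm = MarkovStateModel(k=5, seed=0).fit(trajs[:15])
        assert np.isfinite(msm.score(trajs[15:]))


class TestDensityPeaks:
    def test_single_blob_single_peak(self, rng):
        pts = rng.normal([2.0, -1.0], 0.5, (2000, 2))
        grid = make_shared_grid(pts, bins=40, pct=(0.5, 99.5))
        peaks = find_density_peaks({"A": pts}, grid)
        assert len(peaks) == 1
        assert np.allclose(peaks[0]["location"], [2.0, -1.0], atol=0.5)

    def test_three_gaussian_mixture_three_peaks(self, rng):
        blobs = [rng.normal(loc, 0.4, (1500, 2)) for loc in ((0, 0), (6, 0), (0, 6))]
        pts = np.vstack(blobs)
        grid = make_shared_grid(pts, bins=50, pct=(0.5, 99.5))
        peaks = find_density_peaks({"A": pts}, grid, min_density_frac=0.2)
        assert len(peaks) == 3

    def test_shared_blob_deduplicated_across_treatments(self, rng):
        grid = make_shared_grid(rng.normal(size=(1000, 2)), bins=20)
        peaks = find_density_peaks(
            {"A": rng.normal(size=(6000, 2)), "B": rng.normal(size=(6000, 2))}, grid
        )
        assert len(peaks) == 1


class TestCoarseGraining:
    @staticmethod
    def _two_basin_tm(rng, eps=0.02):
        """4 microstates in 2 weakly-coupled blocks {0,1} and {2,3}."""
        T = np.array(
            [
                [0.49, 0.49, eps / 2, eps / 2],
                [0.49, 0.49, eps / 2, eps / 2],
                [eps / 2, eps / 2, 0.49, 0.49],
                [eps / 2, eps / 2, 0.49, 0.49],
            ]
        )
        counts = np.round(T * 10_000).astype(int)
        centers = np.array([[0.0, 0], [1, 0], [10, 0], [11, 0]])
        return TransitionMatrix(
            counts=counts, probabilities=counts / counts.sum(1, keepdims=True),
            centers=centers,
        )

    def test_two_basin_partition_recovered(self, rng):
        tm = self._two_basin_tm(rng)
        peaks = [{"location": (c[0], c[1]), "treatment": "A", "density": 1.0}
                 for c in tm.centers]
        net = coarse_grain_states(tm, peaks, n_macro=2)
        g = net.micro_to_macro
        assert g[0] == g[1] and g[2] == g[3] and g[0] != g[2]
        assert net.peak_to_macro.tolist() == g.tolist()

    def test_identity_grouping_when_nmacro_equals_k(self, rng):
        tm = self._two_basin_tm(rng)
        net = coarse_grain_states(tm, [{"location": c, "treatment": "A", "density": 1.0}
                                       for c in tm.centers.tolist()], n_macro=4)
        assert sorted(net.micro_to_macro.tolist()) == [0, 1, 2, 3]

    def test_coarse_rows_sum_to_one(self, rng):
        tm = self._two_basin_tm(rng)
        peaks = [{"location": c, "treatment": "A", "density": 1.0}
                 for c in tm.centers.tolist()]
        net = coarse_grain_states(tm, peaks, n_macro=2)
        assert np.allclose(net.coarse_probabilities.sum(axis=1), 1.0, atol=1e-12)

    def test_nmacro_exceeding_peaks_raises(self, rng):
        tm = self._two_basin_tm(rng)
        with pytest.raises(ValueError, match="peaks"):
            coarse_grain_states(tm, [{"location": (0, 0), "treatment": "A",
                                      "density": 1.0}], n_macro=2)

    def test_manual_map_override(self, rng):
        tm = self._two_basin_tm(rng)
        peaks = [{"location": c, "treatment": "A", "density": 1.0}
                 for c in tm.centers.tolist()]
        manual = np.array([0, 1, 1, 0])
        net = coarse_grain_states(tm, peaks, n_macro=2, manual_map=manual)
        assert np.array_equal(net.micro_to_macro, manual)


class TestBayesianBootstrap:
    def test_identical_values_degenerate_interval(self):
        mean, (lo, hi) = bayesian_bootstrap_ci([3.3, 3.3, 3.3], n_draws=1000, seed=0)
        assert mean == pytest.approx(3.3, abs=1e-12)
        assert lo == pytest.approx(hi, abs=1e-12) == pytest.approx(3.3, abs=1e-12)

    def test_two_replicates_uniform_weighted_mean(self):
        """Dirichlet(1,1)-weighted mean of (0,1) is Uniform(0,1):
        the 95% interval approaches (0.025, 0.975)."""
        mean, (lo, hi) = bayesian_bootstrap_ci([0.0, 1.0], n_draws=100_000, seed=1)
        assert mean == pytest.approx(0.5, abs=0.02)
        assert lo == pytest.approx(0.025, abs=0.01)
        assert hi == pytest.approx(0.975, abs=0.01)

    def test_seeded_determinism(self):
        a = bayesian_bootstrap_ci([1.0, 2.0, 4.0], seed=7)
        b = bayesian_bootstrap_ci([1.0, 2.0, 4.0], seed=7)
        assert a == b

    def test_single_replicate_raises(self):
        with pytest.raises(ValueError):
            bayesian_bootstrap_ci([1.0])
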