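"""Experiment drivers: random problems, scans, clusters, patches, images."""

import numpy as np
import pytest

from critdiv import berger_critical_w, berger_problem, two_state_problem
from critdiv import experiments as xp
from critdiv.experiments import (
    N_PATCH_STATES,
    RandomRDSpec,
    cluster_problem,
    count_critical_points,
    criticality_heatmap,
    critical_scan,
    patch_rd_problem,
    patch_state_from_index,
    random_rd_problem,
    synthetic_image_generator,
    ternarize_patch,
    weak_universality_experiment,
)
from critdiv.rd import RDProblem, rd_curve


class TestRandomRDProblem:
    def test_construction_invariants(self):
        prob = random_rd_problem(RandomRDSpec(n=5, seed=11))
        assert prob.q.sum() == pytest.approx(1.0)
        assert np.all(prob.q > 0)
        assert np.all(np.diag(prob.d) == 0.0)
        off = prob.d[~np.eye(5, dtype=bool)]
        assert np.all((off >= 0.0) & (off <= 4.0))

    def test_reproducible_from_seed(self):
        a = random_rd_problem(RandomRDSpec(n=4, seed=99))
        b = random_rd_problem(RandomRDSpec(n=4, seed=99))
        assert np.array_equal(a.q, b.q) and np.array_equal(a.d, b.d)

    def test_feeds_solver_across_beta_range(self):
        prob = random_rd_problem(RandomRDSpec(n=2, seed=5))
        sols = rd_curve(prob, np.geomspace(0.05, 10.0, 25))
        assert all(np.isfinite(s.R) and np.isfinite(s.D) for s in sols)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            RandomRDSpec(n=1, seed=0)
        with pytest.raises(ValueError):
            RandomRDSpec(n=3, seed=0, d_low=2.0, d_high=1.0)


class TestCriticalCounting:
    def test_two_state_has_single_critical_point(self):
        assert count_critical_points(two_state_problem(2.0)) == 1

    def test_berger_has_two_critical_points(self, berger_13):
        scan = critical_scan(berger_13, np.geomspace(0.02, 4.0, 600))
        assert len(scan.peaks) == 2
        # the high-beta peak sits within one grid step of the closed form
        beta_star = -np.log(berger_critical_w(1.0 / 13.0))
        err = abs(np.log(scan.beta_stars[-1]) - np.log(beta_star))
        assert err <= np.log(4.0 / 0.02) / 599 * 1.5

    def test_single_state_problem_has_none(self):
        prob = RDProblem(q=np.array([1.0]), d=np.array([[0.0]]))
        assert count_critical_points(prob) == 0

    def test_two_state_peak_near_closed_form_on_w_grid(self, two_state_a2):
        w_grid = np.linspace(0.02, 0.98, 400)
        _, series = xp.divergence_over_w(two_state_a2, w_grid)
        peaks = xp.find_significant_peaks(series)
        assert len(peaks) == 1
        w_star = (np.sqrt(5.0) - 1.0) / 2.0
        assert abs(peaks.x[0] - w_star) <= (w_grid[1] - w_grid[0])

    def test_peak_sets_insensitive_to_hyperparameters(self, berger_13):
        from critdiv import PeakConfig

        grid = np.geomspace(0.02, 4.0, 400)
        reference = None
        for eta in (0.01, 0.05, 0.1):
            for mu in (0.5, 0.9):
                scan = critical_scan(
                    berger_13, grid, peak_config=PeakConfig(eta=eta, mu=mu)
                )
                got = tuple(np.round(scan.beta_stars, 6))
                if reference is None:
                    reference = got
                assert got == reference


class TestWeakUniversality:
    def test_same_seed_gives_identical_curves(self):
        res = weak_universality_experiment(
            6, seed1=3, seed2=3, beta_grid=np.geomspace(0.05, 10.0, 120)
        )
        assert res.gap == pytest.approx(0.0, abs=1e-12)
        assert np.array_equal(res.peaks1.x, res.peaks2.x)

    def test_curves_close_but_critical_points_differ(self):
        res = weak_universality_experiment(
            30, seed1=1, seed2=2, beta_grid=np.geomspace(0.1, 30.0, 300)
        )
        assert res.gap < 0.5  # bits; curves nearly coincide
        set1 = set(np.round(res.peaks1.x, 3))
        set2 = set(np.round(res.peaks2.x, 3))
        assert set1 != set2

    def test_gap_shrinks_with_state_count(self):
        grid = np.geomspace(0.1, 30.0, 120)
        gaps = {}
        for n in (5, 20):
            g = [
                weak_universality_experiment(
                    n, seed1=10 + k, seed2=20 + k, beta_grid=grid
                ).gap
                for k in range(3)
            ]
            gaps[n] = np.mean(g)
        assert gaps[20] < gaps[5]


class TestCriticalityHeatmap:
    def test_theory_overlay_domain(self):
        u_grid = np.array([0.05, 0.1, 0.15, 0.2, 0.25])
        res = criticality_heatmap(u_grid, np.geomspace(0.5, 5.0, 60))
        assert np.all(res.theory_u <= 3.0 - 2.0 * np.sqrt(2.0))
        assert res.theory_u.size == 3  # 0.05, 0.1, 0.15
        assert res.M.shape == (5, 59)

    def test_ridge_matches_closed_form_at_small_u(self):
        u = 0.05
        beta_star = -np.log(berger_critical_w(u))
        grid = np.geomspace(1.0, 6.0, 300)
        res = criticality_heatmap(np.array([u]), grid)
        ridge = res.t_mid[np.argmax(res.M[0])]
        assert abs(ridge - beta_star) <= 2 * np.diff(grid).max()


class TestClusterProblem:
    def test_default_dimensions(self):
        prob = cluster_problem()
        assert prob.n == 18
        assert prob.d.shape == (18, 18)
        assert np.all(np.diag(prob.d) == 0.0)

    def test_intermediate_beta_codes_one_output_per_cluster(self):
        # an annealing phase where exactly three outputs carry essentially
        # all mass, one representative per block (outputs with p below 1%
        # are slowly-vanishing remnants near the phase boundaries)
        prob = cluster_problem(seed=1)
        sols = rd_curve(prob, np.geomspace(0.05, 10.0, 200))
        counts = np.array([int(np.sum(s.p_out > 0.01)) for s in sols])
        runs = []
        start = None
        for i, c in enumerate(counts):
            if c == 3 and start is None:
                start = i
            elif c != 3 and start is not None:
                runs.append((start, i - 1))
                start = None
        if start is not None:
            runs.append((start, counts.size - 1))
        assert runs, "no one-output-per-cluster phase found"
        longest = max(runs, key=lambda r: r[1] - r[0])
        assert longest[1] - longest[0] + 1 >= 10
        block = np.repeat(np.arange(3), 6)
        mid = sols[(longest[0] + longest[1]) // 2]
        reps = np.flatnonzero(mid.p_out > 0.01)
        assert sorted(block[reps]) == [0, 1, 2]

    def test_within_block_permutation_symmetry(self):
        prob = cluster_problem(jitter=0.0)
        perm = np.arange(18)
        perm[[0, 3]] = perm[[3, 0]]  # swap two states of the first block
        permuted = RDProblem(q=prob.q[perm], d=prob.d[np.ix_(perm, perm)])
        for beta in (0.5, 2.0):
            a = xp.rd_curve(prob, np.array([beta]))[0]
            b = xp.rd_curve(permuted, np.array([beta]))[0]
            assert a.R == pytest.approx(b.R, abs=1e-9)
            assert a.D == pytest.approx(b.D, abs=1e-9)

    def test_rejects_inverted_distortions(self):
        with pytest.raises(ValueError):
            cluster_problem(d_intra=4.0, d_inter=0.5)


class TestTernarization:
    def test_constant_patch_maps_to_all_middle(self):
        state = ternarize_patch(np.full((2, 2), 3.7))
        assert state.digits == (1, 1, 1, 1)
        assert state.bits == (0, 0, 0, 0, 0, 0, 0, 0)

    def test_index_bijection_covers_81_states(self):
        seen = {patch_state_from_index(i).digits for i in range(N_PATCH_STATES)}
        assert len(seen) == N_PATCH_STATES == 3**4
        for i in range(N_PATCH_STATES):
            assert patch_state_from_index(i).index == i

    def test_hand_ternarized_extreme_patch(self):
        state = ternarize_patch(np.array([[-10.0, -10.0], [10.0, 10.0]]))
        assert state.digits == (0, 0, 2, 2)
        assert state.bits == (0, 1, 0, 1, 1, 0, 1, 0)

    def test_wrong_size_rejected(self):
        with pytest.raises(ValueError):
            ternarize_patch(np.ones(5))


class TestPatchRDProblem:
    def test_hamming_distortion_properties(self, rng):
        images = synthetic_image_generator(0, width=32, height=32, count=1)
        prob = patch_rd_problem(images)
        assert np.array_equal(prob.d, prob.d.T)
        assert np.all(np.diag(prob.d) == 0.0)
        assert prob.d.max() <= 8.0
        assert prob.d.max() == 8.0  # opposite extremes differ in all 8 bits

    def test_empirical_distribution_over_81_states(self):
        images = synthetic_image_generator(1, width=64, height=64, count=2)
        prob = patch_rd_problem(images)
        assert prob.q.size == N_PATCH_STATES
        assert prob.q.sum() == pytest.approx(1.0)
        assert np.all(prob.q > 0)  # pseudo-count keeps unseen states positive

    def test_pipeline_finds_few_critical_codebooks(self):
        # natural-like 1/f statistics yield far fewer transitions than the
        # generic n - 1 = 80 within this beta window
        images = synthetic_image_generator(2, width=64, height=64, count=2)
        prob = patch_rd_problem(images)
        count = count_critical_points(prob, np.geomspace(0.1, 10.0, 150))
        assert 0 < count < 40


class TestSyntheticImages:
    def test_deterministic_per_seed(self):
        a = synthetic_image_generator(7, 32, 32, 2)
        b = synthetic_image_generator(7, 32, 32, 2)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_pixel_range_and_spread(self):
        (img,) = synthetic_image_generator(3, 64, 64, 1)
        assert img.min() >= 0.0 and img.max() <= 1.0
        assert img.std() > 0.01

    def test_amplitude_spectrum_slope_near_minus_one(self):
        (img,) = synthetic_image_generator(5, 128, 128, 1)
        amp = np.abs(np.fft.fft2(img - img.mean()))
        fy = np.fft.fftfreq(128)[:, None]
        fx = np.fft.fftfreq(128)[None, :]
        f = np.sqrt(fx**2 + fy**2).ravel()
        a = amp.ravel()
        bins = np.geomspace(1.0 / 64, 0.5, 12)
        centers, means = [], []
        for lo, hi in zip(bins[:-1], bins[1:]):
            sel = (f >= lo) & (f < hi)
            if sel.sum() > 4:
                centers.append(np.sqrt(lo * hi))
                means.append(a[sel].mean())
        slope = np.polyfit(np.log(centers), np.log(means), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.3)

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            synthetic_image_generator(0, width=0, height=10, count=1)
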