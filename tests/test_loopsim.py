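"""Closed-loop geometry, Metropolis sampling and energy minimisation."""

import math

import numpy as np
import pytest

import echbend as eb
from echbend.loopsim import bend_energy_and_gradient

TWO_PI = 2 * math.pi


@pytest.fixture(scope="module")
def quick_ensemble(dna_profile):
    """Short 30-bead run shared by the sampler checks."""
    return eb.mc_sample(
        eb.build_regular_loop(30), dna_profile, sweeps=1200, seed=11
    )


class TestGeometry:
    def test_hexagon(self):
        ch = eb.build_regular_loop(6)
        assert np.allclose(np.linalg.norm(ch.coords, axis=1), 3.3)
        assert np.allclose(eb.bend_angles(ch.coords), math.radians(60))
        assert np.allclose(ch.bond_lengths(), 3.3)

    def test_square(self):
        ch = eb.build_regular_loop(4)
        assert np.allclose(eb.bend_angles(ch.coords), math.pi / 2)

    @pytest.mark.parametrize("n", [3, 7, 50, 333])
    def test_total_turning_is_two_pi(self, n):
        ch = eb.build_regular_loop(n)
        assert np.sum(eb.bend_angles(ch.coords)) == pytest.approx(TWO_PI)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            eb.build_regular_loop(2)

    def test_collinear_and_right_angle(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [2, 1, 0]], dtype=float)
        ang = eb.bend_angles(pts, ring=False)
        assert ang[0] == pytest.approx(0.0, abs=1e-8)
        assert ang[1] == pytest.approx(math.pi / 2)

    def test_degenerate_bond_raises(self):
        pts = np.zeros((4, 3))
        with pytest.raises(ValueError, match="zero-length"):
            eb.bend_angles(pts)


class TestGradient:
    def test_matches_finite_differences(self, dna_profile):
        rng = np.random.default_rng(3)
        x = eb.build_regular_loop(12).coords + rng.normal(0, 0.2, (12, 3))
        e0, g = bend_energy_and_gradient(x, dna_profile)
        eps = 1e-6
        for i, j in [(0, 0), (3, 1), (7, 2), (11, 0)]:
            xp = x.copy()
            xp[i, j] += eps
            ep, _ = bend_energy_and_gradient(xp, dna_profile)
            assert (ep - e0) / eps == pytest.approx(g[i, j], abs=2e-4)

    def test_open_chain_variant(self, dna_profile):
        rng = np.random.default_rng(4)
        x = np.cumsum(rng.normal(0, 1, (8, 3)), axis=0) * 1.5
        e0, g = bend_energy_and_gradient(x, dna_profile, ring=False)
        eps = 1e-6
        xp = x.copy()
        xp[4, 1] += eps
        ep, _ = bend_energy_and_gradient(xp, dna_profile, ring=False)
        assert (ep - e0) / eps == pytest.approx(g[4, 1], abs=2e-4)


class TestSampler:
    def test_seed_determinism(self, dna_profile):
        a = eb.mc_sample(eb.build_regular_loop(20), dna_profile, sweeps=300, seed=5)
        b = eb.mc_sample(eb.build_regular_loop(20), dna_profile, sweeps=300, seed=5)
        assert np.array_equal(a.frames, b.frames)
        assert a.acceptance_rate == b.acceptance_rate

    def test_different_seeds_differ(self, dna_profile):
        a = eb.mc_sample(eb.build_regular_loop(20), dna_profile, sweeps=300, seed=5)
        b = eb.mc_sample(eb.build_regular_loop(20), dna_profile, sweeps=300, seed=6)
        assert not np.array_equal(a.frames, b.frames)

    def test_zero_sweeps_rejected(self, dna_profile):
        with pytest.raises(ValueError):
            eb.mc_sample(eb.build_regular_loop(20), dna_profile, sweeps=0, seed=1)

    def test_acceptance_in_working_range(self, quick_ensemble):
        assert 0.05 < quick_ensemble.acceptance_rate < 0.95

    def test_fenchel_total_curvature(self, quick_ensemble):
        # closed space polygons cannot turn by less than a full revolution
        totals = quick_ensemble.angles.sum(axis=1)
        assert np.all(totals >= TWO_PI - 1e-9)

    def test_bond_lengths_stay_stiff(self, quick_ensemble):
        last = eb.RingChain(coords=quick_ensemble.frames[-1])
        assert np.all(np.abs(last.bond_lengths() - 3.3) < 0.033 * 10)

    def test_energy_bookkeeping(self, quick_ensemble):
        assert quick_ensemble.bookkeeping_drift < 1e-6

    def test_frame_energy_matches_recomputation(self, dna_profile, quick_ensemble):
        from echbend.loopsim import _site_energy_scalar

        v = _site_energy_scalar(dna_profile)
        i = quick_ensemble.n_frames // 2
        recomputed = sum(v(t) for t in eb.bend_angles(quick_ensemble.frames[i]))
        assert quick_ensemble.bend_energies[i] == pytest.approx(recomputed, abs=1e-9)


class TestMinimise:
    def test_harmonic_recovers_regular_polygon(self):
        harm = eb.HarmonicProfile(lp=150, domain=(0.0, math.pi))
        rng = np.random.default_rng(8)
        start = eb.build_regular_loop(100)
        noisy = eb.RingChain(coords=start.coords + rng.normal(0, 0.3, (100, 3)))
        relaxed, per_site = eb.minimize_loop(noisy, harm)
        assert per_site == pytest.approx(0.29609, abs=2e-5)
        assert np.allclose(eb.bend_angles(relaxed.coords), TWO_PI / 100, atol=1e-4)

    def test_gradient_tolerance_met(self, dna_profile):
        relaxed, _ = eb.minimize_loop(eb.build_regular_loop(50), dna_profile)
        _, g = bend_energy_and_gradient(relaxed.coords, dna_profile)
        assert np.max(np.abs(g)) < 1e-6

    def test_large_loop_stays_uniform(self, dna_profile):
        relaxed, per_site = eb.minimize_loop(eb.build_regular_loop(400), dna_profile)
        assert per_site == pytest.approx(
            float(dna_profile.energy(TWO_PI / 400)), rel=1e-6
        )

    def test_kinked_minimum_below_uniform(self, dna_profile, dna_hull):
        ens = eb.mc_sample(eb.build_regular_loop(60), dna_profile, sweeps=2500, seed=17)
        _, per_site = eb.minimize_from_ensemble(ens, dna_profile, n_starts=3)
        tbar = TWO_PI / 60
        assert per_site < float(dna_profile.energy(tbar))
        assert per_site == pytest.approx(
            eb.hull_energy(dna_profile, dna_hull, tbar), rel=0.10
        )


class TestAnalysis:
    def test_occupancy_all_weak(self, dna_hull):
        angles = np.full(100, 0.01)
        weak, strong = eb.angle_occupancy(angles, dna_hull)
        assert (weak, strong) == (1.0, 0.0)

    def test_occupancy_sums_to_one(self, dna_hull, quick_ensemble):
        weak, strong = eb.angle_occupancy(quick_ensemble.all_angles(), dna_hull)
        assert weak + strong == pytest.approx(1.0)
        assert 0 < strong < 1

    def test_minimized_occupancy_matches_lever_rule(self, dna_profile, dna_hull):
        ens = eb.mc_sample(eb.build_regular_loop(60), dna_profile, sweeps=2500, seed=19)
        relaxed, _ = eb.minimize_from_ensemble(ens, dna_profile, n_starts=3)
        _, strong = eb.angle_occupancy(eb.bend_angles(relaxed.coords), dna_hull)
        p = eb.strong_fraction(TWO_PI / 60, dna_hull.theta_a, dna_hull.theta_b)
        # integer kink counts quantise occupancy in steps of 1/60
        assert strong == pytest.approx(p, abs=1.5 / 60)

    def test_histogram_normalisation(self, quick_ensemble):
        centers, density = eb.angle_histogram(quick_ensemble.all_angles())
        width = centers[1] - centers[0]
        assert np.sum(density) * width == pytest.approx(1.0, rel=0.02)

    def test_count_modes_on_synthetic_shapes(self):
        x = np.linspace(0, 1, 120)
        unimodal = np.exp(-(((x - 0.2) / 0.08) ** 2))
        bimodal = unimodal + 0.15 * np.exp(-(((x - 0.7) / 0.08) ** 2))
        assert eb.count_modes(unimodal) == 1
        assert eb.count_modes(bimodal) == 2
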