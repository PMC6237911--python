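"""Boost construction, statistics collection and the phased Langevin engine."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gamdkit as gk
from gamdkit.engine import PotentialStats


def stats_from(values):
    s = PotentialStats()
    for v in values:
        gk.update_stats(s, v)
    return s


class TestPotentialStats:
    def test_basic_stream(self):
        s = stats_from([1.0, 2.0, 3.0])
        assert (s.v_min, s.v_max, s.v_avg) == (1.0, 3.0, 2.0)
        assert s.n_samples == 3

    def test_updating_with_current_mean_keeps_mean(self):
        s = stats_from([1.0, 2.0, 3.0])
        gk.update_stats(s, s.v_avg)
        assert s.v_avg == pytest.approx(2.0)
        assert s.n_samples == 4

    def test_matches_two_pass_computation(self, rng):
        values = rng.standard_normal(10_000)
        s = stats_from(values)
        assert s.v_avg == pytest.approx(values.mean(), abs=1e-10)
        assert s.sigma_v == pytest.approx(values.std(), abs=1e-10)
        assert s.v_min == values.min() and s.v_max == values.max()

    def test_non_finite_rejected(self):
        s = stats_from([1.0])
        with pytest.raises(ValueError):
            gk.update_stats(s, float("nan"))

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=50))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_ordering_invariant(self, values):
        s = stats_from(values)
        assert s.v_min <= s.v_avg <= s.v_max
        assert s.sigma_v >= 0.0
        assert s.n_samples == len(values)


def _stats(vmin, vmax, vavg, sigma, n=100):
    s = PotentialStats(v_min=vmin, v_max=vmax, v_avg=vavg, n_samples=n)
    s._m2 = sigma * sigma * n
    return s


class TestComputeK0:
    def test_lower_bound_formula(self):
        p = gk.compute_k0(_stats(0, 100, 50, 20), sigma0=6.0, bound_mode="lower")
        assert p.k0 == pytest.approx(0.6)
        assert p.E == pytest.approx(100.0)
        assert p.k == pytest.approx(0.006)

    def test_lower_bound_clamps_at_one(self):
        p = gk.compute_k0(_stats(0, 100, 50, 20), sigma0=30.0, bound_mode="lower")
        assert p.k0 == 1.0
        assert p.E == pytest.approx(100.0)

    def test_upper_bound_falls_back_when_out_of_range(self):
        p = gk.compute_k0(_stats(0, 100, 50, 20), sigma0=6.0, bound_mode="upper")
        assert p.k0 == pytest.approx(0.6)      # fell back to the lower rule
        assert p.E == pytest.approx(100.0)
        assert p.effective_bound == "lower"

    def test_upper_bound_accepted(self):
        p = gk.compute_k0(_stats(0, 100, 50, 20), sigma0=12.0, bound_mode="upper")
        assert p.k0 == pytest.approx(0.8)
        assert p.effective_bound == "upper"
        assert p.E == pytest.approx(0.0 + 1.0 / p.k)
        # threshold range V_max <= E <= V_min + 1/k
        assert 100.0 <= p.E <= 0.0 + 1.0 / p.k + 1e-12

    @pytest.mark.parametrize("stats, name", [
        (_stats(50, 50, 50, 10), "V_max"),
        (_stats(0, 100, 100, 10), "V_avg"),
        (_stats(0, 100, 50, 0.0), "sigma"),
    ])
    def test_degenerate_statistics_named_in_error(self, stats, name):
        with pytest.raises(ValueError, match=name):
            gk.compute_k0(stats, sigma0=6.0)


class TestBoost:
    PARAMS = gk.BoostParams(E=100.0, k0=1.0, k=0.01, sigma0=6.0)

    def test_zero_above_threshold(self):
        assert gk.compute_boost(100.0, self.PARAMS) == 0.0
        assert gk.compute_boost(150.0, self.PARAMS) == 0.0

    def test_harmonic_value(self):
        assert gk.compute_boost(80.0, self.PARAMS) == pytest.approx(2.0)

    def test_continuous_at_threshold(self):
        assert gk.compute_boost(100.0 - 1e-8, self.PARAMS) < 1e-10

    def test_force_unbiased_above_threshold(self):
        g = np.array([1.5, -2.0])
        assert np.array_equal(gk.boosted_force(g, 120.0, self.PARAMS), -g)

    def test_force_vanishes_in_flattened_limit(self):
        # k (E - v) = 1 at v = E - 1/k
        v = self.PARAMS.E - 1.0 / self.PARAMS.k
        f = gk.boosted_force(np.array([3.0]), v, self.PARAMS)
        assert np.allclose(f, 0.0, atol=1e-12)

    def test_force_matches_finite_difference_of_boosted_potential(self, rng):
        dw = gk.make_double_well(6.0, 2.0, 0.0)
        params = gk.BoostParams(E=4.0, k0=0.5, k=0.1, sigma0=6.0)

        def v_star(x):
            v = dw.energy(x)
            return v + gk.compute_boost(v, params)

        for _ in range(20):
            x = np.array([rng.uniform(-1.8, 1.8)])
            v = dw.energy(x)
            f = gk.boosted_force(dw.gradient(x), v, params)
            h = 1e-6
            num = (v_star(x + h) - v_star(x - h)) / (2 * h)
            assert f[0] == pytest.approx(-num, rel=1e-5, abs=1e-6)


class TestPhases:
    def test_equipartition_in_cmd(self):
        """Overdamped sampling of a harmonic well reproduces the canonical
        position variance k_B T / stiffness within 5%."""
        pot = gk.make_harmonic(2.0)
        cfg = gk.SimulationConfig(
            n_steps_cmd=1_000_000, n_steps_equil=0, n_steps_production=0,
            friction=5.0, timestep=0.01, save_stride=2, seed=0,
            boost_mode="none")
        traj, _ = gk.run_phase(pot, cfg, "cmd")
        var = traj.coords[:, 0].var()
        assert var == pytest.approx(0.5, rel=0.05)

    def test_zero_k0_production_bitwise_equals_cmd(self):
        dw = gk.make_double_well(6.0, 2.0, 0.0)
        boosted = gk.SimulationConfig(
            n_steps_cmd=5000, n_steps_equil=0, n_steps_production=5000,
            save_stride=10, seed=3, k0_override=0.0)
        t1, s1 = gk.run_phase(dw, boosted, "cmd")
        t2, _ = gk.run_phase(dw, boosted, "production", s1)
        plain = gk.SimulationConfig(
            n_steps_cmd=5000, n_steps_equil=0, n_steps_production=0,
            save_stride=10, seed=3)
        t3, s3 = gk.run_phase(dw, plain, "cmd")
        t4, _ = gk.run_phase(dw, plain, "cmd", s3)
        assert np.array_equal(t2.coords, t4.coords)
        assert np.array_equal(t2.v_total, t4.v_total)
        assert np.all(t2.dv_total == 0.0)

    def test_production_requires_statistics(self):
        dw = gk.make_double_well(6.0, 2.0, 0.0)
        cfg = gk.SimulationConfig()
        with pytest.raises(ValueError):
            gk.run_phase(dw, cfg, "production")

    def test_enhanced_sampling_crosses_barrier_more(self):
        """Per seed, GaMD production yields at least as many inter-well
        transitions as an equal-length conventional run (8 kT barrier)."""
        dw = gk.make_double_well(8.0, 2.0, 0.0)
        n_prod = 300_000

        def transitions(coords):
            sign = np.sign(coords[:, 0])
            sign = sign[sign != 0]
            return int(np.sum(sign[1:] != sign[:-1]))

        for seed in range(5):
            gcfg = gk.SimulationConfig(
                n_steps_cmd=2000, n_steps_equil=10000,
                n_steps_production=n_prod, save_stride=5, seed=seed)
            gres = gk.run_gamd(dw, gcfg)
            ccfg = gk.SimulationConfig(
                n_steps_cmd=2000 + 10000 + n_prod, n_steps_equil=0,
                n_steps_production=0, save_stride=5, seed=seed,
                boost_mode="none")
            ctraj, _ = gk.run_phase(dw, ccfg, "cmd")
            n_g = transitions(gres["production"].coords)
            n_c = transitions(ctraj.coords[2400:])
            assert n_g >= n_c


class TestTrajectoryInvariants:
    def test_boost_branch_structure_on_every_frame(self, doublewell_benchmark):
        """dV >= 0 everywhere; dV = 0 exactly when V >= E; otherwise dV equals
        the harmonic boost recomputed from the frozen parameters."""
        _, _, result = doublewell_benchmark
        prod = result["production"]
        p = prod.final_params["total"]
        assert np.all(prod.dv_total >= 0.0)
        above = prod.v_total >= p.E
        assert np.all(prod.dv_total[above] == 0.0)
        below = ~above
        expected = 0.5 * p.k * (p.E - prod.v_total[below]) ** 2
        assert np.allclose(prod.dv_total[below], expected, atol=1e-12)
        assert np.all(prod.dv_total[below] > 0.0)

    def test_frozen_params_satisfy_threshold_range(self, doublewell_benchmark):
        _, _, result = doublewell_benchmark
        prod = result["production"]
        p = prod.final_params["total"]
        stats = prod.final_stats["total"]
        assert stats["v_max"] <= p.E <= stats["v_min"] + 1.0 / p.k + 1e-9
        assert 0.0 < p.k0 <= 1.0
        assert p.k == pytest.approx(p.k0 / (stats["v_max"] - stats["v_min"]))

    def test_dual_boost_dv_is_sum_of_components(self, allosteric_dual_boost_run):
        _, _, result = allosteric_dual_boost_run
        prod = result["production"]
        assert set(prod.dv_parts) == {"total", "component"}
        assert np.allclose(
            prod.dv_total, prod.dv_parts["total"] + prod.dv_parts["component"])
        assert np.all(prod.dv_total >= 0.0)

    def test_dual_boost_is_near_gaussian(self, allosteric_dual_boost_run):
        """On the multi-term allosteric benchmark the dual-boost distribution
        passes the anharmonicity screen (single-DOF toys do not: see the
        methods note)."""
        _, _, result = allosteric_dual_boost_run
        report = gk.anharmonicity(result["production"].dv_total)
        assert report.anharmonicity < 0.1

    def test_save_load_round_trip(self, tmp_path, allosteric_dual_boost_run):
        _, _, result = allosteric_dual_boost_run
        prod = result["production"]
        prefix = tmp_path / "prod"
        prod.save(prefix)
        back = gk.Trajectory.load(prefix)
        assert np.allclose(back.coords, prod.coords)
        assert np.allclose(back.dv_total, prod.dv_total)
        assert back.final_params["total"].E == pytest.approx(
            prod.final_params["total"].E)
        assert back.config.boost_mode == "dual"


class TestConfigValidation:
    def test_component_mode_requires_terms(self):
        with pytest.raises(ValueError):
            gk.SimulationConfig(boost_mode="dual")

    def test_unknown_component_term(self):
        dw = gk.make_double_well(6.0, 2.0, 0.0)
        cfg = gk.SimulationConfig(boost_mode="component",
                                  component_terms=("bogus",))
        with pytest.raises(ValueError, match="bogus"):
            gk.run_phase(dw, cfg, "cmd")

    def test_negative_steps_rejected(self):
        with pytest.raises(ValueError):
            gk.SimulationConfig(n_steps_cmd=-1)
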