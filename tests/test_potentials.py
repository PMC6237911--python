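"""Toy potentials, the allosteric toy system and the exact Boltzmann oracles."""

import numpy as np
import pytest
from scipy.stats import chi2_contingency

import gamdkit as gk
from gamdkit.potentials import (
    boltzmann_agonist_stats,
    boltzmann_marginal_s,
    boltzmann_mean_s,
    exact_pmf,
)


def _fd_gradient(energy, x, h=1e-6):
    g = np.zeros_like(x)
    for i in range(len(x)):
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        g[i] = (energy(xp) - energy(xm)) / (2 * h)
    return g


class TestDoubleWell:
    def test_symmetric_construction(self):
        dw = gk.make_double_well(6.0, 2.0, 0.0)
        assert dw.energy(np.array([-1.0])) == pytest.approx(0.0, abs=1e-12)
        assert dw.energy(np.array([+1.0])) == pytest.approx(0.0, abs=1e-12)
        assert dw.energy(np.array([0.0])) == pytest.approx(6.0, abs=1e-12)

    @pytest.mark.parametrize("asym", [0.5, 1.0, 2.0])
    def test_asymmetry_is_exact(self, asym):
        dw = gk.make_double_well(6.0, 2.0, asym)
        diff = dw.energy(np.array([-1.0])) - dw.energy(np.array([1.0]))
        assert diff == pytest.approx(asym, abs=1e-9)

    def test_gradient_vanishes_at_minima(self):
        dw = gk.make_double_well(6.0, 2.0, 1.0)
        for m in dw.metadata["minima"]:
            assert dw.gradient(np.array([m]))[0] == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("bad", [
        dict(barrier_height=-1.0, well_separation=2.0),
        dict(barrier_height=6.0, well_separation=0.0),
    ])
    def test_parameter_errors(self, bad):
        with pytest.raises(ValueError):
            gk.make_double_well(**bad)

    def test_gradient_matches_finite_difference(self, rng):
        dw = gk.make_double_well(7.0, 3.0, 1.5)
        (lo, hi), = dw.domain_bounds
        for _ in range(25):
            x = np.array([rng.uniform(lo + 0.1, hi - 0.1)])
            num = _fd_gradient(dw.energy, x)
            ana = dw.gradient(x)
            assert np.allclose(ana, num, rtol=1e-5, atol=1e-6)


class TestAllostericToy:
    def test_ordering_violation_raises(self):
        with pytest.raises(ValueError, match="s_closed"):
            gk.make_allosteric_toy(sb_minima=(7.0, 3.0, 14.8))

    def test_nonpositive_depth_raises(self):
        with pytest.raises(ValueError):
            gk.make_allosteric_toy(orth_depth=-1.0)

    @pytest.mark.parametrize("pam_present", [True, False])
    def test_gradient_matches_finite_difference(self, pam_present, rng):
        system = gk.make_allosteric_toy(pam_present=pam_present)
        d = system.dimensionality
        for _ in range(20):
            x = rng.uniform(-2.0, 2.0, d)
            x[system.s_index] = rng.uniform(1.0, 16.0)
            num = _fd_gradient(system.energy, x)
            ana = system.gradient(x)
            assert np.allclose(ana, num, rtol=1e-5, atol=1e-6)

    def test_terms_sum_to_total(self, rng):
        system = gk.make_allosteric_toy()
        x = rng.uniform(-1.0, 1.0, 5)
        x[4] = 5.0
        vs, gs = system.energy_and_gradient_terms(x)
        assert sum(vs.values()) == pytest.approx(system.energy(x))
        assert np.allclose(sum(gs.values()), system.gradient(x))

    def test_energy_separates_when_uncoupled(self, rng):
        """With c1 = c2 = 0 the energy is a sum of per-coordinate terms, so
        changing s must not change the agonist/PAM contributions."""
        system = gk.make_allosteric_toy(c1=0.0, c2=0.0)
        for _ in range(10):
            x = rng.uniform(-1.5, 1.5, 5)
            x[4] = rng.uniform(1.0, 16.0)
            y = x.copy()
            y[4] = rng.uniform(1.0, 16.0)
            vx, _ = system.energy_and_gradient_terms(x)
            vy, _ = system.energy_and_gradient_terms(y)
            assert vx["orth"] == pytest.approx(vy["orth"], abs=1e-12)
            assert vx["allo"] == pytest.approx(vy["allo"], abs=1e-12)

    def test_marginal_s_has_three_modes_when_uncoupled(self):
        system = gk.make_allosteric_toy(c1=0.0, c2=0.0, pam_present=False)
        s = np.linspace(0.5, 17.5, 600)
        p = boltzmann_marginal_s(system, s)
        modes = [s[i] for i in range(1, len(s) - 1)
                 if p[i] > p[i - 1] and p[i] > p[i + 1]]
        assert len(modes) == 3
        for target in system.config["sb_minima"]:
            assert min(abs(m - target) for m in modes) < 0.3

    def test_pam_coupling_pulls_salt_bridge_closed(self):
        """Oracle check: with the PAM pinned in the allosteric site, c1 > 0
        must lower the Boltzmann-mean salt-bridge distance."""
        base = dict(c2=0.0)
        free = gk.make_allosteric_toy(c1=0.0, **base)
        coupled = gk.make_allosteric_toy(c1=4.0, **base)
        site = free.config["allo_center"]
        m_free = boltzmann_mean_s(free, pam_fixed=site)
        m_coupled = boltzmann_mean_s(coupled, pam_fixed=site)
        assert m_coupled < m_free - 1.0   # decisively, not by quadrature noise

    def test_closed_bridge_confines_agonist(self):
        """Oracle check: with c2 > 0 the agonist position variance at
        s_closed is strictly below that at s_open."""
        system = gk.make_allosteric_toy(c1=0.0, pam_present=False)
        s_closed, _, s_open = system.config["sb_minima"]
        _, cov_closed = boltzmann_agonist_stats(system, s_closed)
        _, cov_open = boltzmann_agonist_stats(system, s_open)
        assert np.trace(cov_closed) < np.trace(cov_open)

    def test_factorization_chi_square(self):
        """Sampled factorization: on a fast-mixing zero-coupling variant the
        chi-square contingency test finds no dependence at alpha = 0.01,
        while a strongly coupled variant is flagged."""
        shallow = dict(c1=0.0, c2=0.0, orth_depth=1.5, allo_depth=1.5,
                       secondary_wells=[], sb_depths=(1.0, 1.0, 1.0))
        cfg = gk.SimulationConfig(
            n_steps_cmd=400000, n_steps_equil=0, n_steps_production=0,
            save_stride=400, friction=2.0, seed=0, boost_mode="none")

        def pvalue(a, b):
            ta = np.digitize(a, np.quantile(a, [1 / 3, 2 / 3]))
            tb = np.digitize(b, np.quantile(b, [1 / 3, 2 / 3]))
            table = np.zeros((3, 3))
            for i, j in zip(ta, tb):
                table[i, j] += 1
            return chi2_contingency(table).pvalue

        traj, _ = gk.run_phase(gk.make_allosteric_toy(**shallow), cfg, "cmd")
        ax, px, s = traj.coords[:, 0], traj.coords[:, 2], traj.coords[:, 4]
        assert pvalue(ax, s) > 0.01
        assert pvalue(px, s) > 0.01
        assert pvalue(ax, px) > 0.01

        coupled = gk.make_allosteric_toy(**{**shallow, "c1": 4.0})
        tc, _ = gk.run_phase(coupled, cfg, "cmd")
        assert pvalue(tc.coords[:, 2], tc.coords[:, 4]) < 0.01

    def test_config_round_trip(self, tmp_path):
        import yaml

        system = gk.make_allosteric_toy(c1=1.5, orth_depth=4.0)
        path = tmp_path / "system.yaml"
        path.write_text(yaml.safe_dump(system.to_config()))
        clone = gk.AllostericToySystem.from_config(
            yaml.safe_load(path.read_text()))
        x = np.array([0.3, -0.2, 1.0, 0.5, 6.0])
        assert clone.energy(x) == pytest.approx(system.energy(x))

    def test_occupancy_indicator(self):
        system = gk.make_allosteric_toy()
        center = np.asarray(system.config["allo_center"])
        r = system.config["site_radius"]
        inside = center + [0.5 * r, 0.0]
        outside = center + [2.0 * r, 0.0]
        assert system.occupancy(np.vstack([inside, outside])).tolist() == [1, 0]


class TestExactPMF:
    def test_flat_potential_gives_zero_pmf(self):
        flat = gk.ToyPotential(
            dimensionality=1,
            energy=lambda x: 0.0,
            gradient=lambda x: np.zeros(1),
            domain_bounds=((-1.0, 1.0),),
        )
        pmf = exact_pmf(flat, np.linspace(-1, 1, 21))
        assert np.allclose(pmf.free_energy, 0.0, atol=1e-12)

    def test_symmetric_double_well_is_mirror_symmetric(self):
        dw = gk.make_double_well(6.0, 2.0, 0.0)
        pmf = exact_pmf(dw, np.linspace(-2, 2, 81))
        assert np.max(np.abs(pmf.free_energy - pmf.free_energy[::-1])) < 1e-6

    def test_harmonic_matches_closed_form(self):
        stiffness = 2.0
        pot = gk.make_harmonic(stiffness)
        pmf = exact_pmf(pot, np.linspace(-1.5, 1.5, 301))
        centers = pmf.centers(0)
        expected = 0.5 * stiffness * centers**2
        shifted = pmf.free_energy - pmf.value_at(0.0)
        assert np.max(np.abs(shifted - expected)) < 1e-4

    def test_grid_outside_domain_raises(self):
        dw = gk.make_double_well(6.0, 2.0, 0.0)
        with pytest.raises(ValueError, match="domain"):
            exact_pmf(dw, np.linspace(-10, 10, 21))

    def test_probabilities_normalized(self):
        dw = gk.make_double_well(6.0, 2.0, 1.0)
        pmf = exact_pmf(dw, np.linspace(-2, 2, 41))
        assert pmf.reweighted_probability.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.nanmin(pmf.free_energy) == pytest.approx(0.0, abs=1e-12)
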