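"""Nonbonded energetics, switching functions and Metropolis sampling."""

import math

import numpy as np
import pytest

from saisolv import (NonbondedSettings, ValidationError, harmonic_reference,
                     lj_energy, lj_force, load_trajectory, make_toy_solute,
                     make_solvated_system, mc_sample, softcore_lj_energy,
                     switching_factor, total_energy, vacuum_system,
                     write_trajectory)
from saisolv.engine import (KB, StatePotential, Trajectory, build_site_table,
                            softcore_lj_dudl)
from saisolv.schedule import build_schedule


class TestSwitchingFactor:
    @pytest.mark.parametrize("kind", ["OMM_VSWI", "VSWI"])
    def test_boundaries(self, kind):
        s = NonbondedSettings(r_on=10.0, r_off=12.0, switch_kind=kind)
        assert switching_factor(10.0, s) == pytest.approx(1.0)
        assert switching_factor(12.0, s) == pytest.approx(0.0, abs=1e-12)

    def test_smoothstep_midpoint_symmetry(self):
        s = NonbondedSettings(r_on=10.0, r_off=12.0, switch_kind="OMM_VSWI")
        assert switching_factor(11.0, s) == pytest.approx(0.5)

    def test_force_switch_has_no_multiplier(self):
        s = NonbondedSettings(switch_kind="VFSW")
        assert math.isnan(switching_factor(11.0, s))

    def test_bad_window_rejected(self):
        with pytest.raises(ValidationError):
            NonbondedSettings(r_on=12.0, r_off=10.0)

    @pytest.mark.parametrize("kind", ["OMM_VSWI", "VSWI"])
    def test_continuity_at_window_edges(self, kind):
        s = NonbondedSettings(r_on=10.0, r_off=12.0, switch_kind=kind)
        eps = 1e-7
        for r0 in (10.0, 12.0):
            below = lj_energy(r0 - eps, 3.8, 0.15, s)
            above = lj_energy(r0 + eps, 3.8, 0.15, s)
            assert abs(above - below) < 1e-9


class TestLJEnergy:
    def test_well_depth_without_switch(self):
        assert lj_energy(3.8, 3.8, 0.15, None) == pytest.approx(-0.15)

    @pytest.mark.parametrize("kind", ["OMM_VSWI", "VSWI", "VFSW", "NONE"])
    def test_zero_beyond_cutoff(self, kind):
        s = NonbondedSettings(switch_kind=kind)
        assert lj_energy(12.5, 3.8, 0.15, s) == 0.0

    def test_force_switch_force_is_continuous(self):
        """Numerical derivative of the VFSW potential matches the analytic
        force to 1e-6 kcal/mol/A across the switching region."""
        s = NonbondedSettings(r_on=10.0, r_off=12.0, switch_kind="VFSW")
        h = 1e-6
        for r in np.arange(9.9, 12.0, 0.01):
            numeric = -(lj_energy(r + h, 3.8, 0.15, s)
                        - lj_energy(r - h, 3.8, 0.15, s)) / (2 * h)
            analytic = lj_force(r, 3.8, 0.15, s)
            assert abs(numeric - analytic) < 1e-6

    def test_force_switch_force_vanishes_at_cutoff(self):
        s = NonbondedSettings(switch_kind="VFSW")
        assert lj_force(12.0 - 1e-9, 3.8, 0.15, s) == pytest.approx(
            0.0, abs=1e-6)


class TestSoftcore:
    def test_lam_one_recovers_plain_lj(self, small_settings):
        r = np.linspace(2.0, 9.0, 40)
        np.testing.assert_allclose(
            softcore_lj_energy(r, 1.0, 3.8, 0.15, 5.0, small_settings),
            lj_energy(r, 3.8, 0.15, small_settings), atol=1e-12)

    def test_lam_zero_is_zero_everywhere(self, small_settings):
        r = np.linspace(0.1, 9.0, 40)
        assert np.all(softcore_lj_energy(r, 0.0, 3.8, 0.15, 5.0,
                                         small_settings) == 0.0)

    def test_finite_at_contact(self):
        assert np.isfinite(softcore_lj_energy(1e-6, 0.5, 3.8, 0.15, 5.0))

    def test_dudl_matches_finite_difference(self, small_settings):
        h = 1e-6
        for lam in (0.2, 0.5, 0.8):
            for r in (2.5, 4.0, 7.0):
                numeric = (softcore_lj_energy(r, lam + h, 3.8, 0.15, 5.0,
                                              small_settings)
                           - softcore_lj_energy(r, lam - h, 3.8, 0.15, 5.0,
                                                small_settings)) / (2 * h)
                analytic = softcore_lj_dudl(r, lam, 3.8, 0.15, 5.0,
                                            small_settings)
                assert numeric == pytest.approx(analytic, abs=1e-6)


class TestHarmonicReference:
    def test_closed_forms(self):
        assert harmonic_reference(2.0, 300.0) - harmonic_reference(
            2.0, 300.0) == 0.0
        t = 303.15
        df = harmonic_reference(4 * 1.3, t) - harmonic_reference(1.3, t)
        assert df == pytest.approx(math.log(2.0))
        df = harmonic_reference(math.e**2 * 0.7, t) - harmonic_reference(
            0.7, t)
        assert df == pytest.approx(1.0)

    def test_nonpositive_force_constant_rejected(self):
        with pytest.raises(ValidationError):
            harmonic_reference(0.0, 300.0)


class TestTotalEnergy:
    def test_two_dummy_atoms_have_zero_energy(self, small_settings):
        from saisolv.chem_system import (AtomRecord, SoluteTopology,
                                         SolvatedSystem)
        atoms = (AtomRecord(0, "C", 0.0, 4.0, 0.0),
                 AtomRecord(1, "C", 0.0, 4.0, 0.0))
        topology = SoluteTopology(name="dummies", atoms=atoms,
                                  bonds=((0, 1),))
        system = SolvatedSystem(
            solute=topology, solute_coords=np.array([[8.0, 8.0, 8.0],
                                                     [8.0, 8.0, 11.0]]),
            water_coords=np.zeros((0, 3, 3)), box_edge=16.5, periodic=True)
        e = total_energy(system, None, small_settings)
        assert e.intra_solute == 0.0 and e.solute_solvent == 0.0

    def test_matches_brute_force_pair_sum(self, small_settings):
        """Random 10-particle box vs an independent O(N^2) double loop."""
        solute = make_toy_solute(4, 6, "chain", seed=21)
        system = make_solvated_system(solute, n_waters=0, box_edge=16.5,
                                      seed=21)
        rng = np.random.default_rng(5)
        coords = rng.uniform(0, system.box_edge, (10, 3))
        e = total_energy(system, None, small_settings, coords=coords)
        t = build_site_table(system)
        expected = 0.0
        for i in range(10):
            for j in range(i + 1, 10):
                if not t.allowed[i, j]:
                    continue
                d = coords[i] - coords[j]
                d -= system.box_edge * np.round(d / system.box_edge)
                r = float(np.linalg.norm(d))
                s = small_settings
                if r >= s.r_off:
                    continue
                x = max((r - s.r_on) / (s.r_off - s.r_on), 0.0)
                sw = 1 - 10 * x**3 + 15 * x**4 - 6 * x**5
                rm = 0.5 * (t.r_min[i] + t.r_min[j])
                ep = math.sqrt(t.epsilon[i] * t.epsilon[j])
                expected += ep * ((rm / r)**12 - 2 * (rm / r)**6) * sw
                expected += 332.0637 * t.charge[i] * t.charge[j] / r * sw
        nonbonded = e.total - e.bond
        assert nonbonded == pytest.approx(expected, abs=1e-8)

    def test_components_sum_to_total(self, tiny_aq_system, small_settings):
        e = total_energy(tiny_aq_system, None, small_settings)
        assert (e.solute_solvent + e.intra_solute + e.solvent_solvent
                + e.bond) == pytest.approx(e.total, abs=1e-10)

    def test_translation_invariance(self, tiny_aq_system, small_settings):
        t = build_site_table(tiny_aq_system)
        e0 = total_energy(tiny_aq_system, None, small_settings)
        shift = np.array([3.7, -1.2, 9.9])
        e1 = total_energy(tiny_aq_system, None, small_settings,
                          coords=t.positions + shift)
        assert e1.total == pytest.approx(e0.total, abs=1e-9)

    def test_box_too_small_rejected(self, tiny_aq_system):
        with pytest.raises(ValidationError):
            total_energy(tiny_aq_system, None,
                         NonbondedSettings(r_on=10.0, r_off=12.0))


class TestMCSampling:
    def test_identical_seeds_identical_frames(self, tiny_aq_system,
                                              small_settings):
        schedule = build_schedule(tiny_aq_system.solute)
        t1 = mc_sample(tiny_aq_system, schedule.states[0], small_settings,
                       n_sweeps=40, seed=7)
        t2 = mc_sample(tiny_aq_system, schedule.states[0], small_settings,
                       n_sweeps=40, seed=7)
        np.testing.assert_array_equal(t1.frames, t2.frames)

    def test_zero_temperature_limit_is_greedy(self, tiny_vac_system):
        """As beta -> inf the Metropolis chain only ever lowers the energy."""
        cold = NonbondedSettings(r_on=6.0, r_off=8.0, temperature=1e-9)
        schedule = build_schedule(tiny_vac_system.solute)
        pot = StatePotential(tiny_vac_system, schedule.states[0], cold)
        traj = mc_sample(tiny_vac_system, schedule.states[0], cold,
                         n_sweeps=60, seed=3, save_every=1)
        energies = [pot.total(traj.frames[i], None)
                    for i in range(traj.n_frames)]
        assert all(b <= a + 1e-9 for a, b in zip(energies, energies[1:]))

    def test_ideal_gas_positions_are_uniform(self, small_settings):
        """With all interactions off, wrapped positions are uniform: the
        mean coordinate matches box/2 within 3 standard errors."""
        solute = make_toy_solute(1, 0, "chain", seed=2)
        from saisolv.chem_system import AtomRecord, SoluteTopology
        from dataclasses import replace
        dummy = replace(solute, atoms=(replace(solute.atoms[0], charge=0.0,
                                               epsilon=0.0),))
        system = make_solvated_system(dummy, n_waters=0, box_edge=16.5,
                                      seed=2)
        traj = mc_sample(system, None, small_settings, n_sweeps=4000, seed=8,
                         save_every=10)
        xs = traj.frames[100:, 0, :].ravel()
        box = system.box_edge
        se = box / math.sqrt(12.0) / math.sqrt(len(xs) / 8.0)  # correlated
        assert abs(xs.mean() - box / 2.0) < 3.0 * se

    def test_acceptance_in_target_window(self, tiny_aq_system,
                                         small_settings):
        schedule = build_schedule(tiny_aq_system.solute)
        traj = mc_sample(tiny_aq_system, schedule.states[0], small_settings,
                         n_sweeps=300, seed=11)
        assert 0.2 <= traj.acceptance["water"] <= 0.6

    def test_bond_length_variance_matches_boltzmann(self, small_settings):
        """Detailed-balance smoke test: a lone harmonic bond samples
        var(d) = kB T / (2 k)."""
        from dataclasses import replace
        solute = make_toy_solute(2, 0, "chain", seed=4)
        neutral = replace(solute, atoms=tuple(
            replace(a, charge=0.0, epsilon=0.0) for a in solute.atoms))
        system = vacuum_system(neutral, seed=4)
        traj = mc_sample(system, None, small_settings, n_sweeps=6000, seed=5,
                         save_every=4)
        d = np.linalg.norm(traj.frames[200:, 0, :] - traj.frames[200:, 1, :],
                           axis=1)
        expected_var = KB * small_settings.temperature / (2.0 * 300.0)
        # 3-SE band from batch means over 8 blocks
        blocks = np.array_split(d, 8)
        block_vars = [np.var(b) for b in blocks]
        se = np.std(block_vars, ddof=1) / math.sqrt(len(blocks))
        assert abs(np.var(d) - expected_var) < 3.0 * se + 0.1 * expected_var


class TestTrajectoryIO:
    def test_round_trip(self, tiny_aq_system, small_settings, tmp_path):
        schedule = build_schedule(tiny_aq_system.solute)
        traj = mc_sample(tiny_aq_system, schedule.states[0], small_settings,
                         n_sweeps=20, seed=1, save_every=5)
        path = tmp_path / "traj.xyz"
        write_trajectory(traj, path)
        loaded = load_trajectory(path)
        assert loaded.n_frames == traj.n_frames
        np.testing.assert_allclose(loaded.frames, traj.frames, atol=1e-9)
        np.testing.assert_allclose(loaded.box_edges, traj.box_edges)
        assert loaded.state_index == traj.state_index

    def test_frames_are_wrapped(self, tiny_aq_system, small_settings):
        schedule = build_schedule(tiny_aq_system.solute)
        traj = mc_sample(tiny_aq_system, schedule.states[0], small_settings,
                         n_sweeps=50, seed=2, save_every=10)
        # every water O site lies inside the primary box
        ns = tiny_aq_system.n_solute_atoms
        o_sites = traj.frames[:, ns::3, :]
        assert np.all(o_sites >= 0.0) and np.all(
            o_sites < tiny_aq_system.box_edge)
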