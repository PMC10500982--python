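"""MBAR, TI and combination: oracles and invariants.

The independent MBAR oracle used here solves the same estimation problem
by direct minimization of the convex MBAR objective with scipy (BFGS with
analytic gradient) -- a different algorithmic route from the package's
self-consistent/Newton solver.
"""

import math
import warnings

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import logsumexp

from saisolv import (EnergyMatrix, FreeEnergyResult, OverlapWarning,
                     TIProfile, Trajectory, ValidationError,
                     aggregate_repeats, combine_asfe, discard_equilibration,
                     load_energy_matrix, mbar_covariance, mbar_delta_f,
                     mbar_solve, overlap_matrix, reduced_potential_matrix,
                     save_energy_matrix, ti_estimate)
from saisolv.engine import KB, NonbondedSettings, mc_sample
from saisolv.schedule import Schedule, StateSpec, build_schedule

BETA = 1.0 / (KB * 303.15)


def reference_mbar(u, n_k):
    """Independent MBAR: direct minimization of the convex objective
    F(f) = sum_n ln sum_k N_k exp(f_k - u_nk) - sum_k N_k f_k."""
    n_k = np.asarray(n_k, float)
    log_nk = np.log(n_k)

    def objective(f_free):
        f = np.concatenate([[0.0], f_free])
        a = f[None, :] - u + log_nk[None, :]
        val = logsumexp(a, axis=1).sum() - float(n_k @ f)
        w = np.exp(a - logsumexp(a, axis=1)[:, None])
        grad = w.sum(axis=0) - n_k
        return val, grad[1:]

    res = minimize(objective, np.zeros(u.shape[1] - 1), jac=True,
                   method="BFGS", options={"gtol": 1e-12, "maxiter": 2000})
    return np.concatenate([[0.0], res.x])


def harmonic_matrix(ks, n, seed, temperature=303.15):
    """Exact samples from 1-D harmonic states U_k = (1/2) k x^2."""
    beta = 1.0 / (KB * temperature)
    rng = np.random.default_rng(seed)
    xs = [rng.normal(0.0, math.sqrt(KB * temperature / k), n) for k in ks]
    x = np.concatenate(xs)
    u = np.column_stack([beta * 0.5 * k * x**2 for k in ks])
    return EnergyMatrix(u=u, n_k=np.array([n] * len(ks)), beta=beta)


class TestDiscardEquilibration:
    @pytest.mark.parametrize("n,fraction,kept", [
        (10000, 0.25, 7500),   # the production convention
        (8, 0.0, 8),
        (7, 0.25, 6),          # drop floor(0.25 * 7) = 1
    ])
    def test_floor_convention(self, n, fraction, kept):
        traj = Trajectory(frames=np.zeros((n, 1, 3)),
                          box_edges=np.full(n, 20.0), state_index=1, seed=0)
        assert discard_equilibration(traj, fraction).n_frames == kept

    def test_empty_trajectory_rejected(self):
        traj = Trajectory(frames=np.zeros((0, 1, 3)),
                          box_edges=np.zeros(0), state_index=1, seed=0)
        with pytest.raises(ValidationError):
            discard_equilibration(traj)


class TestReducedPotentialMatrix:
    def _schedule_and_trajs(self, system, settings, n_states=None,
                            sweeps=30):
        schedule = build_schedule(system.solute)
        if n_states is not None:
            schedule = Schedule(states=schedule.states[:n_states],
                                heavy_order=schedule.heavy_order,
                                solute_name=schedule.solute_name)
        trajs = [mc_sample(system, st, settings, n_sweeps=sweeps,
                           seed=10 + st.index, save_every=10)
                 for st in schedule.states]
        return schedule, trajs

    def test_identical_states_give_constant_rows(self, tiny_aq_system,
                                                 small_settings):
        n = tiny_aq_system.n_solute_atoms
        ones = tuple([1.0] * n)
        states = tuple(StateSpec(index=i + 1, charge_scale=ones,
                                 lj_scale=ones, block="charge")
                       for i in range(3))
        schedule = Schedule(states=states, heavy_order=(0,),
                            solute_name=tiny_aq_system.solute.name)
        traj = mc_sample(tiny_aq_system, states[0], small_settings,
                         n_sweeps=30, seed=1, save_every=10)
        matrix = reduced_potential_matrix([traj] * 3, schedule,
                                          tiny_aq_system, small_settings)
        assert np.allclose(matrix.u, matrix.u[:, :1])

    def test_shape_bookkeeping(self, tiny_aq_system, small_settings):
        schedule, trajs = self._schedule_and_trajs(tiny_aq_system,
                                                   small_settings)
        matrix = reduced_potential_matrix(trajs, schedule, tiny_aq_system,
                                          small_settings)
        assert matrix.u.shape == (sum(t.n_frames for t in trajs),
                                  schedule.n_states)
        assert matrix.n_k.sum() == matrix.u.shape[0]

    def test_missing_state_rejected(self, tiny_aq_system, small_settings):
        schedule, trajs = self._schedule_and_trajs(tiny_aq_system,
                                                   small_settings)
        with pytest.raises(ValidationError):
            reduced_potential_matrix(trajs[:-1], schedule, tiny_aq_system,
                                     small_settings)

    def test_dummied_atom_difference_is_its_pair_sum(self, tiny_aq_system,
                                                     small_settings):
        """Between two states differing by one dummied atom, the reduced
        potential difference equals beta times that atom's pair-energy sum
        (independent brute-force loop)."""
        from saisolv.engine import build_site_table, _pair_energies
        system = tiny_aq_system
        n = system.n_solute_atoms
        ones = [1.0] * n
        off = [1.0] * n
        target = 0
        off[target] = 0.0
        s1 = StateSpec(index=1, charge_scale=tuple([0.0] * n),
                       lj_scale=tuple(ones), block="heavy_lj")
        s2 = StateSpec(index=2, charge_scale=tuple([0.0] * n),
                       lj_scale=tuple(off), block="heavy_lj")
        schedule = Schedule(states=(s1, s2), heavy_order=(0,),
                            solute_name=system.solute.name)
        traj = mc_sample(system, s1, small_settings, n_sweeps=10, seed=3,
                         save_every=10)
        single = Trajectory(frames=traj.frames[:1],
                            box_edges=traj.box_edges[:1], state_index=1,
                            seed=3)
        matrix = reduced_potential_matrix([single, single], schedule,
                                          system, small_settings)
        du = matrix.u[0, 0] - matrix.u[0, 1]

        t = build_site_table(system)
        pos = single.frames[0]
        # under s1 the atom's LJ pairs are live and charges are all off
        removed = 0.0
        for j in range(t.n_sites):
            if j == target or not t.allowed[target, j]:
                continue
            d = pos[target] - pos[j]
            d -= system.box_edge * np.round(d / system.box_edge)
            r = float(np.linalg.norm(d))
            removed += float(_pair_energies(
                np.array([r]), np.array([0.0]),
                np.array([0.5 * (t.r_min[target] + t.r_min[j])]),
                np.array([math.sqrt(t.epsilon[target] * t.epsilon[j])]),
                small_settings, True)[0])
        assert du == pytest.approx(matrix.beta * removed, abs=1e-8)


class TestMBAR:
    def test_two_identical_states(self):
        rng = np.random.default_rng(0)
        u_col = rng.normal(5.0, 1.0, 400)
        matrix = EnergyMatrix(u=np.column_stack([u_col, u_col]),
                              n_k=np.array([200, 200]), beta=BETA)
        f = mbar_solve(matrix)
        assert abs(f[1] - f[0]) < 1e-10

    def test_harmonic_pair_recovers_ln2(self):
        matrix = harmonic_matrix([1.5, 6.0], 4000, seed=17)
        df, se = mbar_delta_f(matrix)
        assert abs(df - math.log(2.0)) < 3.0 * se

    def test_agrees_with_direct_minimization_oracle(self):
        """Self-consistent/Newton solution vs independent scipy direct
        minimization of the MBAR objective, random matrices, 1e-6."""
        rng = np.random.default_rng(23)
        for _ in range(5):
            n, k = 120, 4
            centers = rng.uniform(0.0, 3.0, k)
            u = rng.normal(0.0, 1.0, (n, k)) + centers[None, :]
            n_k = np.array([30, 40, 20, 30])
            matrix = EnergyMatrix(u=u, n_k=n_k, beta=BETA)
            f = mbar_solve(matrix)
            f_ref = reference_mbar(u, n_k)
            np.testing.assert_allclose(f, f_ref, atol=1e-6)

    def test_antisymmetry_and_cycle_closure(self):
        matrix = harmonic_matrix([1.0, 2.0, 4.0], 800, seed=5)
        f = mbar_solve(matrix)
        df01, df12, df20 = f[1] - f[0], f[2] - f[1], f[0] - f[2]
        assert df01 + df12 + df20 == pytest.approx(0.0, abs=1e-12)
        assert f[1] - f[0] == pytest.approx(-(f[0] - f[1]))

    def test_harmonic_recovery_over_random_pairs(self):
        """MBAR reproduces (1/2) ln(k2/k1) for 10 random force-constant
        pairs within 3 SE each."""
        rng = np.random.default_rng(99)
        for trial in range(10):
            k1, k2 = rng.uniform(0.5, 10.0, 2)
            matrix = harmonic_matrix([k1, k2], 2500, seed=1000 + trial)
            df, se = mbar_delta_f(matrix)
            assert abs(df - 0.5 * math.log(k2 / k1)) < 3.0 * se

    def test_zero_samples_rejected(self):
        matrix = EnergyMatrix(u=np.zeros((4, 2)), n_k=np.array([4, 0]),
                              beta=BETA)
        with pytest.raises(ValidationError):
            mbar_solve(matrix)


class TestOverlapMatrix:
    def test_identical_states_mix_uniformly(self):
        rng = np.random.default_rng(1)
        u_col = rng.normal(0.0, 1.0, 300)
        matrix = EnergyMatrix(u=np.column_stack([u_col] * 3),
                              n_k=np.array([100] * 3), beta=BETA)
        with warnings.catch_warnings():
            warnings.simplefilter("error", OverlapWarning)
            o = overlap_matrix(matrix)
        np.testing.assert_allclose(o, np.full((3, 3), 1.0 / 3.0), atol=1e-12)

    def test_disjoint_states_warn(self):
        """Two harmonic states with means 10 sigma apart: off-diagonal
        overlap ~ 0 and a warning is raised."""
        rng = np.random.default_rng(2)
        n = 300
        x1 = rng.normal(0.0, 1.0, n)
        x2 = rng.normal(10.0, 1.0, n)
        x = np.concatenate([x1, x2])
        u = np.column_stack([0.5 * x**2, 0.5 * (x - 10.0) ** 2])
        matrix = EnergyMatrix(u=u, n_k=np.array([n, n]), beta=BETA)
        with pytest.warns(OverlapWarning):
            o = overlap_matrix(matrix)
        assert o[0, 1] < 1e-6 and o[1, 0] < 1e-6

    def test_rows_sum_to_one(self):
        matrix = harmonic_matrix([1.0, 3.0, 9.0], 400, seed=8)
        o = overlap_matrix(matrix, warn=False)
        np.testing.assert_allclose(o.sum(axis=1), 1.0, atol=1e-8)


class TestTI:
    def _profile(self, fn, n=21, stderr=None):
        lam = np.linspace(0.0, 1.0, n)
        return TIProfile(lambdas=lam, dudl_means=fn(lam),
                         dudl_stderr=stderr)

    def test_constant_integrand(self):
        result = ti_estimate(self._profile(lambda x: np.full_like(x, 2.5)))
        assert result.delta_g == pytest.approx(2.5, abs=1e-12)

    def test_exact_for_cubics(self):
        result = ti_estimate(self._profile(lambda x: 3.0 * x**2))
        assert result.delta_g == pytest.approx(1.0, abs=1e-10)

    def test_quadratic_matches_simpson(self):
        from scipy.integrate import simpson
        lam = np.linspace(0.0, 1.0, 21)
        vals = 4.0 * lam**2 - lam + 0.3
        result = ti_estimate(TIProfile(lambdas=lam, dudl_means=vals))
        assert result.delta_g == pytest.approx(simpson(vals, x=lam),
                                               abs=1e-8)

    def test_duplicate_lambda_rejected(self):
        with pytest.raises(ValidationError):
            TIProfile(lambdas=np.array([0.0, 0.5, 0.5, 1.0]),
                      dudl_means=np.zeros(4))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            ti_estimate(TIProfile(lambdas=np.array([0.0, 0.4, 1.0]),
                                  dudl_means=np.zeros(3)))

    def test_stderr_propagates_through_weights(self):
        prof = self._profile(lambda x: x, stderr=np.full(21, 0.5))
        result = ti_estimate(prof)
        # the quadrature weights sum to 1, so the SE is below 0.5
        assert 0.0 < result.stderr < 0.5


class TestCombination:
    def test_arithmetic(self):
        vac = FreeEnergyResult(delta_g=5.0, stderr=0.1, leg="vacuum")
        aq = FreeEnergyResult(delta_g=10.0, stderr=0.2, leg="aqueous")
        res = combine_asfe(vac, aq, lrc=0.0)
        assert res.value == pytest.approx(-5.0)
        assert res.stderr == pytest.approx(math.sqrt(0.05))

    def test_identical_legs_give_lrc(self):
        leg = FreeEnergyResult(delta_g=3.0, stderr=0.0)
        assert combine_asfe(leg, leg, lrc=-0.4).value == pytest.approx(-0.4)

    def test_mismatched_solutes_rejected(self):
        vac = FreeEnergyResult(delta_g=1.0, stderr=0.0, solute="a")
        aq = FreeEnergyResult(delta_g=1.0, stderr=0.0, solute="b")
        with pytest.raises(ValidationError):
            combine_asfe(vac, aq)


class TestAggregateRepeats:
    def test_constant_repeats(self):
        assert aggregate_repeats([1.0, 1.0, 1.0, 1.0]) == (1.0, 0.0)

    def test_two_values(self):
        mean, sd = aggregate_repeats([0.0, 2.0])
        assert mean == 1.0 and sd == pytest.approx(math.sqrt(2.0))

    def test_single_repeat_rejected(self):
        with pytest.raises(ValidationError):
            aggregate_repeats([1.0])

    def test_repeat_sd_consistent_with_asymptotic_se(self):
        """SD over 4 independent harmonic repeats agrees with the MBAR
        asymptotic SE within a factor of 3."""
        dfs, ses = [], []
        for rep in range(4):
            matrix = harmonic_matrix([2.0, 8.0], 2000, seed=300 + rep)
            df, se = mbar_delta_f(matrix)
            dfs.append(df)
            ses.append(se)
        _, sd = aggregate_repeats(dfs)
        se = float(np.mean(ses))
        assert se / 3.0 < sd < 3.0 * se


class TestMatrixArchive:
    def test_round_trip(self, tmp_path):
        matrix = harmonic_matrix([1.0, 4.0], 50, seed=0)
        path = tmp_path / "matrix.tsv"
        save_energy_matrix(matrix, path)
        loaded = load_energy_matrix(path)
        np.testing.assert_allclose(loaded.u, matrix.u, atol=1e-12)
        np.testing.assert_array_equal(loaded.n_k, matrix.n_k)
        assert loaded.beta == pytest.approx(matrix.beta)
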