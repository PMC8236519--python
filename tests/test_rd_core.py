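"""Unit tests for the reaction–diffusion core."""

import numpy as np
import pytest
from scipy import optimize

from spinepattern import rd_core as rc
from spinepattern.params import Grid, ModelParams, SimSchedule, StabilityError, preset


def random_state(grid, rng, t=0.0):
    """Random positive state; H bounded away from zero so that explicit
    Euler at dt=0.05 stays finite over a short test run."""
    return rc.FieldState(
        rng.uniform(0.0, 1.5, grid.shape),
        rng.uniform(0.5, 2.0, grid.shape),
        rng.uniform(0.5, 2.0, grid.shape),
        rng.uniform(0.0, 1.5, grid.shape),
        t=t,
    )


class TestLaplacian:
    def test_constant_field_is_zero(self, small_grid):
        f = np.full(small_grid.shape, 3.7)
        assert np.all(rc.laplacian(f, small_grid) == 0)

    def test_zero_flux_conserves_total(self, small_grid, rng):
        f = rng.uniform(0, 1, small_grid.shape)
        total = rc.laplacian(f, small_grid).sum()
        assert abs(total) < 1e-12

    def test_matches_dense_neumann_operator(self, rng):
        """5-point mirror-boundary stencil == explicit dense matrix."""
        grid = Grid(nx=4, ny=4, dx=0.3)
        n = grid.nx * grid.ny
        L = np.zeros((n, n))
        for i in range(grid.ny):
            for j in range(grid.nx):
                row = i * grid.nx + j
                for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                    ii = min(max(i + di, 0), grid.ny - 1)
                    jj = min(max(j + dj, 0), grid.nx - 1)
                    L[row, ii * grid.nx + jj] += 1.0
                L[row, row] -= 4.0
        L /= grid.dx**2
        f = rng.uniform(0, 1, grid.shape)
        dense = (L @ f.ravel()).reshape(grid.shape)
        np.testing.assert_allclose(rc.laplacian(f, grid), dense, atol=1e-13)

    def test_shape_mismatch_rejected(self, small_grid):
        with pytest.raises(ValueError, match="shape"):
            rc.laplacian(np.zeros((2, 2)), small_grid)


class TestReactionRhs:
    def test_production_vanishes_at_zero_activator_and_cytoskeleton(self, small_grid):
        p = preset("fig4")
        state = rc.FieldState(
            np.zeros(small_grid.shape), np.ones(small_grid.shape),
            np.ones(small_grid.shape), np.zeros(small_grid.shape),
        )
        dA, dH, dS, dY = rc.reaction_rhs(state, p)
        assert np.all(dA == 0)
        np.testing.assert_allclose(dH, -p.nu)
        assert np.all(dY == 0)

    def test_hand_evaluated_value_at_unit_state(self, small_grid):
        # c*1*1/1 - mu*1 + (rho_A + delta_A)*1 = 0.002 - 0.16 + 0.02
        p = preset("fig4")
        ones = np.ones(small_grid.shape)
        state = rc.FieldState(ones, ones.copy(), ones.copy(), ones.copy())
        dA, _, _, _ = rc.reaction_rhs(state, p)
        np.testing.assert_allclose(dA, -0.138, atol=1e-15)

    def test_zero_at_reaction_fixed_point(self, small_grid):
        """A numerically solved uniform root of the four reaction equations."""
        p = preset("fig4")

        def rhs(v):
            st = rc.FieldState(*(np.full(small_grid.shape, x) for x in v))
            return [d.flat[0] for d in rc.reaction_rhs(st, p)]

        root = optimize.fsolve(rhs, [0.3, 0.01, 0.6, 1.0], full_output=False)
        residuals = rhs(root)
        if max(abs(r) for r in residuals) < 1e-9:  # fsolve found a true root
            state = rc.FieldState(*(np.full(small_grid.shape, x) for x in root))
            for d in rc.reaction_rhs(state, p):
                np.testing.assert_allclose(d, 0.0, atol=1e-8)

    def test_nonfinite_input_names_field(self, small_grid):
        a = np.ones(small_grid.shape)
        state = rc.FieldState(a, a.copy(), a.copy(), a.copy())
        state.S[0, 0] = np.nan
        with pytest.raises(FloatingPointError, match="S"):
            rc.reaction_rhs(state, preset("fig4"))


class TestStepEuler:
    def test_zero_dt_is_identity(self, small_grid, rng):
        state = random_state(small_grid, rng)
        new, clamped = rc.step_euler(state, preset("fig4"), small_grid, 0.0)
        assert clamped == 0
        for name in rc.FIELD_NAMES:
            np.testing.assert_array_equal(getattr(new, name), getattr(state, name))

    def test_uniform_trivial_fixed_point_is_stationary(self, small_grid):
        """(A,H,S,Y) = (0,0,c0/gamma,0) solves all four equations exactly."""
        p = preset("fig4")
        z = np.zeros(small_grid.shape)
        state = rc.FieldState(z, z.copy(), np.full(small_grid.shape, p.c0 / p.gamma), z.copy())
        new, _ = rc.step_euler(state, p, small_grid, 0.05)
        for name in rc.FIELD_NAMES:
            np.testing.assert_array_equal(getattr(new, name), getattr(state, name))

    def test_matches_hand_assembled_update(self, rng):
        """One step == old + dt*(reaction + D * laplacian), cell by cell."""
        grid = Grid(3, 3, dx=0.3)
        p = preset("fig4")
        state = random_state(grid, rng)
        dt = 0.02
        new, _ = rc.step_euler(state, p, grid, dt)
        dA, dH, dS, dY = rc.reaction_rhs(state, p)
        expect = {
            "A": state.A + dt * (dA + p.D_A * rc.laplacian(state.A, grid)),
            "H": state.H + dt * (dH + p.D_H * rc.laplacian(state.H, grid)),
            "S": state.S + dt * (dS + p.D_S * rc.laplacian(state.S, grid)),
            "Y": state.Y + dt * dY,
        }
        for name in rc.FIELD_NAMES:
            np.testing.assert_array_equal(
                getattr(new, name), np.maximum(expect[name], 0.0)
            )


class TestSimulate:
    def test_zero_steps_returns_initial_only(self, small_grid, rng):
        state = random_state(small_grid, rng)
        traj = rc.simulate(state, preset("fig4"), small_grid,
                           SimSchedule(dt=0.05, n_steps=0))
        assert len(traj) == 1
        assert traj.initial == state

    def test_composition_is_bitwise_exact(self, small_grid, rng):
        """n1+n2 steps equals n2 steps restarted from the n1-step state."""
        p = preset("fig4")
        state = random_state(small_grid, rng)
        whole = rc.simulate(state, p, small_grid,
                            SimSchedule(dt=0.05, n_steps=60, record_every=20))
        part1 = rc.simulate(state, p, small_grid,
                            SimSchedule(dt=0.05, n_steps=25, record_every=25))
        part2 = rc.simulate(part1.final, p, small_grid,
                            SimSchedule(dt=0.05, n_steps=35, record_every=35))
        assert whole.final == part2.final

    def test_compiled_loop_matches_reference_step(self, small_grid, rng):
        p = preset("fig4")
        state = random_state(small_grid, rng)
        ref = state.copy()
        for _ in range(40):
            ref, _ = rc.step_euler(ref, p, small_grid, 0.05)
        traj = rc.simulate(state, p, small_grid,
                           SimSchedule(dt=0.05, n_steps=40, record_every=40))
        for name in rc.FIELD_NAMES:
            np.testing.assert_array_equal(
                getattr(traj.final, name), getattr(ref, name)
            )
        assert traj.final.t == pytest.approx(ref.t)

    def test_bitwise_determinism_with_noise(self, small_grid, rng):
        p = preset("fig4")
        state = random_state(small_grid, rng)
        sched = SimSchedule(dt=0.05, n_steps=50, record_every=10,
                            noise_amp=0.01, rng_seed=7)
        t1 = rc.simulate(state, p, small_grid, sched)
        t2 = rc.simulate(state, p, small_grid, sched)
        assert all(a == b for a, b in zip(t1.snapshots, t2.snapshots))

    def test_diffusion_only_conserves_mass(self, small_grid, rng):
        """All reaction coefficients zero -> pure Neumann diffusion.

        Y starts at zero: its bistable self-switch has no coefficient, but
        it vanishes identically at Y = 0, leaving pure diffusion for A/H/S.
        """
        p = ModelParams(c=0, mu=0, nu=0, rho_A=0, rho_H=0, delta_A=0,
                        delta_H=0, c0=0, gamma=0, epsilon=0, d=0, e=0, f=0)
        state = random_state(small_grid, rng)
        state.Y[:] = 0.0
        traj = rc.simulate(state, p, small_grid,
                           SimSchedule(dt=0.05, n_steps=500, record_every=500))
        for name in rc.FIELD_NAMES:
            before = getattr(state, name).sum()
            after = getattr(traj.final, name).sum()
            assert after == pytest.approx(before, rel=1e-12)

    def test_stability_bound_enforced(self, small_grid):
        with pytest.raises(StabilityError):
            rc.simulate(
                rc.FieldState(*(np.ones(small_grid.shape) for _ in range(4))),
                preset("fig4"), small_grid, SimSchedule(dt=0.5, n_steps=1),
            )

    def test_uniform_state_stays_uniform(self, small_grid):
        state = rc.FieldState(*(np.full(small_grid.shape, v) for v in (1.0, 0.5, 1.0, 1.0)))
        traj = rc.simulate(state, preset("fig4"), small_grid,
                           SimSchedule(dt=0.05, n_steps=200, record_every=200))
        for name in rc.FIELD_NAMES:
            assert getattr(traj.final, name).std() < 1e-10


class TestInitialConditions:
    def test_single_spine_seed_geometry(self):
        state = rc.make_initial_single_spine()
        assert int((state.Y == 1.0).sum()) == 50
        seed = state.A == 2.0
        rows = np.nonzero(seed.any(axis=1))[0]
        cols = np.nonzero(seed.any(axis=0))[0]
        assert rows.max() == 99 and len(rows) == 10  # flush with the bottom
        assert len(cols) == 5
        assert np.all(state.H[seed] == 0.02)
        background = ~seed
        assert np.all(state.A[background] == 0.001)
        assert np.all(state.Y[background] == 0.0)
        assert np.all(state.S == 1.0)

    def test_dendrite_seed_geometry(self):
        state = rc.make_initial_dendrite()
        assert state.shape == (150, 200)
        assert int((state.Y == 1.0).sum()) == 50
        assert np.all(state.A[state.Y == 1.0] == 2.0)

    def test_repeat_call_identical(self):
        assert rc.make_initial_dendrite() == rc.make_initial_dendrite()

    def test_seed_larger_than_grid_rejected(self):
        with pytest.raises(ValueError, match="fit"):
            rc.make_initial_single_spine(Grid(4, 4))

    def test_dendrite_protocol_zero_stage2_steps(self):
        grid = Grid(nx=12, ny=12)
        s1 = SimSchedule(dt=0.05, n_steps=20, record_every=10)
        s2 = SimSchedule(dt=0.05, n_steps=0)
        traj = rc.run_dendrite_protocol(
            preset("fig2b"), preset("fig5-stage2"), grid, s1, s2
        )
        alone = rc.simulate(rc.make_initial_dendrite(grid), preset("fig2b"), grid, s1)
        assert traj.final == alone.final
        assert traj.stage_boundary == len(alone.snapshots)


class TestProtocolSanity:
    def test_halving_dt_changes_final_Y_below_one_percent(self):
        """Time-step refinement check for the standard mushroom condition."""
        p = preset("fig4", epsilon=0.01)
        grid = Grid(100, 100)
        coarse = rc.run_single_spine(
            p, grid, SimSchedule(dt=0.05, n_steps=14_000, record_every=14_000))
        fine = rc.run_single_spine(
            p, grid, SimSchedule(dt=0.025, n_steps=28_000, record_every=28_000))
        diff = np.abs(coarse.final.Y - fine.final.Y).max()
        assert diff < 0.01 * fine.final.Y.max()

    def test_no_negative_clamping_under_default_protocol(self):
        p = preset("fig4", epsilon=0.05)
        traj = rc.run_single_spine(p)
        assert traj.clamp_count == 0
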