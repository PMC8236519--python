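"""Reaction–diffusion system: right-hand side, stepping and simulation protocols.

The dynamics are

    dA/dt = c A^2 S / H - mu A + (rho_A + delta_A) Y + D_A lap(A)
    dH/dt = c A^2 S     - nu H + (rho_H + delta_H) Y + D_H lap(H)
    dS/dt = c0 - gamma S - epsilon Y S               + D_S lap(S)
    dY/dt = d A - e Y + Y^2 / (1 + f Y^2)

integrated by explicit forward Euler on a regular grid with zero-flux
(mirror) boundaries.  The activator equation divides by ``H``; ``H`` is
clamped to ``H_FLOOR`` inside that denominator only, since the background
initial inhibitor level (0.001) makes raw division fragile.  Negative values
produced by an Euler undershoot are clamped to zero and counted rather than
treated as fatal.

Two simulation protocols are provided: a single spine growing from a small
seed rectangle on a square grid, and a two-stage dendrite protocol in which a
trunk first grows under one parameter set and spines then sprout from it
under another.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .params import Grid, ModelParams, SimSchedule

logger = logging.getLogger(__name__)

#: Floor applied to H inside the A-equation denominator.
H_FLOOR = 1e-6

#: Seed ("black region") and background ("white region") initial values.
SEED_VALUES = {"A": 2.0, "H": 0.02, "S": 1.0, "Y": 1.0}
BACKGROUND_VALUES = {"A": 0.001, "H": 0.001, "S": 1.0, "Y": 0.0}

FIELD_NAMES = ("A", "H", "S", "Y")


@dataclass
class FieldState:
    """The four scalar fields on a grid at a single time."""

    A: np.ndarray
    H: np.ndarray
    S: np.ndarray
    Y: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        shape = self.A.shape
        for name in FIELD_NAMES:
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            if arr.shape != shape:
                raise ValueError(
                    f"field {name} has shape {arr.shape}, expected {shape}"
                )
            setattr(self, name, arr)
        self.require_finite()

    @property
    def shape(self) -> tuple[int, int]:
        return self.A.shape

    def fields(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in FIELD_NAMES}

    def copy(self) -> "FieldState":
        return FieldState(
            self.A.copy(), self.H.copy(), self.S.copy(), self.Y.copy(), self.t
        )

    def require_finite(self) -> None:
        for name in FIELD_NAMES:
            if not np.all(np.isfinite(getattr(self, name))):
                raise FloatingPointError(f"field {name} contains non-finite values")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FieldState):
            return NotImplemented
        return self.t == other.t and all(
            np.array_equal(getattr(self, n), getattr(other, n)) for n in FIELD_NAMES
        )


@dataclass
class Trajectory:
    """Ordered snapshots of a simulation plus the configuration that made it."""

    snapshots: list[FieldState]
    params: ModelParams
    grid: Grid
    schedule: SimSchedule
    clamp_count: int = 0
    stage_boundary: int | None = None  # snapshot index starting stage 2
    stage2_params: ModelParams | None = None

    def __post_init__(self) -> None:
        times = self.times
        if np.any(np.diff(times) <= 0):
            raise ValueError("snapshot times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.snapshots])

    @property
    def initial(self) -> FieldState:
        return self.snapshots[0]

    @property
    def final(self) -> FieldState:
        return self.snapshots[-1]

    def __len__(self) -> int:
        return len(self.snapshots)


def laplacian(field: np.ndarray, grid: Grid) -> np.ndarray:
    """5-point Laplacian with zero-flux (mirror) boundaries, scaled by 1/dx^2."""
    field = np.asarray(field, dtype=np.float64)
    if field.shape != grid.shape:
        raise ValueError(f"field shape {field.shape} != grid shape {grid.shape}")
    p = np.pad(field, 1, mode="edge")
    lap = (
        p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:] - 4.0 * field
    ) * (1.0 / grid.dx**2)
    return lap


def reaction_rhs(
    state: FieldState, params: ModelParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise reaction terms (no diffusion) for the four fields."""
    state.require_finite()
    A, H, S, Y = state.A, state.H, state.S, state.Y
    p = params
    H_safe = np.maximum(H, H_FLOOR)
    auto = p.c * A * A * S
    dA = auto / H_safe - p.mu * A + (p.rho_A + p.delta_A) * Y
    dH = auto - p.nu * H + (p.rho_H + p.delta_H) * Y
    dS = p.c0 - p.gamma * S - p.epsilon * Y * S
    dY = p.d * A - p.e * Y + Y * Y / (1.0 + p.f * Y * Y)
    return dA, dH, dS, dY


def step_euler(
    state: FieldState,
    params: ModelParams,
    grid: Grid,
    dt: float,
) -> tuple[FieldState, int]:
    """One explicit forward-Euler step.

    Returns the new state and the number of cells clamped from negative
    values to zero.  Reference implementation; :func:`simulate` runs the same
    arithmetic in a compiled loop.
    """
    dA, dH, dS, dY = reaction_rhs(state, params)
    new = FieldState(
        state.A + dt * (dA + params.D_A * laplacian(state.A, grid)),
        state.H + dt * (dH + params.D_H * laplacian(state.H, grid)),
        state.S + dt * (dS + params.D_S * laplacian(state.S, grid)),
        state.Y + dt * dY,
        state.t + dt,
    )
    clamped = 0
    for name in FIELD_NAMES:
        arr = getattr(new, name)
        neg = arr < 0.0
        clamped += int(np.count_nonzero(neg))
        arr[neg] = 0.0
    return new, clamped


def _apply_initial_noise(state: FieldState, schedule: SimSchedule) -> FieldState:
    if schedule.noise_amp <= 0:
        return state
    rng = np.random.default_rng(schedule.rng_seed)
    out = state.copy()
    for name in FIELD_NAMES:
        arr = getattr(out, name)
        arr += schedule.noise_amp * rng.uniform(-1.0, 1.0, size=arr.shape)
        np.clip(arr, 0.0, None, out=arr)
    return out


def simulate(
    initial: FieldState,
    params: ModelParams,
    grid: Grid,
    schedule: SimSchedule,
) -> Trajectory:
    """Integrate the system for ``schedule.n_steps`` steps.

    Snapshots are recorded every ``schedule.record_every`` steps (the initial
    state and the final state are always included).  Deterministic: the RNG
    seed is consumed only when ``noise_amp > 0``.
    """
    if initial.shape != grid.shape:
        raise ValueError(
            f"initial state shape {initial.shape} != grid shape {grid.shape}"
        )
    schedule.validate(grid, params)
    start = _apply_initial_noise(initial, schedule)
    snapshots = [start.copy()]
    if schedule.n_steps == 0:
        return Trajectory(snapshots, params, grid, schedule)

    p = params
    coeffs = np.array(
        [
            p.c, p.mu, p.nu, p.rho_A + p.delta_A, p.rho_H + p.delta_H,
            p.c0, p.gamma, p.epsilon, p.D_A, p.D_H, p.D_S,
            p.d, p.e, p.f,
        ],
        dtype=np.float64,
    )
    A, H, S, Y = (start.A.copy(), start.H.copy(), start.S.copy(), start.Y.copy())
    clamp_total = 0
    t = start.t
    steps_done = 0
    wall_start = time.perf_counter()
    while steps_done < schedule.n_steps:
        chunk = min(schedule.record_every, schedule.n_steps - steps_done)
        clamps = _kernels.run_steps(
            A, H, S, Y, coeffs, grid.dx, schedule.dt, chunk, H_FLOOR
        )
        if clamps < 0:
            step = steps_done + (-clamps)
            raise FloatingPointError(
                f"non-finite field value produced at step {step}"
            )
        clamp_total += clamps
        steps_done += chunk
        t = start.t + steps_done * schedule.dt
        snapshots.append(FieldState(A.copy(), H.copy(), S.copy(), Y.copy(), t))
    if logger.isEnabledFor(logging.DEBUG):
        wall = time.perf_counter() - wall_start
        last, prev = snapshots[-1], snapshots[-2] if len(snapshots) > 1 else snapshots[-1]
        dt_snap = max(last.t - prev.t, schedule.dt)
        max_dY = float(np.abs(last.Y - prev.Y).max()) / dt_snap
        logger.debug(
            "simulate: %d steps, t=%.6g, clamps=%d, max|dY/dt|=%.3g, "
            "%.1f ms / 1000 steps",
            schedule.n_steps, t, clamp_total, max_dY,
            1000.0 * wall / max(schedule.n_steps, 1) * 1000.0,
        )
    return Trajectory(snapshots, params, grid, schedule, clamp_count=clamp_total)


def _seed_state(grid: Grid, seed_w: int, seed_h: int) -> FieldState:
    """Background-valued state with a seed rectangle flush with the bottom edge.

    Rows are indexed top-to-bottom (raster convention), so "bottom" means the
    last rows.  The seed is horizontally centred.
    """
    if seed_w > grid.nx or seed_h > grid.ny:
        raise ValueError(
            f"seed {seed_w}x{seed_h} does not fit grid {grid.nx}x{grid.ny}"
        )
    fields = {}
    for name in FIELD_NAMES:
        arr = np.full(grid.shape, BACKGROUND_VALUES[name], dtype=np.float64)
        fields[name] = arr
    col0 = (grid.nx - seed_w) // 2
    for name in FIELD_NAMES:
        fields[name][grid.ny - seed_h :, col0 : col0 + seed_w] = SEED_VALUES[name]
    return FieldState(**fields, t=0.0)


def make_initial_single_spine(grid: Grid | None = None) -> FieldState:
    """Initial state for the single-spine protocol.

    A 10 x 5 (rows x cols) seed, i.e. 5 cells wide and 10 tall, bottom-centred
    on a 100 x 100 grid.  A seed no wider than the inhibitor's lateral range
    carries a single activator peak at its tip, so one spine grows upward;
    wider seeds split the peak to the corners.
    """
    grid = grid or Grid(100, 100)
    return _seed_state(grid, seed_w=5, seed_h=10)


def make_initial_dendrite(grid: Grid | None = None) -> FieldState:
    """Initial state for the dendrite protocol.

    A 5-wide x 10-tall seed bottom-centred on a 150 x 200 (rows x cols)
    grid — the same narrow upright rectangle as the single-spine seed, for
    the same reason: only a seed narrower than the inhibitor's range grows a
    single upward trunk.
    """
    grid = grid or Grid(nx=200, ny=150)
    return _seed_state(grid, seed_w=5, seed_h=10)


def default_spine_schedule(**overrides) -> SimSchedule:
    """Schedule under which the standard-condition single spine is fully formed.

    t_end = 700: the low-consumption (mushroom) spine has formed and stalled,
    while fast-growing thin spines have not yet sprouted secondary laterals
    or reached the far boundary.
    """
    kw = dict(dt=0.05, n_steps=14_000, record_every=2_000)
    kw.update(overrides)
    return SimSchedule(**kw)


def default_dendrite_schedules(**overrides) -> tuple[SimSchedule, SimSchedule]:
    """(stage 1, stage 2) schedules for the dendrite protocol."""
    kw = dict(dt=0.05, n_steps=30_000, record_every=3_000)
    kw.update(overrides)
    s = SimSchedule(**kw)
    return s, s


def run_single_spine(
    params: ModelParams,
    grid: Grid | None = None,
    schedule: SimSchedule | None = None,
) -> Trajectory:
    """Single-spine protocol: simulate from the 10x5 seed rectangle."""
    grid = grid or Grid(100, 100)
    schedule = schedule or default_spine_schedule()
    return simulate(make_initial_single_spine(grid), params, grid, schedule)


def run_dendrite_protocol(
    stage1: ModelParams,
    stage2: ModelParams,
    grid: Grid | None = None,
    schedule1: SimSchedule | None = None,
    schedule2: SimSchedule | None = None,
) -> Trajectory:
    """Two-stage dendrite protocol.

    Stage 1 grows a trunk from the 5x10 seed; stage 2 continues from the
    trunk under spine-growth parameters.  The returned trajectory is the
    concatenation, with ``stage_boundary`` marking the first stage-2 snapshot
    index and ``stage2_params`` the stage-2 coefficients.
    """
    grid = grid or Grid(nx=200, ny=150)
    if schedule1 is None or schedule2 is None:
        d1, d2 = default_dendrite_schedules()
        schedule1 = schedule1 or d1
        schedule2 = schedule2 or d2
    traj1 = simulate(make_initial_dendrite(grid), stage1, grid, schedule1)
    traj2 = simulate(traj1.final, stage2, grid, schedule2)
    snapshots = traj1.snapshots + traj2.snapshots[1:]
    return Trajectory(
        snapshots,
        stage1,
        grid,
        schedule1,
        clamp_count=traj1.clamp_count + traj2.clamp_count,
        stage_boundary=len(traj1.snapshots),
        stage2_params=stage2,
    )
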