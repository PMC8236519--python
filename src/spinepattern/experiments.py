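"""Scripted computational experiments: parameter sweeps with tabular outputs.

Three experiments mirror the questions the model answers:

* ``sweep_epsilon_shapes`` — how the substrate-consumption rate ``epsilon``
  (neuron activity) sets the shape class of a single spine;
* ``sweep_exogenous_density`` — how exogenous activator/inhibitor supply
  sets the density of spines along a dendrite;
* ``wavelength_vs_exogenous`` — the linear-stability mechanism: the Turing
  wavelength measured at spine-nucleation sites of the same dendrite runs.

Every sweep row carries enough provenance (preset, swept value, schedule,
seed) to re-run that single condition bit-identically.

Density protocol.  Lateral spines along a simulated dendrite merge distally
into a connected web soon after nucleation (their arbors touch), so counting
connected components conflates density with growth stage.  Two conventions
make the count well defined: (i) each condition is measured when its newborn
spine area first reaches a fixed target (growth-stage matching — conditions
grow at very different speeds), and (ii) spines are counted as runs of
newborn cells crossing the two vertical lines a fixed distance from the
trunk, which is immune to distal merging.  The apical region (where the
trunk tip meets the boundary) and the basal rows are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd

from . import morphometry as mm
from . import rd_core as rc
from . import turing as tg
from .params import Grid, ModelParams, SimSchedule, preset

#: Seed-top row of the default single-spine protocol (10-tall seed on 100 rows).
SPINE_BASE_ROW = 90

#: Default epsilon scan: fine where the mushroom/stubby boundaries lie,
#: coarse across the wide thin interval.
DEFAULT_EPS_SCAN = tuple(np.round(np.arange(0.01, 0.051, 0.01), 3)) + tuple(
    np.round(np.arange(0.10, 0.91, 0.05), 3)
)


def classify_single_spine(
    params: ModelParams,
    grid: Grid | None = None,
    schedule: SimSchedule | None = None,
) -> mm.SpineMetrics:
    """Run the single-spine protocol and classify the newborn spine."""
    grid = grid or Grid(100, 100)
    traj = rc.run_single_spine(params, grid, schedule)
    mask = mm.newborn_mask(traj.final.Y, SPINE_BASE_ROW, grid.dx)
    return mm.classify_spine(mask)


def sweep_epsilon_shapes(
    eps_values: Sequence[float] = DEFAULT_EPS_SCAN,
    delta_A: float = 0.01,
    delta_H: float = 0.00005,
    preset_name: str = "fig2a",
    schedule: SimSchedule | None = None,
) -> pd.DataFrame:
    """Classify single-spine outcomes along an epsilon scan.

    Returns one row per epsilon, ordered by epsilon, with the measured
    geometry, RAW/RCW and shape class.  Per-row failures are flagged in the
    ``error`` column rather than aborting the sweep.
    """
    schedule = schedule or rc.default_spine_schedule()
    rows = []
    for eps in sorted(eps_values):
        base = dict(
            epsilon=eps, delta_A=delta_A, delta_H=delta_H,
            preset=preset_name, n_steps=schedule.n_steps, dt=schedule.dt,
            seed=schedule.rng_seed,
        )
        try:
            p = preset(preset_name, epsilon=eps, delta_A=delta_A, delta_H=delta_H)
            met = classify_single_spine(p, schedule=schedule)
            rows.append({**base, "h": met.h, "w_head": met.w_head,
                         "w_neck": met.w_neck, "raw": met.raw, "rcw": met.rcw,
                         "shape_class": met.shape_class, "error": None})
        except Exception as exc:  # noqa: BLE001 - flagged per row
            rows.append({**base, "h": None, "w_head": None, "w_neck": None,
                         "raw": None, "rcw": None, "shape_class": None,
                         "error": str(exc)})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# dendrite density experiment
# --------------------------------------------------------------------------

#: Stage-1 trunk schedule: the trunk tip reaches the far boundary and growth
#: stalls at ~40000 time units, leaving no free tip to split in stage 2.
TRUNK_STEPS = 800_000


@dataclass(frozen=True)
class DensityProtocol:
    """Measurement conventions of the dendrite density experiment.

    Conditions grow at very different speeds, so each is measured at a
    matched growth stage: when its *protruding* newborn area (newborn cells
    at least ``sheath_margin`` px outside the trunk band — strongly
    inhibited conditions thicken the trunk into a sheath without ever
    protruding) first reaches ``area_target``, capped at ``t_max`` time
    units for conditions whose pattern is largely suppressed.
    """

    area_target: int = 400        # protruding newborn px triggering measurement
    sheath_margin: int = 2        # px around the band not counted as protruding
    t_max: float = 4000.0         # cap on stage-2 simulated time
    chunk_steps: int = 400        # stepping/recording granularity
    probe_dist: int = 5           # distance (px) of the counting lines
    top_excl: int = 12            # apical rows excluded from counting
    bot_excl: int = 5             # basal rows excluded from counting
    noise_amp: float = 0.01       # symmetry-breaking initial perturbation
    seeds: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8)
    dt: float = 0.05


@lru_cache(maxsize=2)
def grow_trunk(
    grid: Grid | None = None,
    n_steps: int = TRUNK_STEPS,
    dt: float = 0.05,
) -> rc.FieldState:
    """Stage 1: grow the dendrite trunk from the seed rectangle (cached)."""
    grid = grid or Grid(nx=200, ny=150)
    sched = SimSchedule(dt=dt, n_steps=n_steps, record_every=n_steps)
    traj = rc.simulate(rc.make_initial_dendrite(grid), preset("fig2b"), grid, sched)
    return traj.final


def count_lateral_spines(
    mask: np.ndarray,
    base_mask: np.ndarray,
    trunk_band: tuple[int, int],
    probe_dist: int = 5,
    top_excl: int = 12,
    bot_excl: int = 5,
) -> int:
    """Number of newborn laterals crossing lines ``probe_dist`` px from the trunk."""
    newborn = np.asarray(mask, bool) & ~np.asarray(base_mask, bool)
    lo, hi = trunk_band
    total = 0
    for col in (lo - probe_dist, hi + probe_dist - 1):
        if not 0 <= col < newborn.shape[1]:
            continue
        colv = newborn[:, col].copy()
        if top_excl:
            colv[:top_excl] = False
        if bot_excl:
            colv[-bot_excl:] = False
        total += len(mm._row_runs(colv))
    return total


@dataclass
class DensityOutcome:
    """Result of one dendrite density condition (one seed)."""

    count: int
    newborn_area: int
    t_measured: float
    trunk_band: tuple[int, int]
    final_state: rc.FieldState
    strip_S: np.ndarray  # (time, rows, strip cols) around the trunk
    strip_Y: np.ndarray
    strip_cols: tuple[int, int]


def run_density_condition(
    params2: ModelParams,
    stage1: rc.FieldState | None = None,
    grid: Grid | None = None,
    protocol: DensityProtocol = DensityProtocol(),
    seed: int = 1,
) -> DensityOutcome:
    """Stage 2 of the dendrite protocol under one parameter condition.

    Steps in chunks from the trunk state, recording an S/Y strip around the
    trunk, until the protruding newborn area reaches
    ``protocol.area_target`` and at least one lateral has crossed the
    counting lines (or ``t_max`` elapses).  The reported count is the
    maximum line-crossing count over the run: laterals fuse at their bases
    soon after outgrowth, so the maximum counts each spine that ever
    distinctly protruded.
    """
    grid = grid or Grid(nx=200, ny=150)
    if stage1 is None:
        stage1 = grow_trunk(grid)
    base_mask = mm.cell_mask(stage1.Y)
    band = mm.trunk_band_from_mask(base_mask)
    c0 = max(band[0] - 20, 0)
    c1 = min(band[1] + 20, grid.nx)

    state = stage1.copy()
    strips_S = [state.S[:, c0:c1].copy()]
    strips_Y = [state.Y[:, c0:c1].copy()]
    first = SimSchedule(
        dt=protocol.dt, n_steps=protocol.chunk_steps,
        record_every=protocol.chunk_steps,
        noise_amp=protocol.noise_amp, rng_seed=seed,
    )
    later = SimSchedule(
        dt=protocol.dt, n_steps=protocol.chunk_steps,
        record_every=protocol.chunk_steps,
    )
    elapsed = 0.0
    sched = first
    counts = []
    while True:
        state = rc.simulate(state, params2, grid, sched).final
        sched = later
        elapsed += protocol.chunk_steps * protocol.dt
        strips_S.append(state.S[:, c0:c1].copy())
        strips_Y.append(state.Y[:, c0:c1].copy())
        counts.append(count_lateral_spines(
            mm.cell_mask(state.Y), base_mask, band,
            protocol.probe_dist, protocol.top_excl, protocol.bot_excl,
        ))
        newborn = mm.cell_mask(state.Y) & ~base_mask
        protruding = newborn.copy()
        protruding[:, max(band[0] - protocol.sheath_margin, 0) :
                   band[1] + protocol.sheath_margin] = False
        area = int(protruding.sum())
        matured = area >= protocol.area_target and max(counts) > 0
        if matured or elapsed >= protocol.t_max:
            break
    return DensityOutcome(
        count=max(counts), newborn_area=area, t_measured=elapsed,
        trunk_band=band, final_state=state, strip_S=np.stack(strips_S),
        strip_Y=np.stack(strips_Y), strip_cols=(c0, c1),
    )


def _mean_count(
    params2: ModelParams,
    stage1: rc.FieldState,
    grid: Grid,
    protocol: DensityProtocol,
) -> tuple[float, list[DensityOutcome]]:
    outs = [
        run_density_condition(params2, stage1, grid, protocol, seed)
        for seed in protocol.seeds
    ]
    return float(np.mean([o.count for o in outs])), outs


def sweep_exogenous_density(
    delta_A_values: Sequence[float] = (0, 0.01, 0.02, 0.03, 0.04),
    delta_H_values: Sequence[float] = (0, 0.00005, 0.0001, 0.00015, 0.0002),
    eps_values: Sequence[float] = (0.5, 1.0, 1.5, 2.0, 2.5),
    protocol: DensityProtocol = DensityProtocol(),
    grid: Grid | None = None,
    stage1: rc.FieldState | None = None,
) -> pd.DataFrame:
    """Dendrite spine counts across the three density sweeps.

    One row per condition; ``spine_count`` is the mean line-crossing count
    over the protocol's noise seeds, ``density`` divides it by the trunk
    length.  The three sweeps vary delta_A (at delta_H=5e-5, eps=1),
    delta_H (at delta_A=0.01, eps=1) and eps (at the standard deltas).
    """
    grid = grid or Grid(nx=200, ny=150)
    if stage1 is None:
        stage1 = grow_trunk(grid)
    rows = []
    sweeps = (
        [("delta_A", v, {"delta_A": v}) for v in sorted(delta_A_values)]
        + [("delta_H", v, {"delta_H": v}) for v in sorted(delta_H_values)]
        + [("epsilon", v, {"epsilon": v}) for v in sorted(eps_values)]
    )
    for swept, value, kw in sweeps:
        p2 = preset("fig5-stage2", **kw)
        try:
            mean, outs = _mean_count(p2, stage1, grid, protocol)
            band = outs[0].trunk_band
            trunk_len = stage1.Y.shape[0] * grid.dx
            rows.append({
                "swept": swept, "value": value, "spine_count": mean,
                "counts_per_seed": tuple(o.count for o in outs),
                "newborn_area": tuple(o.newborn_area for o in outs),
                "t_measured": tuple(o.t_measured for o in outs),
                "density": mean / trunk_len, "preset": "fig5-stage2",
                "seeds": protocol.seeds, "error": None,
            })
        except Exception as exc:  # noqa: BLE001
            rows.append({"swept": swept, "value": value, "spine_count": None,
                         "counts_per_seed": None, "newborn_area": None,
                         "t_measured": None, "density": None,
                         "preset": "fig5-stage2", "seeds": protocol.seeds,
                         "error": str(exc)})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Turing wavelength experiment
# --------------------------------------------------------------------------

def nucleation_wavelength(
    outcome: DensityOutcome,
    params2: ModelParams,
    stage1: rc.FieldState,
) -> tuple[float, int]:
    """Median Turing wavelength over spine-nucleation sites of one run.

    For every cell (in the recorded strip) whose cytoskeleton switches on
    during stage 2, the recorded (S, Y) curve is tested against the Turing
    instability space; the wavelength is computed at the *last* in-space
    curve point of each cell (the deterministic analogue of picking the
    intersection by eye) and the median over cells is returned, with the
    number of contributing cells.
    """
    S_arr, Y_arr = outcome.strip_S, outcome.strip_Y
    base = mm.cell_mask(stage1.Y)[:, outcome.strip_cols[0] : outcome.strip_cols[1]]
    flipped = (Y_arr[-1] > 0.5) & (Y_arr[0] < 0.5) & ~base
    Ls = []
    for r, c in zip(*np.nonzero(flipped)):
        s_curve, y_curve = S_arr[:, r, c], Y_arr[:, r, c]
        best = None
        for i in range(len(s_curve)):
            if 0.05 <= y_curve[i] <= 0.95 and tg.is_turing_unstable(
                s_curve[i], y_curve[i], params2, check_consistency=False
            ):
                best = i
        if best is not None:
            _, _, L = tg.turing_wavelength(s_curve[best], y_curve[best], params2)
            Ls.append(L)
    if not Ls:
        return float("nan"), 0
    return float(np.median(Ls)), len(Ls)


def wavelength_vs_exogenous(
    delta_A_values: Sequence[float] = (0, 0.01, 0.02),
    delta_H_values: Sequence[float] = (0, 0.00005, 0.0001),
    protocol: DensityProtocol = DensityProtocol(),
    grid: Grid | None = None,
    stage1: rc.FieldState | None = None,
) -> pd.DataFrame:
    """Turing wavelength at nucleation sites across exogenous conditions.

    Reuses the dendrite density protocol (first seed only — the wavelength
    is a property of the deterministic S–Y curves, not of the noise) and
    reports the median wavelength at spine-nucleation sites per condition.
    """
    grid = grid or Grid(nx=200, ny=150)
    if stage1 is None:
        stage1 = grow_trunk(grid)
    # finer recording so the S-Y curve resolves the fast cytoskeleton switch
    one_seed = replace(protocol, seeds=protocol.seeds[:1], chunk_steps=80)
    rows = []
    sweeps = (
        [("delta_A", v, {"delta_A": v}) for v in sorted(delta_A_values)]
        + [("delta_H", v, {"delta_H": v}) for v in sorted(delta_H_values)]
    )
    for swept, value, kw in sweeps:
        p2 = preset("fig5-stage2", **kw)
        try:
            out = run_density_condition(p2, stage1, grid, one_seed,
                                        seed=one_seed.seeds[0])
            L, n_sites = nucleation_wavelength(out, p2, stage1)
            rows.append({"swept": swept, "value": value, "wavelength": L,
                         "n_sites": n_sites, "spine_count": out.count,
                         "preset": "fig5-stage2", "seed": one_seed.seeds[0],
                         "error": None if n_sites else "no intersection"})
        except Exception as exc:  # noqa: BLE001
            rows.append({"swept": swept, "value": value, "wavelength": None,
                         "n_sites": 0, "spine_count": None,
                         "preset": "fig5-stage2", "seed": one_seed.seeds[0],
                         "error": str(exc)})
    return pd.DataFrame(rows)
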