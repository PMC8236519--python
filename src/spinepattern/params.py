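"""Model parameters, spatial grid and integration schedule.

The reaction–diffusion model couples four fields on a 2-D grid: an
autocatalytic activator ``A``, a fast-diffusing inhibitor ``H``, a consumable
substrate ``S`` produced by the neuron, and a slow cytoskeleton marker ``Y``
whose bistable self-switch makes ``Y ~ 1`` mark the cell body.  Exogenous
substances enter as additive source rates ``delta_A`` and ``delta_H`` on the
activator and inhibitor equations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields, replace


class StabilityError(ValueError):
    """Raised when an explicit-Euler schedule violates the diffusion CFL bound."""


@dataclass(frozen=True)
class ModelParams:
    """The 16 dimensionless coefficients of the reaction–diffusion system.

    Rates: ``c`` activator autocatalysis, ``mu``/``nu``/``gamma`` degradation
    of A/H/S, ``rho_A``/``rho_H`` endogenous production of A/H by the
    cytoskeleton, ``delta_A``/``delta_H`` exogenous activator/inhibitor
    supply, ``c0`` substrate production, ``epsilon`` substrate consumption by
    the cytoskeleton, ``d``/``e`` cytoskeleton production/degradation and
    ``f`` the saturation constant of the Y self-switch.  ``D_A``, ``D_H``,
    ``D_S`` are diffusion coefficients; lateral inhibition requires
    ``D_H > D_A``.
    """

    c: float = 0.002
    mu: float = 0.16
    nu: float = 0.04
    rho_A: float = 0.01
    rho_H: float = 0.00005
    delta_A: float = 0.0
    delta_H: float = 0.0
    c0: float = 0.02
    gamma: float = 0.02
    epsilon: float = 0.01
    D_A: float = 0.02
    D_H: float = 0.26
    D_S: float = 0.06
    d: float = 0.0035
    e: float = 0.1
    f: float = 10.0

    def __post_init__(self) -> None:
        for fld in fields(self):
            value = getattr(self, fld.name)
            if not value >= 0:
                raise ValueError(f"parameter {fld.name!r} must be >= 0, got {value}")
        if not self.D_H > self.D_A:
            warnings.warn(
                f"D_H ({self.D_H}) <= D_A ({self.D_A}): lateral inhibition "
                "requires the inhibitor to out-diffuse the activator",
                stacklevel=3,
            )

    def with_(self, **changes: float) -> "ModelParams":
        """Return a copy with the given coefficients replaced."""
        return replace(self, **changes)

    @property
    def max_diffusivity(self) -> float:
        return max(self.D_A, self.D_H, self.D_S)


# Named parameter presets for the standard study conditions.
_PRESETS: dict[str, ModelParams] = {
    # Single-spine simulation, fixed coefficients (epsilon/deltas are the
    # experimental dials and default to the standard spine condition).
    "fig2a": ModelParams(),
    # Dendrite trunk growth (stage 1): no exogenous terms.
    "fig2b": ModelParams(rho_A=0.03, rho_H=0.0001, epsilon=0.017),
    # Dendrite spine growth (stage 2): richer substrate supply.
    "fig2c": ModelParams(rho_A=0.02, c0=0.05, epsilon=1.0),
    # Shape experiment standard condition.
    "fig4": ModelParams(delta_A=0.01, delta_H=0.00005),
    # Density experiment standard condition (stage-2 coefficients).
    "fig5-stage2": ModelParams(
        rho_A=0.02, c0=0.05, delta_A=0.01, delta_H=0.00005, epsilon=1.0
    ),
}


def preset(name: str, **overrides: float) -> ModelParams:
    """Look up a named parameter preset, optionally overriding coefficients.

    Known names: ``fig2a``, ``fig2b``, ``fig2c``, ``fig4``, ``fig5-stage2``.
    """
    try:
        base = _PRESETS[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; known presets: {sorted(_PRESETS)}"
        ) from None
    return base.with_(**overrides) if overrides else base


def preset_names() -> list[str]:
    return sorted(_PRESETS)


@dataclass(frozen=True)
class Grid:
    """Regular 2-D grid with zero-flux (mirror) boundaries."""

    nx: int = 100
    ny: int = 100
    dx: float = 0.3

    def __post_init__(self) -> None:
        if self.nx < 3 or self.ny < 3:
            raise ValueError(f"grid must be at least 3x3, got {self.nx}x{self.ny}")
        if not self.dx > 0:
            raise ValueError(f"dx must be positive, got {self.dx}")

    @property
    def shape(self) -> tuple[int, int]:
        """Raster shape (rows, cols) = (ny, nx)."""
        return (self.ny, self.nx)


@dataclass(frozen=True)
class SimSchedule:
    """Explicit-Euler integration schedule.

    ``dt`` must satisfy the explicit-scheme stability bound
    ``dt < dx**2 / (4 * max(D_A, D_H, D_S))``; the constructor cannot check
    this without a grid and parameters, so :meth:`validate` does.
    ``noise_amp`` adds a one-off uniform perturbation to the initial state
    (symmetry breaking); the seed is only consumed when ``noise_amp > 0``.
    """

    dt: float = 0.05
    n_steps: int = 12000
    record_every: int = 2000
    noise_amp: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.n_steps < 0:
            raise ValueError(f"n_steps must be >= 0, got {self.n_steps}")
        if self.record_every < 1:
            raise ValueError(f"record_every must be >= 1, got {self.record_every}")
        if self.noise_amp < 0:
            raise ValueError(f"noise_amp must be >= 0, got {self.noise_amp}")

    def validate(self, grid: Grid, params: ModelParams) -> None:
        """Reject schedules violating the diffusion stability bound."""
        bound = grid.dx**2 / (4.0 * params.max_diffusivity)
        if not self.dt < bound:
            raise StabilityError(
                f"dt={self.dt} violates the explicit-scheme bound "
                f"dx^2/(4 max D) = {bound:.6g}"
            )

    @property
    def t_end(self) -> float:
        return self.dt * self.n_steps
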