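"""Linear (Turing) stability analysis of the activator–inhibitor subsystem.

Freezing the slow fields S and Y turns the four-species model into a
two-species activator–inhibitor system

    dA/dt = c A^2 S / H - mu A + (rho_A + delta_A) Y + D_A lap(A)
    dH/dt = c A^2 S     - nu H + (rho_H + delta_H) Y + D_H lap(H)

parameterised by the frozen (S, Y).  A point of the S–Y plane is *Turing
unstable* when the reaction-only steady state (A*, H*) is linearly stable
(tr J < 0, det J > 0) yet some spatial mode k > 0 grows: the largest real
eigenvalue of

    J(k) = [[f_A - k^2 D_A, f_H], [g_A, g_H - k^2 D_H]]

is positive.  The set of such points is the Turing instability space; the
fastest-growing wavenumber k_m gives the Turing wavelength Lambda = 2 pi /
k_m, which sets the spacing — and hence the density — of spines nucleating
along a dendrite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

from .params import ModelParams
from .rd_core import Trajectory

__all__ = [
    "AHJacobian",
    "DispersionCurve",
    "TuringPointResult",
    "ah_steady_state",
    "ah_jacobian",
    "dispersion_curve",
    "is_turing_unstable",
    "turing_space",
    "turing_wavelength",
    "sy_trajectory",
    "analyze_point",
]

#: Residual tolerance for steady-state roots.
ROOT_TOL = 1e-10

#: Wavenumber search window for the fastest-growing mode.  The simulation
#: grid (dx = 0.3) cannot represent wavelengths much below ~0.6, so k > 10
#: is unphysical for comparisons with simulated patterns.
K_MIN, K_MAX = 0.01, 10.0
K_GRID_POINTS = 2000


@dataclass(frozen=True)
class AHJacobian:
    """Reaction Jacobian of the frozen A–H subsystem at a steady state.

    Entries: f_A = 2cA S/H - mu, f_H = -cA^2 S/H^2, g_A = 2cA S, g_H = -nu,
    evaluated at (A, H) with frozen (S, Y).
    """

    f_A: float
    f_H: float
    g_A: float
    g_H: float
    A: float = np.nan
    H: float = np.nan
    S: float = np.nan
    Y: float = np.nan

    @property
    def trace(self) -> float:
        return self.f_A + self.g_H

    @property
    def det(self) -> float:
        return self.f_A * self.g_H - self.f_H * self.g_A

    @property
    def stable_without_diffusion(self) -> bool:
        return self.trace < 0 and self.det > 0


@dataclass(frozen=True)
class DispersionCurve:
    """Re lambda(k) sampled on an increasing wavenumber grid."""

    k: np.ndarray
    re_lambda: np.ndarray

    def __post_init__(self) -> None:
        k = np.asarray(self.k, dtype=float)
        rl = np.asarray(self.re_lambda, dtype=float)
        if k.shape != rl.shape:
            raise ValueError("k and re_lambda must have the same shape")
        if np.any(np.diff(k) <= 0):
            raise ValueError("k must be strictly increasing")
        if not (np.all(np.isfinite(k)) and np.all(np.isfinite(rl))):
            raise ValueError("dispersion curve must be finite")
        object.__setattr__(self, "k", k)
        object.__setattr__(self, "re_lambda", rl)


@dataclass(frozen=True)
class TuringPointResult:
    """Outcome of the instability analysis at one frozen (S, Y) point."""

    S: float
    Y: float
    A_star: float | None
    H_star: float | None
    jacobian: AHJacobian | None
    in_turing_space: bool
    lambda_m: float | None = None
    k_m: float | None = None
    wavelength: float | None = None
    reason: str = ""


class NoSteadyStateError(ValueError):
    """No positive reaction steady state exists at the requested point."""


def _ah_residuals(A: float, S: float, Y: float, p: ModelParams) -> tuple[float, float, float]:
    """(A-equation residual, H*, H-equation residual) with H eliminated."""
    H = (p.c * A * A * S + (p.rho_H + p.delta_H) * Y) / p.nu
    if H <= 0:
        return np.inf, H, 0.0
    fA = p.c * A * A * S / H - p.mu * A + (p.rho_A + p.delta_A) * Y
    fH = p.c * A * A * S - p.nu * H + (p.rho_H + p.delta_H) * Y
    return fA, H, fH


def ah_steady_state(
    S: float,
    Y: float,
    params: ModelParams,
    A_max: float = 100.0,
) -> tuple[float, float]:
    """Positive steady state (A*, H*) of the frozen A–H reaction system.

    Eliminates H via H* = (c A^2 S + (rho_H + delta_H) Y) / nu and searches
    the A-equation residual for sign changes on (0, A_max], refining each
    bracket by bisection.  When several roots exist the one that is stable
    without diffusion (tr J < 0, det J > 0) is preferred; otherwise the
    smallest positive root is returned.

    Raises :class:`NoSteadyStateError` when no positive root exists.
    """
    if S < 0 or Y < 0:
        raise ValueError("S and Y must be >= 0")
    p = params
    sigma_A = (p.rho_A + p.delta_A) * Y
    sigma_H = (p.rho_H + p.delta_H) * Y

    if sigma_A == 0 and sigma_H == 0:
        # closed form: cA^2S/H = mu A with H = cA^2S/nu  =>  A = nu/mu
        A = p.nu / p.mu
        H = p.c * S * A * A / p.nu
        if H <= 0:
            raise NoSteadyStateError(f"no positive steady state at S={S}, Y={Y}")
        return A, H

    cS = p.c * S
    if cS == 0:
        # linear balance: mu A = sigma_A, nu H = sigma_H
        if sigma_A <= 0 or sigma_H <= 0:
            raise NoSteadyStateError(f"no positive steady state at S={S}, Y={Y}")
        return sigma_A / p.mu, sigma_H / p.nu

    # Eliminating H and clearing the (positive) denominator leaves a cubic:
    # -mu*cS A^3 + cS(nu + sigma_A) A^2 - mu*sigma_H A + sigma_A*sigma_H = 0
    coeffs = [
        -p.mu * cS,
        cS * (p.nu + sigma_A),
        -p.mu * sigma_H,
        sigma_A * sigma_H,
    ]
    raw_roots = np.roots(coeffs)
    roots = sorted(
        float(r.real)
        for r in raw_roots
        if abs(r.imag) < 1e-9 * max(1.0, abs(r.real)) and 0 < r.real <= A_max
    )
    # polish each root against the unscaled residual
    polished = []
    for a in roots:
        try:
            a = optimize.brentq(
                lambda x: _ah_residuals(x, S, Y, p)[0],
                a * 0.5,
                a * 2.0,
                xtol=1e-15,
                rtol=8.9e-16,
            )
        except ValueError:
            pass
        polished.append(a)
    roots = polished
    if not roots:
        raise NoSteadyStateError(f"no positive steady state at S={S}, Y={Y}")

    def h_of(a: float) -> float:
        return _ah_residuals(a, S, Y, p)[1]

    for a in roots:
        jac = ah_jacobian(a, h_of(a), S, p)
        if jac.stable_without_diffusion:
            return a, h_of(a)
    return roots[0], h_of(roots[0])


def ah_jacobian(A: float, H: float, S: float, params: ModelParams) -> AHJacobian:
    """Closed-form reaction Jacobian of the frozen A–H subsystem."""
    if H <= 0:
        raise ValueError(f"H must be positive, got {H}")
    p = params
    return AHJacobian(
        f_A=2.0 * p.c * A * S / H - p.mu,
        f_H=-p.c * A * A * S / (H * H),
        g_A=2.0 * p.c * A * S,
        g_H=-p.nu,
        A=A,
        H=H,
        S=S,
    )


def _lambda_max(jac: AHJacobian, D_A: float, D_H: float, k: np.ndarray) -> np.ndarray:
    """Re of the larger eigenvalue of J(k), via the quadratic closed form."""
    k2 = np.asarray(k, dtype=float) ** 2
    a11 = jac.f_A - k2 * D_A
    a22 = jac.g_H - k2 * D_H
    tr = a11 + a22
    det = a11 * a22 - jac.f_H * jac.g_A
    disc = tr * tr / 4.0 - det
    root = np.where(
        disc >= 0,
        tr / 2.0 + np.sqrt(np.maximum(disc, 0.0)),
        tr / 2.0,  # complex pair: real part is tr/2
    )
    return root


def dispersion_curve(
    jac: AHJacobian,
    D_A: float,
    D_H: float,
    k_grid: Sequence[float] | np.ndarray,
) -> DispersionCurve:
    """Growth rate Re lambda(k) of spatial modes under the linearisation."""
    k = np.asarray(k_grid, dtype=float)
    return DispersionCurve(k=k, re_lambda=_lambda_max(jac, D_A, D_H, k))


def _turing_inequality(jac: AHJacobian, D_A: float, D_H: float) -> bool:
    """Classic two-species criterion for diffusion-driven instability."""
    if not jac.stable_without_diffusion:
        return False
    lhs = D_H * jac.f_A + D_A * jac.g_H
    return lhs > 0 and lhs * lhs > 4.0 * D_A * D_H * jac.det


def _default_k_grid() -> np.ndarray:
    return np.geomspace(K_MIN, K_MAX, K_GRID_POINTS)


def is_turing_unstable(
    S: float,
    Y: float,
    params: ModelParams,
    check_consistency: bool = True,
) -> bool:
    """Whether the frozen (S, Y) point is diffusion-driven unstable.

    Evaluated both through the closed-form inequality on the Jacobian and
    through the sign of the dispersion curve's maximum; the two routes must
    agree (``check_consistency``).  A point with no positive steady state is
    reported stable.
    """
    try:
        A, H = ah_steady_state(S, Y, params)
    except NoSteadyStateError:
        return False
    jac = ah_jacobian(A, H, S, params)
    by_inequality = _turing_inequality(jac, params.D_A, params.D_H)
    if check_consistency:
        curve = dispersion_curve(jac, params.D_A, params.D_H, _default_k_grid())
        by_curve = jac.stable_without_diffusion and curve.re_lambda.max() > 0
        if by_curve != by_inequality:
            raise AssertionError(
                f"instability tests disagree at S={S}, Y={Y}: "
                f"inequality={by_inequality}, dispersion={by_curve}"
            )
    return by_inequality


def turing_space(
    params: ModelParams,
    S_range: tuple[float, float] = (0.0, 2.0),
    Y_range: tuple[float, float] = (0.0, 2.0),
    resolution: tuple[int, int] = (200, 200),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boolean instability raster over the S–Y plane.

    Returns ``(raster, S_values, Y_values)`` where ``raster[i, j]`` refers to
    ``(S_values[j], Y_values[i])``.
    """
    nS, nY = resolution
    S_vals = np.linspace(*S_range, nS)
    Y_vals = np.linspace(*Y_range, nY)
    raster = np.zeros((nY, nS), dtype=bool)
    for i, Yv in enumerate(Y_vals):
        for j, Sv in enumerate(S_vals):
            raster[i, j] = is_turing_unstable(Sv, Yv, params, check_consistency=False)
    return raster, S_vals, Y_vals


def turing_wavelength(
    S: float,
    Y: float,
    params: ModelParams,
) -> tuple[float, float, float]:
    """(lambda_m, k_m, Lambda) of a Turing-unstable point.

    The fastest-growing wavenumber is located on a log-spaced grid over
    [K_MIN, K_MAX] and refined by bounded scalar maximisation; the Turing
    wavelength is Lambda = 2 pi / k_m.

    Raises ``ValueError`` when the point is not Turing-unstable.
    """
    if not is_turing_unstable(S, Y, params, check_consistency=False):
        raise ValueError(f"point S={S}, Y={Y} is not Turing-unstable")
    A, H = ah_steady_state(S, Y, params)
    jac = ah_jacobian(A, H, S, params)
    k = _default_k_grid()
    rl = _lambda_max(jac, params.D_A, params.D_H, k)
    i = int(np.argmax(rl))
    lo = k[max(i - 1, 0)]
    hi = k[min(i + 1, len(k) - 1)]
    res = optimize.minimize_scalar(
        lambda kk: -_lambda_max(jac, params.D_A, params.D_H, np.array([kk]))[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    k_m = float(res.x)
    lambda_m = float(-res.fun)
    return lambda_m, k_m, 2.0 * np.pi / k_m


def sy_trajectory(traj: Trajectory, point: tuple[int, int]) -> np.ndarray:
    """(S, Y) values at one grid cell across the snapshots, in time order.

    ``point`` is a (row, col) index; the S–Y curve is a pure readout of the
    recorded trajectory and does not depend on any analysis parameters.
    """
    r, c = point
    ny, nx = traj.initial.shape
    if not (0 <= r < ny and 0 <= c < nx):
        raise IndexError(f"point {point} outside grid {(ny, nx)}")
    return np.array([(s.S[r, c], s.Y[r, c]) for s in traj.snapshots])


def analyze_point(
    traj: Trajectory,
    point: tuple[int, int],
    params: ModelParams | None = None,
) -> TuringPointResult:
    """Instability analysis along the S–Y curve of one grid cell.

    Each point of the S–Y curve is tested for Turing instability under
    ``params`` (default: the trajectory's stage-2 parameters if present,
    else its own).  The representative intersection is the *last* in-space
    curve point — fully deterministic, in contrast to picking one by eye —
    and lambda_m, k_m and Lambda are computed there.
    """
    if params is None:
        params = traj.stage2_params or traj.params
    curve = sy_trajectory(traj, point)
    in_space = [
        bool(is_turing_unstable(S, Y, params, check_consistency=False))
        for S, Y in curve
    ]
    if not any(in_space):
        S, Y = curve[-1]
        return TuringPointResult(
            S=S, Y=Y, A_star=None, H_star=None, jacobian=None,
            in_turing_space=False, reason="no intersection",
        )
    idx = max(i for i, flag in enumerate(in_space) if flag)
    S, Y = curve[idx]
    A, H = ah_steady_state(S, Y, params)
    jac = ah_jacobian(A, H, S, params)
    lambda_m, k_m, wavelength = turing_wavelength(S, Y, params)
    return TuringPointResult(
        S=float(S), Y=float(Y), A_star=A, H_star=H, jacobian=jac,
        in_turing_space=True, lambda_m=lambda_m, k_m=k_m, wavelength=wavelength,
    )
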