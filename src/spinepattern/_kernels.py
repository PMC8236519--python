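"""Compiled explicit-Euler stepping loop.

``run_steps`` advances the four fields in place and performs, per cell, the
same arithmetic in the same order as the reference ``step_euler`` /
``reaction_rhs`` / ``laplacian`` path, so the two routes agree bit for bit.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def run_steps(A, H, S, Y, coeffs, dx, dt, n_steps, h_floor):  # pragma: no cover
    """Advance the fields ``n_steps`` Euler steps in place.

    Returns the number of cells clamped from negative to zero, or
    ``-(step+1)`` if a non-finite value appeared at 1-based step ``step+1``.
    """
    c = coeffs[0]
    mu = coeffs[1]
    nu = coeffs[2]
    src_A = coeffs[3]
    src_H = coeffs[4]
    c0 = coeffs[5]
    gamma = coeffs[6]
    eps = coeffs[7]
    D_A = coeffs[8]
    D_H = coeffs[9]
    D_S = coeffs[10]
    d = coeffs[11]
    e = coeffs[12]
    f = coeffs[13]

    ny, nx = A.shape
    inv_dx2 = 1.0 / (dx * dx)

    An = np.empty_like(A)
    Hn = np.empty_like(H)
    Sn = np.empty_like(S)
    Yn = np.empty_like(Y)

    cA, cH, cS, cY = A, H, S, Y
    nA, nH, nS, nY = An, Hn, Sn, Yn

    clamps = 0
    for step in range(n_steps):
        for i in range(ny):
            im1 = i - 1 if i > 0 else 0
            ip1 = i + 1 if i < ny - 1 else ny - 1
            for j in range(nx):
                jm1 = j - 1 if j > 0 else 0
                jp1 = j + 1 if j < nx - 1 else nx - 1

                a = cA[i, j]
                h = cH[i, j]
                s = cS[i, j]
                y = cY[i, j]

                lap_A = (
                    cA[im1, j] + cA[ip1, j] + cA[i, jm1] + cA[i, jp1] - 4.0 * a
                ) * inv_dx2
                lap_H = (
                    cH[im1, j] + cH[ip1, j] + cH[i, jm1] + cH[i, jp1] - 4.0 * h
                ) * inv_dx2
                lap_S = (
                    cS[im1, j] + cS[ip1, j] + cS[i, jm1] + cS[i, jp1] - 4.0 * s
                ) * inv_dx2

                h_safe = h if h > h_floor else h_floor
                auto = c * a * a * s
                dA = auto / h_safe - mu * a + src_A * y
                dH = auto - nu * h + src_H * y
                dS = c0 - gamma * s - eps * y * s
                dY = d * a - e * y + y * y / (1.0 + f * y * y)

                na = a + dt * (dA + D_A * lap_A)
                nh = h + dt * (dH + D_H * lap_H)
                ns = s + dt * (dS + D_S * lap_S)
                nyv = y + dt * dY

                if not (
                    np.isfinite(na)
                    and np.isfinite(nh)
                    and np.isfinite(ns)
                    and np.isfinite(nyv)
                ):
                    return -(step + 1)

                if na < 0.0:
                    na = 0.0
                    clamps += 1
                if nh < 0.0:
                    nh = 0.0
                    clamps += 1
                if ns < 0.0:
                    ns = 0.0
                    clamps += 1
                if nyv < 0.0:
                    nyv = 0.0
                    clamps += 1

                nA[i, j] = na
                nH[i, j] = nh
                nS[i, j] = ns
                nY[i, j] = nyv

        cA, nA = nA, cA
        cH, nH = nH, cH
        cS, nS = nS, cS
        cY, nY = nY, cY

    if n_steps % 2 == 1:
        A[:, :] = cA
        H[:, :] = cH
        S[:, :] = cS
        Y[:, :] = cY
    return clamps
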