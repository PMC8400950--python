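"""Independent finite-difference oracle for the membrane diffusion problem.

Solves  dC/dt = D d2C/dx2  on 0 < x < L with C(0,t) = K*Cd, C(L,t) = 0,
C(x,0) = 0, and accumulates the outflux at x = L:

    Q(t) = integral_0^t  -D dC/dx|_{x=L}  dt'     (per unit area)

Discretization: second-order central differences in space on a uniform grid.
The resulting linear ODE system is integrated exactly through the discrete
sine eigendecomposition of the Dirichlet Laplacian (method of lines with
closed-form modal integration), so the only discretization error is spatial.
The boundary flux uses a second-order one-sided difference.  Grid-doubling
Richardson extrapolation removes the leading h^2 and h^4 error terms; the
spread between refinement levels doubles as a self-convergence estimate.

This path shares nothing with the package's eigenfunction-series evaluation:
eigenvalues, mode shapes, initial-condition coefficients and the flux
extraction are all those of the discrete operator.
"""

from __future__ import annotations

import numpy as np


def _cumulative_outflux_fd(t: np.ndarray, D: float, K: float, L: float,
                           Cd: float, nx: int) -> np.ndarray:
    """Q(t) for one uniform grid with nx intervals."""
    h = L / nx
    j = np.arange(1, nx)                       # interior nodes
    x = j * h
    n = np.arange(1, nx)                       # discrete modes
    mu = D * (4.0 / h**2) * np.sin(n * np.pi * h / (2 * L)) ** 2

    # steady state is linear, C_ss = K*Cd*(1 - x/L); transient v = C - C_ss
    v0 = -K * Cd * (1.0 - x / L)
    phi = np.sin(np.outer(n, x) * np.pi / L)   # (mode, node)
    a = (2.0 / nx) * phi @ v0                  # discrete sine coefficients

    # -dC/dx at x=L, one-sided 2nd order with C(L)=0:
    #   -(3*0 - 4*C_{N-1} + C_{N-2})/(2h)
    g = (4.0 * np.sin(n * np.pi * (L - h) / L)
         - np.sin(n * np.pi * (L - 2 * h) / L)) / (2.0 * h)

    # steady outflux is exactly D*K*Cd/L (one-sided difference is exact on a line)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    transient = ((a * (D * g) / mu)[:, None] * (1.0 - np.exp(-np.outer(mu, t)))).sum(axis=0)
    return D * K * Cd / L * t + transient


def pde_cumulative(t, D: float, K: float, L: float, Cd: float,
                   nx: int = 128) -> tuple[np.ndarray, np.ndarray]:
    """Richardson-extrapolated FD value of Q(t) and a self-convergence estimate.

    Returns ``(q, err)`` where ``err`` is the absolute difference between the
    two finest extrapolation levels — refine ``nx`` until it is small enough
    for the comparison at hand.
    """
    q1 = _cumulative_outflux_fd(t, D, K, L, Cd, nx)
    q2 = _cumulative_outflux_fd(t, D, K, L, Cd, 2 * nx)
    q4 = _cumulative_outflux_fd(t, D, K, L, Cd, 4 * nx)
    r12 = (4.0 * q2 - q1) / 3.0
    r24 = (4.0 * q4 - q2) / 3.0
    extrap = (16.0 * r24 - r12) / 15.0
    return extrap, np.abs(extrap - r24)
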