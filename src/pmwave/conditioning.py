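"""Condition-number estimation for the linearized time-step operator.

Raising the extension order L changes the conditioning of the discretized
update; the dynamic-L rule refuses an increase whose condition number grows
by a factor of 10 or more.  The matrix monitored here is the one-step update
A = I + tau * D(u), where D(u) is the diffusion right-hand side linearized by
freezing its scalar coefficient fields (diffusivity and its gradient factor)
at the current state, discretized by wavelet collocation on a small probe
grid.  A one-norm condition estimate comes from the exact matrix one-norm and
a deterministic Hager-style estimate of the inverse's norm.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import lu_factor, lu_solve

from .bases import ScalingFunctionSpec
from .interval import IntervalGrid, basis_matrix

__all__ = ["cond_estimate_1norm", "linearized_update_matrix"]


def _hager_inverse_1norm(lu_piv, n: int, iters: int = 5) -> float:
    """Deterministic Hager lower-bound estimate of ||A^{-1}||_1."""
    x = np.full(n, 1.0 / n)
    est = 0.0
    for _ in range(iters):
        y = lu_solve(lu_piv, x)
        est = float(np.abs(y).sum())
        xi = np.sign(y)
        xi[xi == 0] = 1.0
        z = lu_solve(lu_piv, xi, trans=1)
        jmax = int(np.argmax(np.abs(z)))
        if np.abs(z[jmax]) <= z @ x:
            break
        x = np.zeros(n)
        x[jmax] = 1.0
    return est


def cond_estimate_1norm(A: np.ndarray) -> float:
    """One-norm condition estimate: exact ||A||_1, Hager estimate of the inverse.

    Singular-to-working-precision matrices report +inf.
    """
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    norm_A = float(np.abs(A).sum(axis=0).max())
    try:
        lu_piv = lu_factor(A)
    except np.linalg.LinAlgError:
        return float("inf")
    if not np.all(np.isfinite(lu_piv[0])) or np.any(np.diag(lu_piv[0]) == 0.0):
        return float("inf")
    return norm_A * _hager_inverse_1norm(lu_piv, n)


def _deriv_matrices_1d(n_level: int, spec: ScalingFunctionSpec, L: int,
                       domain=(0.0, 1.0)):
    """Nodal collocation matrices D1, D2 at level j with 2^j+1 = n nodes."""
    j = int(np.log2(n_level - 1))
    if 2**j + 1 != n_level:
        raise ValueError("probe grid side must be 2^j + 1")
    g = IntervalGrid(domain[0], domain[1], j)
    Lc = min(L, 2**j)
    if spec.family == "daub_autocorr":
        Lc = min(Lc, 2 * spec.M - 1)
    D1 = basis_matrix(g.nodes, g, spec, 1, Lc, Lc)
    D2 = basis_matrix(g.nodes, g, spec, 2, Lc, Lc)
    return D1, D2


def linearized_update_matrix(values: np.ndarray, spec: ScalingFunctionSpec,
                             L: int, tau: float, c_type: str, k: float) -> np.ndarray:
    """A = I + tau * D for the diffusion RHS linearized at ``values``.

    ``values`` are nodal values on a square probe grid (side 2^j + 1, unit
    square).  Fields are laid out row-major ([y, x]), so u_xx corresponds to
    kron(I, D2) and u_yy to kron(D2, I).
    """
    from .solver import _diffusivity_fields  # local import avoids a cycle

    V = np.asarray(values, dtype=float)
    n = V.shape[0]
    if V.shape != (n, n):
        raise ValueError("probe state must be square")
    D1, D2 = _deriv_matrices_1d(n, spec, L)
    h = 1.0 / (n - 1)
    ux = V @ D1.T
    uy = D1 @ V
    c, q = _diffusivity_fields(h * np.hypot(ux, uy), c_type, k)
    q = q * h * h

    I_n = np.eye(n)
    Kxx = np.kron(I_n, D2)
    Kyy = np.kron(D2, I_n)
    Kxy = np.kron(D1, D1)
    cf = c.ravel()
    qf = q.ravel()
    D = (cf[:, None] * (Kxx + Kyy)
         + qf[:, None] * ((ux.ravel() ** 2)[:, None] * Kxx
                          + 2.0 * (ux.ravel() * uy.ravel())[:, None] * Kxy
                          + (uy.ravel() ** 2)[:, None] * Kyy))
    return np.eye(n * n) + tau * D
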