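"""Multilevel 2-D interpolation on dyadic grids with sparse coefficients.

A field sampled on the (2^J+1)^2 dyadic grid of a rectangle is represented as
a coarse level-j0 interpolant plus, for each level j = j0..J-1, hierarchical
surpluses ("interpolatory wavelet coefficients") at the nodes that are new at
level j+1.  The new nodes split into three families by parity of the fine
indices -- (odd, even), (even, odd) and (odd, odd) in (x, y) -- with
coefficient tables alpha1, alpha2, alpha3.  Each coefficient is the field
value at its node minus the interpolant of all coarser levels there, so
thresholding the coefficients yields an adaptive sparse grid: only nodes
whose surplus exceeds the threshold stay active.

Index layout: arrays are [row, col] = [y, x], so alpha1 (odd x, even y) has
shape (2^j + 1, 2^j).  Note the boundary lines of each family are kept; a
formulation that stops both indices at 2^j - 1 drops the last even line and
cannot reconstruct losslessly.

The decomposition is computed level by level from residuals (cost counted in
coefficients, O(4^J) of them); the explicit extension operators C1/C2/C3 that
map fine nodal values directly to coefficients are assembled only as a
small-grid verification oracle, since their assembly costs O(4^{2J}).
"""

from __future__ import annotations

import dataclasses
import functools

import numpy as np

from .bases import ScalingFunctionSpec
from .interval import IntervalGrid, basis_matrix

__all__ = [
    "MultilevelGrid2D",
    "SparseCoefficientSet",
    "restriction",
    "decompose",
    "reconstruct",
    "reconstruct_grid",
    "compress",
    "active_point_count",
    "assemble_extension_operators",
    "apply_extension_operators",
]


@dataclasses.dataclass(frozen=True)
class MultilevelGrid2D:
    """Nested dyadic grids on a rectangle, levels j0 (coarsest) .. J (finest)."""

    j0: int
    J: int
    domain: tuple = ((0.0, 1.0), (0.0, 1.0))

    def __post_init__(self):
        if self.j0 < 0 or self.J < self.j0:
            raise ValueError("need 0 <= j0 <= J")

    def n(self, j: int) -> int:
        return 2**j + 1

    def axis_grid(self, j: int, axis: int) -> IntervalGrid:
        lo, hi = self.domain[axis]
        return IntervalGrid(lo, hi, j)

    def nodes_1d(self, j: int, axis: int) -> np.ndarray:
        return self.axis_grid(j, axis).nodes

    def node(self, j: int, k1: int, k2: int) -> tuple:
        """(x_{k1}^j, y_{k2}^j)."""
        return (self.axis_grid(j, 0).node(k1), self.axis_grid(j, 1).node(k2))


def restriction(l: int, k1: int, k2: int, j: int, m1: int, m2: int) -> int:
    """1 iff node (k1,k2) at level l and node (m1,m2) at level j coincide."""
    return int(k1 * 2**j == m1 * 2**l and k2 * 2**j == m2 * 2**l)


@dataclasses.dataclass
class SparseCoefficientSet:
    """Coarse nodal values plus per-level surplus tables and activity masks.

    alpha1[j][ky, kx] lives at (x_{2kx+1}^{j+1}, y_{2ky}^{j+1}), alpha2 at
    (even x, odd y), alpha3 at (odd, odd).  ``ops`` counts the coefficients
    computed during decomposition (the work unit of the recursive route).
    """

    grid: MultilevelGrid2D
    spec: ScalingFunctionSpec
    L_sides: tuple  # (L_x_left, L_x_right, L_y_low, L_y_high)
    coarse: np.ndarray
    alpha1: dict
    alpha2: dict
    alpha3: dict
    mask1: dict
    mask2: dict
    mask3: dict
    threshold: float = 0.0
    ops: int = 0

    def copy(self) -> "SparseCoefficientSet":
        return SparseCoefficientSet(
            self.grid, self.spec, self.L_sides, self.coarse.copy(),
            {j: a.copy() for j, a in self.alpha1.items()},
            {j: a.copy() for j, a in self.alpha2.items()},
            {j: a.copy() for j, a in self.alpha3.items()},
            {j: m.copy() for j, m in self.mask1.items()},
            {j: m.copy() for j, m in self.mask2.items()},
            {j: m.copy() for j, m in self.mask3.items()},
            self.threshold, self.ops)


def _clamp_L(L: int, j: int, spec: ScalingFunctionSpec) -> int:
    """L cannot exceed the number of interior nodes; compact-support bases cap
    it at 2M-1 (beyond which external shifts never reach the domain)."""
    cap = 2**j
    if spec.family == "daub_autocorr":
        cap = min(cap, 2 * spec.M - 1)
    return max(0, min(L, cap))


def _sides(L) -> tuple:
    if np.isscalar(L):
        L = (L, L, L, L)
    return tuple(int(v) for v in L)


@functools.lru_cache(maxsize=512)
def _basis_matrix_nodes(spec: ScalingFunctionSpec, axis_lo: float, axis_hi: float,
                        j_basis: int, J_target: int, deriv: int,
                        L_left: int, L_right: int):
    """B[t, k] = w_{j_basis,k}^(deriv) at the level-J_target nodes (cached)."""
    gb = IntervalGrid(axis_lo, axis_hi, j_basis)
    xs = IntervalGrid(axis_lo, axis_hi, J_target).nodes
    B = basis_matrix(xs, gb, spec, deriv, L_left, L_right)
    B.setflags(write=False)
    return B


def _level_matrices(coeffs_or_grid, spec, L_sides, j_basis: int, J: int,
                    m: int, n: int):
    """(Bx, By) for basis level j_basis evaluated on the level-J node grid."""
    grid = coeffs_or_grid
    (xlo, xhi), (ylo, yhi) = grid.domain
    Lxl, Lxr, Lyl, Lyh = (_clamp_L(L_sides[0], j_basis, spec),
                          _clamp_L(L_sides[1], j_basis, spec),
                          _clamp_L(L_sides[2], j_basis, spec),
                          _clamp_L(L_sides[3], j_basis, spec))
    Bx = _basis_matrix_nodes(spec, xlo, xhi, j_basis, J, m, Lxl, Lxr)
    By = _basis_matrix_nodes(spec, ylo, yhi, j_basis, J, n, Lyl, Lyh)
    return Bx, By


def decompose(nodal_values, grid: MultilevelGrid2D, spec: ScalingFunctionSpec,
              L=3, threshold: float = 0.0) -> SparseCoefficientSet:
    """Level-by-level interpolatory wavelet decomposition of fine nodal values.

    ``L`` is the extension order, either a scalar or a per-side tuple
    (x_left, x_right, y_low, y_high); it is clamped per level to the valid
    range.  All coefficients start active; apply :func:`compress` to sparsify.
    """
    V = np.asarray(nodal_values, dtype=float)
    N = grid.n(grid.J)
    if V.shape != (N, N):
        raise ValueError(f"expected nodal values of shape {(N, N)}, got {V.shape}")
    L_sides = _sides(L)
    j0, J = grid.j0, grid.J

    stride0 = 2 ** (J - j0)
    coarse = V[::stride0, ::stride0].copy()
    ops = coarse.size
    Bx0, By0 = _level_matrices(grid, spec, L_sides, j0, J, 0, 0)
    G = By0 @ coarse @ Bx0.T

    alpha1, alpha2, alpha3 = {}, {}, {}
    mask1, mask2, mask3 = {}, {}, {}
    for j in range(j0, J):
        s = 2 ** (J - j - 1)              # fine-index stride of level j+1
        idx_e = np.arange(2**j + 1) * 2 * s
        idx_o = (np.arange(2**j) * 2 + 1) * s
        a1 = V[np.ix_(idx_e, idx_o)] - G[np.ix_(idx_e, idx_o)]
        a2 = V[np.ix_(idx_o, idx_e)] - G[np.ix_(idx_o, idx_e)]
        a3 = V[np.ix_(idx_o, idx_o)] - G[np.ix_(idx_o, idx_o)]
        ops += a1.size + a2.size + a3.size
        alpha1[j], alpha2[j], alpha3[j] = a1, a2, a3
        mask1[j] = np.ones(a1.shape, dtype=bool)
        mask2[j] = np.ones(a2.shape, dtype=bool)
        mask3[j] = np.ones(a3.shape, dtype=bool)
        if j < J - 1:                     # last level's surpluses never re-interpolated
            Bx, By = _level_matrices(grid, spec, L_sides, j + 1, J, 0, 0)
            G = G + By[:, ::2] @ a1 @ Bx[:, 1::2].T \
                  + By[:, 1::2] @ a2 @ Bx[:, ::2].T \
                  + By[:, 1::2] @ a3 @ Bx[:, 1::2].T

    out = SparseCoefficientSet(grid, spec, L_sides, coarse,
                               alpha1, alpha2, alpha3, mask1, mask2, mask3,
                               threshold=0.0, ops=ops)
    if threshold > 0.0:
        out = compress(out, threshold)
    return out


def reconstruct_grid(coeffs: SparseCoefficientSet, m: int = 0, n: int = 0) -> np.ndarray:
    """Multilevel interpolant (or its (m,n) mixed derivative) on the level-J grid.

    Only active coefficients contribute.
    """
    if m + n > 2:
        raise ValueError("derivative order m+n must be <= 2")
    grid, spec, L_sides = coeffs.grid, coeffs.spec, coeffs.L_sides
    j0, J = grid.j0, grid.J
    Bx0, By0 = _level_matrices(grid, spec, L_sides, j0, J, m, n)
    G = By0 @ coeffs.coarse @ Bx0.T
    for j in range(j0, J):
        a1 = coeffs.alpha1[j] * coeffs.mask1[j]
        a2 = coeffs.alpha2[j] * coeffs.mask2[j]
        a3 = coeffs.alpha3[j] * coeffs.mask3[j]
        Bx, By = _level_matrices(grid, spec, L_sides, j + 1, J, m, n)
        G = G + By[:, ::2] @ a1 @ Bx[:, 1::2].T \
              + By[:, 1::2] @ a2 @ Bx[:, ::2].T \
              + By[:, 1::2] @ a3 @ Bx[:, 1::2].T
    return G


def reconstruct(coeffs: SparseCoefficientSet, x, y, m: int = 0, n: int = 0):
    """Point evaluation of the multilevel interpolant or its (m,n) derivative."""
    if m + n > 2:
        raise ValueError("derivative order m+n must be <= 2")
    grid, spec, L_sides = coeffs.grid, coeffs.spec, coeffs.L_sides
    (xlo, xhi), (ylo, yhi) = grid.domain
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if np.any(x < xlo - 1e-12) or np.any(x > xhi + 1e-12) \
            or np.any(y < ylo - 1e-12) or np.any(y > yhi + 1e-12):
        raise ValueError("evaluation point outside the domain")
    scalar = x.size == 1 and y.size == 1

    def mats(j_basis):
        gx = grid.axis_grid(j_basis, 0)
        gy = grid.axis_grid(j_basis, 1)
        Bx = basis_matrix(x, gx, spec, m,
                          _clamp_L(L_sides[0], j_basis, spec),
                          _clamp_L(L_sides[1], j_basis, spec))
        By = basis_matrix(y, gy, spec, n,
                          _clamp_L(L_sides[2], j_basis, spec),
                          _clamp_L(L_sides[3], j_basis, spec))
        return Bx, By

    Bx, By = mats(grid.j0)
    out = np.einsum("ta,ab,tb->t", By, coeffs.coarse, Bx)
    for j in range(grid.j0, grid.J):
        a1 = coeffs.alpha1[j] * coeffs.mask1[j]
        a2 = coeffs.alpha2[j] * coeffs.mask2[j]
        a3 = coeffs.alpha3[j] * coeffs.mask3[j]
        Bx, By = mats(j + 1)
        out = out + np.einsum("ta,ab,tb->t", By[:, ::2], a1, Bx[:, 1::2])
        out = out + np.einsum("ta,ab,tb->t", By[:, 1::2], a2, Bx[:, ::2])
        out = out + np.einsum("ta,ab,tb->t", By[:, 1::2], a3, Bx[:, 1::2])
    return float(out[0]) if scalar else out


def compress(coeffs: SparseCoefficientSet, threshold: float) -> SparseCoefficientSet:
    """Activity masks |alpha| >= threshold; coarse values are always active."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    out = coeffs.copy()
    out.threshold = threshold
    for j in out.alpha1:
        out.mask1[j] = np.abs(out.alpha1[j]) >= threshold
        out.mask2[j] = np.abs(out.alpha2[j]) >= threshold
        out.mask3[j] = np.abs(out.alpha3[j]) >= threshold
    return out


def active_point_count(coeffs: SparseCoefficientSet) -> int:
    """Coarse nodes plus active detail coefficients (the sparse grid size)."""
    total = coeffs.coarse.size
    for j in coeffs.mask1:
        total += int(coeffs.mask1[j].sum() + coeffs.mask2[j].sum()
                     + coeffs.mask3[j].sum())
    return int(total)


# ---------------------------------------------------------------------------
# Explicit extension operators (small-grid verification oracle)
# ---------------------------------------------------------------------------

def assemble_extension_operators(grid: MultilevelGrid2D, spec: ScalingFunctionSpec,
                                 L=3) -> dict:
    """Assemble the explicit operators C1/C2/C3: fine nodal values -> surpluses.

    Built by the operator recursion: the running interpolation operator T maps
    flattened fine values to the current interpolant on the fine grid; each
    level's coefficient operator is (sampling at new nodes) @ (I - T).  The
    assembly is the O(4^{2J}) route, so keep the grids tiny; it exists to
    cross-check the recursive residual decomposition.
    """
    L_sides = _sides(L)
    j0, J = grid.j0, grid.J
    N = grid.n(J)
    NN = N * N

    stride0 = 2 ** (J - j0)
    sel0 = np.zeros((grid.n(j0) ** 2, NN))
    rows = np.arange(grid.n(j0)) * stride0
    for a, ry in enumerate(rows):
        for b, rx in enumerate(rows):
            sel0[a * grid.n(j0) + b, ry * N + rx] = 1.0
    Bx0, By0 = _level_matrices(grid, spec, L_sides, j0, J, 0, 0)
    T = np.kron(By0, Bx0) @ sel0

    def selector(idx_y, idx_x):
        S = np.zeros((idx_y.size * idx_x.size, NN))
        for a, ry in enumerate(idx_y):
            for b, rx in enumerate(idx_x):
                S[a * idx_x.size + b, ry * N + rx] = 1.0
        return S

    ops: dict = {}
    for j in range(j0, J):
        s = 2 ** (J - j - 1)
        idx_e = np.arange(2**j + 1) * 2 * s
        idx_o = (np.arange(2**j) * 2 + 1) * s
        Bx, By = _level_matrices(grid, spec, L_sides, j + 1, J, 0, 0)
        for fam, (iy, ix, Bys, Bxs) in enumerate(
                [(idx_e, idx_o, By[:, ::2], Bx[:, 1::2]),
                 (idx_o, idx_e, By[:, 1::2], Bx[:, ::2]),
                 (idx_o, idx_o, By[:, 1::2], Bx[:, 1::2])], start=1):
            S = selector(iy, ix)
            C = S - S @ T
            ops[(j, fam)] = (C, (iy.size, ix.size))
        # extend T with this level's contribution: T += W_fam @ C_fam
        for fam, (Bys, Bxs) in enumerate(
                [(By[:, ::2], Bx[:, 1::2]),
                 (By[:, 1::2], Bx[:, ::2]),
                 (By[:, 1::2], Bx[:, 1::2])], start=1):
            C, _ = ops[(j, fam)]
            T = T + np.kron(Bys, Bxs) @ C
    return ops


def apply_extension_operators(ops: dict, nodal_values) -> dict:
    """Surplus tables from the explicit operators (oracle path)."""
    v = np.asarray(nodal_values, dtype=float).ravel()
    out = {}
    for (j, fam), (C, shape) in ops.items():
        out[(j, fam)] = (C @ v).reshape(shape)
    return out
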