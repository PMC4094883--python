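"""Interpolation bases on an interval: Lagrange extension and dynamic order.

A collocation basis built from shifts of an interpolating scaling function
needs values beyond the endpoints of [xmin, xmax].  The interval construction
supplies L fictitious ("external") collocation points per side whose values
are extrapolated from the L interior points nearest that boundary, so the
boundary artifacts of the basis are pushed into the extension region.

Two equivalent extrapolation forms are provided:

* Lagrange weights (:func:`lagrange_extension_coeffs`), the static form in
  which the degree-(L-1) extrapolation weights are precomputed;
* Newton divided differences (:class:`NewtonExtrapolator`), which add one
  term per extra point without recomputing earlier ones, so the order L can
  be raised incrementally at O(L) cost.

The dynamic choice of L (:func:`select_L_dynamic`) uses the decay of divided
differences as a smoothness proxy -- the order-m divided difference estimates
f^(m)/m! -- and refuses any increase of L that inflates the condition number
of the discretized system by a factor >= ``cond_ratio_max``.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np

from .bases import ScalingFunctionSpec

__all__ = [
    "IntervalGrid",
    "ExtensionCoeffs",
    "DividedDifferenceTable",
    "DynamicLConfig",
    "NewtonExtrapolator",
    "make_interval_grid",
    "lagrange_extension_coeffs",
    "extension_matrix",
    "extrapolate_external_lagrange",
    "divided_differences",
    "extrapolate_external_newton",
    "select_L_dynamic",
    "select_L_from_differences",
    "basis_matrix",
    "interval_interpolant",
]

log = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class IntervalGrid:
    """2^j + 1 equispaced nodes x_{j,k} = xmin + k (xmax-xmin)/2^j."""

    xmin: float
    xmax: float
    j: int

    def __post_init__(self):
        if self.xmax <= self.xmin:
            raise ValueError("xmax must exceed xmin")
        if self.j < 0:
            raise ValueError("level j must be >= 0")

    @property
    def n_nodes(self) -> int:
        return 2**self.j + 1

    @property
    def spacing(self) -> float:
        return (self.xmax - self.xmin) / 2**self.j

    @property
    def nodes(self) -> np.ndarray:
        return np.linspace(self.xmin, self.xmax, self.n_nodes)

    def node(self, k: int) -> float:
        """x_{j,k}; k may lie outside 0..2^j (external points)."""
        return self.xmin + k * self.spacing


def make_interval_grid(xmin: float, xmax: float, j: int) -> IntervalGrid:
    return IntervalGrid(xmin, xmax, j)


# ---------------------------------------------------------------------------
# Lagrange extension (static L)
# ---------------------------------------------------------------------------

def _lagrange_row(x_t: float, xs: np.ndarray) -> np.ndarray:
    """Lagrange basis weights for evaluating at x_t from nodes xs."""
    w = np.empty(xs.size)
    for k in range(xs.size):
        others = np.delete(xs, k)
        w[k] = np.prod((x_t - others) / (xs[k] - others))
    return w


@dataclasses.dataclass(frozen=True)
class ExtensionCoeffs:
    """Lagrange extension weights a_nk (left) and b_nk (right).

    ``left_weights[i]`` predicts the external node x_{j,-(i+1)} from the
    interior nodes x_{j,0..L-1}; ``right_weights[i]`` predicts x_{j,2^j+1+i}
    from x_{j,2^j-L+1..2^j}.  Every row sums to 1 (constants reproduced).
    """

    L: int
    left_weights: np.ndarray
    right_weights: np.ndarray


def lagrange_extension_coeffs(grid: IntervalGrid, L: int) -> ExtensionCoeffs:
    if L == 0:
        return ExtensionCoeffs(0, np.zeros((0, 0)), np.zeros((0, 0)))
    if not 1 <= L <= 2**grid.j:
        raise ValueError(f"L must satisfy 1 <= L <= 2^j; got L={L}, j={grid.j}")
    nodes = grid.nodes
    nmax = 2**grid.j
    left = np.vstack([_lagrange_row(grid.node(-(i + 1)), nodes[:L])
                      for i in range(L)])
    right = np.vstack([_lagrange_row(grid.node(nmax + 1 + i), nodes[nmax - L + 1:])
                       for i in range(L)])
    return ExtensionCoeffs(L, left, right)


def extrapolate_external_lagrange(values, grid: IntervalGrid, L: int):
    """External values f(x_{j,n}) for n = -1..-L (left) and 2^j+1..2^j+L (right)."""
    values = np.asarray(values, dtype=float)
    if values.shape[-1] != grid.n_nodes:
        raise ValueError(f"expected {grid.n_nodes} nodal values, got {values.shape[-1]}")
    c = lagrange_extension_coeffs(grid, L)
    left = values[..., :L] @ c.left_weights.T
    right = values[..., -L:] @ c.right_weights.T
    return left, right


def extension_matrix(grid: IntervalGrid, L_left: int, L_right: int,
                     width_left: int | None = None,
                     width_right: int | None = None) -> np.ndarray:
    """Map interior nodal values to the extended vector (n = -W_l..2^j+W_r).

    L per side sets the extrapolation *order* (degree L-1, from the L interior
    nodes nearest that boundary); the extension *width* W >= L sets how many
    external points are filled (default W = L).  A compactly supported basis
    needs W to cover its support so that boundary quadrature identities --
    constant reproduction in particular -- hold exactly; the extrapolation
    order stays the accuracy/roughness knob.

    Row order is ascending in n: rows 0..W_l-1 are the left external points
    (farthest first), then the interior identity, then the right externals.
    """
    n = grid.n_nodes
    Wl = L_left if width_left is None else max(width_left, L_left)
    Wr = L_right if width_right is None else max(width_right, L_right)
    if (Wl and not L_left) or (Wr and not L_right):
        raise ValueError("a positive extension width requires L >= 1 on that side")
    E = np.zeros((Wl + n + Wr, n))
    E[Wl:Wl + n, :] = np.eye(n)
    for i in range(Wl):
        # ascending n puts external node -(i+1) at row Wl-1-i
        E[Wl - 1 - i, :L_left] = _lagrange_row(grid.node(-(i + 1)), grid.nodes[:L_left])
    for i in range(Wr):
        E[Wl + n + i, n - L_right:] = _lagrange_row(grid.node(2**grid.j + 1 + i),
                                                    grid.nodes[n - L_right:])
    return E


# ---------------------------------------------------------------------------
# Newton divided differences (dynamic L)
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DividedDifferenceTable:
    """Triangular table; levels[m][i] = f[x_i, ..., x_{i+m}]."""

    nodes: np.ndarray
    levels: list

    @property
    def depth(self) -> int:
        return len(self.levels) - 1

    @property
    def top_row(self) -> np.ndarray:
        """f[x_0..x_m] for m = 0..depth (the Newton coefficients)."""
        return np.array([lvl[0] for lvl in self.levels])


def divided_differences(nodes, values, depth: int | None = None) -> DividedDifferenceTable:
    nodes = np.asarray(nodes, dtype=float)
    values = np.asarray(values, dtype=float)
    if nodes.size != values.size:
        raise ValueError("nodes and values must have equal length")
    if np.unique(nodes).size != nodes.size:
        raise ValueError("nodes must be distinct")
    if depth is None:
        depth = nodes.size - 1
    if depth >= nodes.size:
        raise ValueError("depth must be < number of nodes")
    levels = [values.copy()]
    for m in range(1, depth + 1):
        prev = levels[-1]
        levels.append((prev[1:] - prev[:-1]) / (nodes[m:] - nodes[:-m]))
    return DividedDifferenceTable(nodes, levels)


def extrapolate_external_newton(table: DividedDifferenceTable, x_external: float,
                                L: int) -> float:
    """Truncated Newton form using the first L points (degree L-1).

    Equals the Lagrange extrapolation through the same L nodes; raising L by
    one adds exactly one product term (the inheritance property).
    """
    if L < 1 or L - 1 > table.depth:
        raise ValueError("L exceeds the divided-difference table depth")
    coeffs = table.top_row
    acc = coeffs[0]
    prod = 1.0
    for m in range(1, L):
        prod *= (x_external - table.nodes[m - 1])
        acc += coeffs[m] * prod
    return float(acc)


class NewtonExtrapolator:
    """Incremental Newton extrapolation with an operation counter.

    Points are added one at a time; each addition extends the divided
    difference table by one antidiagonal (O(current L) divisions) and each
    evaluation update costs O(1) products, so the counter grows linearly in L
    -- in contrast with rebuilding Lagrange weights, where raising L redoes
    O(L^2) products per external node.
    """

    def __init__(self, x_external: float):
        self.x = float(x_external)
        self.nodes: list[float] = []
        self.diag: list[float] = []   # trailing antidiagonal of the table
        self.coeffs: list[float] = []
        self._prod = 1.0
        self.value = 0.0
        self.ops = 0

    @property
    def L(self) -> int:
        return len(self.nodes)

    def add_point(self, x: float, f: float) -> float:
        """Add node (x, f); returns the updated extrapolant value."""
        new_diag = [float(f)]
        for m, prev in enumerate(self.diag):
            new_diag.append((new_diag[-1] - prev) / (x - self.nodes[-(m + 1)]))
            self.ops += 1
        self.diag = new_diag
        self.coeffs.append(new_diag[-1])
        if self.nodes:
            self._prod *= (self.x - self.nodes[-1])
            self.ops += 1
        self.nodes.append(float(x))
        self.value += self.coeffs[-1] * self._prod
        self.ops += 1
        return self.value


# ---------------------------------------------------------------------------
# Dynamic choice of L
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class DynamicLConfig:
    """Thresholds controlling the dynamic extension order.

    T_a : absolute tolerance on divided differences (on [0,1]-scaled
        intensities); eps : the divided-difference criterion threshold,
        defaulting to T_a; L_max : hard cap; cond_ratio_max : largest
        admissible growth of the condition number when L increases by one.
    """

    T_a: float = 1e-3
    eps: float | None = None
    L_max: int = 6
    cond_ratio_max: float = 10.0

    def __post_init__(self):
        if self.T_a <= 0 or (self.eps is not None and self.eps <= 0):
            raise ValueError("tolerances must be positive")
        if self.L_max < 1:
            raise ValueError("L_max must be >= 1")

    @property
    def threshold(self) -> float:
        return self.T_a if self.eps is None else self.eps


def select_L_from_differences(diffs, cfg: DynamicLConfig, cond_probe=None) -> int:
    """Pick L from |f[x_0..x_m]| magnitudes (diffs[m-1] = order-m difference).

    The smallest L with |f[x_0..x_L]| < threshold, or with the magnitude
    decaying below the previous order, wins.  When neither branch ever
    triggers the difference sequence is growing -- the boundary data are
    rough and high-order extrapolation would amplify that roughness -- so the
    fallback is the order with the smallest difference magnitude (L = 1 for
    monotone growth), the choice that minimizes the extrapolation error
    polynomial.  An increase of L whose condition-number ratio reaches
    ``cond_ratio_max`` is never accepted.
    """
    d = np.abs(np.asarray(diffs, dtype=float))
    if d.size < 1:
        raise ValueError("need at least one divided difference")
    cap = min(cfg.L_max, d.size)
    thresh = cfg.threshold
    chosen = None
    for L in range(1, cap + 1):
        if d[L - 1] < thresh or (L >= 2 and d[L - 1] < d[L - 2]):
            chosen = L
            break
    if chosen is None:
        chosen = int(np.argmin(d[:cap])) + 1
        log.debug("dynamic-L: no decay criterion met up to L_max=%d; "
                  "falling back to the smallest-difference order L=%d",
                  cfg.L_max, chosen)
    if cond_probe is not None and chosen > 1:
        prev = float(cond_probe(1))
        for L in range(2, chosen + 1):
            cur = float(cond_probe(L))
            if prev > 0 and cur / prev >= cfg.cond_ratio_max:
                return L - 1
            prev = cur
    return chosen


def select_L_dynamic(boundary_values, cfg: DynamicLConfig, cond_probe=None,
                     spacing: float = 1.0) -> int:
    """Dynamic extension order from the L_max+1 nodal values nearest a boundary."""
    v = np.asarray(boundary_values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 boundary values")
    nodes = spacing * np.arange(v.size)
    table = divided_differences(nodes, v)
    diffs = np.abs(table.top_row[1:])
    return select_L_from_differences(diffs, cfg, cond_probe)


# ---------------------------------------------------------------------------
# Interval interpolant
# ---------------------------------------------------------------------------

def basis_matrix(xs, grid: IntervalGrid, spec: ScalingFunctionSpec,
                 deriv: int = 0, L_left: int = 0, L_right: int = 0) -> np.ndarray:
    """Collocation matrix B[t, k] = w_{j,k}^(deriv)(xs[t]).

    The interval basis w_{j,k} is the scaling-function shift phi(2^j x' - k)
    plus its Lagrange-extension corrections, folded in by composing the plain
    shift evaluations with the extension matrix.  For a compactly supported
    basis the extension width is the support half-width (so that boundary
    quadrature identities hold exactly); L sets the extrapolation order.
    """
    xs = np.atleast_1d(np.asarray(xs, dtype=float))
    span = grid.xmax - grid.xmin
    u = (xs - grid.xmin) / span * 2**grid.j
    if spec.family == "daub_autocorr" and L_left and L_right:
        Wl = max(L_left, 2 * spec.M - 2)
        Wr = max(L_right, 2 * spec.M - 2)
    else:
        Wl, Wr = L_left, L_right
    n_ext = np.arange(-Wl, 2**grid.j + Wr + 1)
    Phi = spec.evaluate(u[:, None] - n_ext[None, :], deriv)
    Phi = Phi * (2.0**grid.j / span) ** deriv
    E = extension_matrix(grid, L_left, L_right, Wl, Wr)
    return Phi @ E


class IntervalInterpolant:
    """Evaluator of the interval wavelet interpolant f_j and its derivatives."""

    def __init__(self, values, grid: IntervalGrid, L: int,
                 spec: ScalingFunctionSpec):
        self.values = np.asarray(values, dtype=float)
        if self.values.size != grid.n_nodes:
            raise ValueError(f"expected {grid.n_nodes} nodal values")
        self.grid = grid
        self.L = L
        self.spec = spec

    def __call__(self, x, deriv: int = 0):
        x = np.asarray(x, dtype=float)
        if np.any(x < self.grid.xmin - 1e-12) or np.any(x > self.grid.xmax + 1e-12):
            raise ValueError("evaluation outside [xmin, xmax]")
        B = basis_matrix(x, self.grid, self.spec, deriv, self.L, self.L)
        out = B @ self.values
        return float(out[0]) if out.size == 1 and x.ndim == 0 else out


def interval_interpolant(values, grid: IntervalGrid, L: int,
                         spec: ScalingFunctionSpec) -> IntervalInterpolant:
    return IntervalInterpolant(values, grid, L, spec)
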