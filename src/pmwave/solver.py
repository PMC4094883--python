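"""Perona-Malik diffusion on the sparse multilevel grid.

The model is the anisotropic diffusion equation

    du/dt = div( c(h |grad u|) grad u ),    u(x, y, 0) = f(x, y)

on the unit square, with diffusivity c either rational, 1/(1 + (g/k)^2), or
exponential, exp(-(g/k)^2).  The diffusivity senses the intensity jump per
pixel -- its argument is h |grad u| with h the fine-grid spacing -- so the
edge threshold k lives on the [0, 1] intensity scale: k = 0.1 marks a 10%
intensity change between neighbouring pixels as an edge, independent of
image resolution.  Expanding the divergence gives the collocation form

    F = c (u_xx + u_yy) + h^2 q (u_x^2 u_xx + 2 u_x u_y u_xy + u_y^2 u_yy),

with q(s) = c'(s)/s evaluated at s = h |grad u|; q is smooth through zero
gradient for both diffusivities.  All spatial derivatives come from the
multilevel sparse-grid interpolant.

Time stepping embeds each step in a homotopy of the right-hand side between
t_n and t_{n+1}; truncating the perturbation series at first order yields an
explicit predictor (Euler step along F_n, the zeroth-order term) whose
wavelet coefficients are refreshed before the trapezoidal corrector -- i.e.
Heun's method with a sparse-coefficient update between the two stages.  After
every refresh the coefficients are thresholded, so the active collocation set
adapts (and typically shrinks) as the image smooths.

A dense explicit finite-difference solver (:func:`fd_reference_solve`) is
included as the comparison baseline: conservative fluxes, mirror boundaries,
forward Euler.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np

from .bases import ScalingFunctionSpec
from .conditioning import cond_estimate_1norm, linearized_update_matrix
from .interval import DynamicLConfig, divided_differences, select_L_from_differences
from .sparse_grid import (MultilevelGrid2D, SparseCoefficientSet,
                          active_point_count, compress, decompose,
                          reconstruct_grid)

__all__ = [
    "ImageField",
    "DiffusionConfig",
    "HPMStepState",
    "diffusivity",
    "pm_rhs",
    "homotopy_parameter",
    "hpm_step",
    "solve",
    "fd_reference_solve",
]

C_TYPES = ("rational", "exponential")


@dataclasses.dataclass
class ImageField:
    """Nodal values of u on the (2^J+1)^2 dyadic grid of the unit square."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape != (n, n):
            raise ValueError("ImageField values must be square")
        J = int(round(math.log2(n - 1)))
        if 2**J + 1 != n:
            raise ValueError("grid side must be 2^J + 1")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("nonfinite image values")

    @property
    def J(self) -> int:
        return int(round(math.log2(self.values.shape[0] - 1)))


@dataclasses.dataclass
class DiffusionConfig:
    """PDE, basis and grid parameters for a denoising run.

    c_type : diffusivity family; k : edge threshold on [0,1] intensities
    (gradients on unit-square coordinates); tau, t_end : time step and
    terminal time; spec : scaling-function family; j0 : coarsest level;
    threshold : surplus magnitude below which a collocation point goes
    inactive (None disables compression entirely); L : static extension
    order (scalar or per-side tuple); L_mode : "static" or "dynamic";
    dyn : thresholds for the dynamic choice; probe_level : grid level of the
    condition-number probe.
    """

    c_type: str = "rational"
    k: float = 0.1
    tau: float = 1e-5
    t_end: float = 5e-5
    spec: ScalingFunctionSpec = dataclasses.field(
        default_factory=lambda: ScalingFunctionSpec("daub_autocorr", M=3))
    j0: int = 4
    threshold: float | None = 1e-3
    L: int | tuple = 3
    L_mode: str = "static"
    dyn: DynamicLConfig = dataclasses.field(default_factory=DynamicLConfig)
    probe_level: int = 4

    def __post_init__(self):
        if self.c_type not in C_TYPES:
            raise ValueError(f"c_type must be one of {C_TYPES}")
        if self.k <= 0 or self.tau <= 0:
            raise ValueError("k and tau must be positive")
        if self.t_end < self.tau:
            raise ValueError("t_end must be >= tau")
        if self.L_mode not in ("static", "dynamic"):
            raise ValueError("L_mode must be 'static' or 'dynamic'")


@dataclasses.dataclass
class HPMStepState:
    """Per-step state: time, nodal values, cached RHS and coefficients."""

    t_n: float
    phi_n: np.ndarray
    F_n: np.ndarray
    coeffs: SparseCoefficientSet


def _diffusivity_fields(g: np.ndarray, c_type: str, k: float):
    """(c(g), q(g) = c'(g)/g); q is the smooth gradient factor through g=0."""
    s = (g / k) ** 2
    if c_type == "rational":
        c = 1.0 / (1.0 + s)
        q = -(2.0 / k**2) * c * c
    else:
        c = np.exp(-s)
        q = -(2.0 / k**2) * c
    return c, q


def diffusivity(g, cfg: DiffusionConfig):
    """c(|grad u|): 1 at zero gradient, decaying past the edge threshold k."""
    g = np.asarray(g, dtype=float)
    if np.any(g < 0):
        raise ValueError("gradient modulus must be nonnegative")
    c, _ = _diffusivity_fields(g, cfg.c_type, cfg.k)
    return float(c) if c.ndim == 0 else c


def pm_rhs(field, coeffs: SparseCoefficientSet, cfg: DiffusionConfig) -> np.ndarray:
    """div(c(|grad u|) grad u) at the collocation nodes, by the chain rule.

    All five derivatives u_x, u_y, u_xx, u_xy, u_yy are evaluated from the
    (masked) sparse interpolant.
    """
    if field is not None:
        V = field.values if isinstance(field, ImageField) else np.asarray(field)
        N = coeffs.grid.n(coeffs.grid.J)
        if V.shape != (N, N):
            raise ValueError("field shape inconsistent with coefficient grid")
    ux = reconstruct_grid(coeffs, 1, 0)
    uy = reconstruct_grid(coeffs, 0, 1)
    uxx = reconstruct_grid(coeffs, 2, 0)
    uxy = reconstruct_grid(coeffs, 1, 1)
    uyy = reconstruct_grid(coeffs, 0, 2)
    (xlo, xhi), _ = coeffs.grid.domain
    h = (xhi - xlo) / 2**coeffs.grid.J          # pixel spacing
    c, q = _diffusivity_fields(h * np.hypot(ux, uy), cfg.c_type, cfg.k)
    return c * (uxx + uyy) + h * h * q * (ux * ux * uxx + 2.0 * ux * uy * uxy
                                          + uy * uy * uyy)


def homotopy_parameter(t: float, t_n: float, t_n1: float) -> float:
    """eps(t) = (t - t_n)/(t_{n+1} - t_n), the step-local homotopy variable."""
    if t_n1 <= t_n:
        raise ValueError("t_{n+1} must exceed t_n")
    if t < t_n - 1e-15 or t > t_n1 + 1e-15:
        raise ValueError("t outside the step bracket")
    return (t - t_n) / (t_n1 - t_n)


def _decompose_compress(V, grid, cfg, L_sides) -> SparseCoefficientSet:
    c = decompose(V, grid, cfg.spec, L=L_sides)
    if cfg.threshold is not None:
        c = compress(c, cfg.threshold)
    return c


def _select_sides(V: np.ndarray, cfg: DiffusionConfig, spacing: float,
                  cond_probe=None) -> tuple:
    """Dynamic per-side extension order from boundary divided differences.

    For each side, order-m divided differences are computed along the
    boundary-normal direction on the L_max+1 nearest node lines and
    aggregated by maximum magnitude over the lines.
    """
    m = min(cfg.dyn.L_max + 1, V.shape[0])
    nodes = spacing * np.arange(m)

    def diffs(block):  # block rows = lines, cols = distance from boundary
        d = []
        prev = block.T.astype(float)
        for order in range(1, m):
            prev = (prev[1:] - prev[:-1]) / (nodes[order:, None] - nodes[:-order, None])
            d.append(np.max(np.abs(prev[0])))
        return d

    sides = []
    for block in (V[:, :m], V[:, ::-1][:, :m], V[:m, :].T, V[::-1][:m, :].T):
        sides.append(select_L_from_differences(diffs(block), cfg.dyn, cond_probe))
    # order: x_left, x_right, y_low, y_high
    return tuple(sides)


def hpm_step(state: HPMStepState, cfg: DiffusionConfig,
             grid: MultilevelGrid2D | None = None, rhs=None) -> HPMStepState:
    """One predictor-corrector step of length tau.

    Predictor: explicit Euler along the cached F_n (the zeroth-order homotopy
    term); its coefficients are refreshed and thresholded before the second
    RHS evaluation.  Corrector: trapezoid over (F_n, F(predictor)).
    """
    if grid is None:
        grid = state.coeffs.grid
    if rhs is None:
        rhs = pm_rhs
    tau = cfg.tau
    pred = state.phi_n + tau * state.F_n
    coeffs_p = _decompose_compress(pred, grid, cfg, state.coeffs.L_sides)
    F_p = rhs(pred, coeffs_p, cfg)
    phi_next = state.phi_n + 0.5 * tau * (state.F_n + F_p)
    if not np.all(np.isfinite(phi_next)) or np.max(np.abs(phi_next)) > 1e12:
        raise RuntimeError("diverging values after step (unstable); reduce tau")
    coeffs_next = _decompose_compress(phi_next, grid, cfg, state.coeffs.L_sides)
    F_next = rhs(phi_next, coeffs_next, cfg)
    return HPMStepState(state.t_n + tau, phi_next, F_next, coeffs_next)


def solve(image, cfg: DiffusionConfig, rhs=None, collect=None):
    """Run the denoising flow to t_end; returns (ImageField, diagnostics).

    Diagnostics: per-step active point counts, sup-norm change, selected
    extension orders and (in dynamic mode) condition estimates.  ``collect``
    may be a list that receives one dict per step.
    """
    field = image if isinstance(image, ImageField) else ImageField(np.asarray(image))
    V = field.values.copy()
    J = field.J
    j0 = min(cfg.j0, J)
    grid = MultilevelGrid2D(j0, J)
    n_steps = int(math.ceil(cfg.t_end / cfg.tau - 1e-12))
    spacing = 1.0 / 2**J
    if rhs is None:
        rhs = pm_rhs

    diagnostics = {"active_points": [], "sup_change": [], "L_sides": [],
                   "cond": [], "t": []}

    def cond_probe_factory(Vc):
        np_side = 2 ** min(cfg.probe_level, J) + 1
        stride = (Vc.shape[0] - 1) // (np_side - 1)
        probe_state = Vc[::stride, ::stride]
        cache = {}

        def probe(L):
            if L not in cache:
                A = linearized_update_matrix(probe_state, cfg.spec, L, cfg.tau,
                                             cfg.c_type, cfg.k)
                cache[L] = cond_estimate_1norm(A)
            return cache[L]
        return probe

    t = 0.0
    state = None
    for step in range(n_steps):
        probe = cond_probe_factory(V)
        if cfg.L_mode == "dynamic":
            L_sides = _select_sides(V, cfg, spacing, probe)
        else:
            L_sides = tuple(cfg.L) if not np.isscalar(cfg.L) else (cfg.L,) * 4
        if state is None or tuple(state.coeffs.L_sides) != tuple(L_sides):
            coeffs = _decompose_compress(V, grid, cfg, L_sides)
            state = HPMStepState(t, V, rhs(V, coeffs, cfg), coeffs)
        diagnostics["active_points"].append(active_point_count(state.coeffs))
        diagnostics["L_sides"].append(tuple(state.coeffs.L_sides))
        diagnostics["cond"].append(probe(max(state.coeffs.L_sides)))
        diagnostics["t"].append(t + cfg.tau)
        new_state = hpm_step(state, cfg, grid, rhs)
        diagnostics["sup_change"].append(
            float(np.max(np.abs(new_state.phi_n - state.phi_n))))
        if collect is not None:
            collect.append({"step": step + 1, "t": new_state.t_n,
                            "L_sides": tuple(state.coeffs.L_sides),
                            "cond": diagnostics["cond"][-1],
                            "active_points": diagnostics["active_points"][-1]})
        V = new_state.phi_n
        t = new_state.t_n
        state = new_state
    return ImageField(V), diagnostics


def fd_reference_solve(image, cfg: DiffusionConfig):
    """Explicit conservative finite-difference baseline.

    Central differences for the gradient modulus, diffusivity averaged onto
    cell faces, flux-form divergence with zero boundary flux (mirror
    boundaries), forward Euler with the same tau.  The flux form makes the
    gray-level sum exactly conserved.
    """
    field = image if isinstance(image, ImageField) else ImageField(np.asarray(image))
    V = field.values.copy()
    N = V.shape[0]
    h = 1.0 / (N - 1)
    if cfg.tau > 0.25 * h * h:
        warnings.warn("tau exceeds the explicit stability bound h^2/4",
                      RuntimeWarning, stacklevel=2)
    n_steps = int(math.ceil(cfg.t_end / cfg.tau - 1e-12))
    for _ in range(n_steps):
        P = np.pad(V, 1, mode="reflect")
        gx = (P[1:-1, 2:] - P[1:-1, :-2]) / (2 * h)
        gy = (P[2:, 1:-1] - P[:-2, 1:-1]) / (2 * h)
        c, _ = _diffusivity_fields(h * np.hypot(gx, gy), cfg.c_type, cfg.k)
        cfx = 0.5 * (c[:, 1:] + c[:, :-1])          # faces between columns
        cfy = 0.5 * (c[1:, :] + c[:-1, :])          # faces between rows
        flux_x = cfx * (V[:, 1:] - V[:, :-1])
        flux_y = cfy * (V[1:, :] - V[:-1, :])
        div = np.zeros_like(V)
        div[:, :-1] += flux_x
        div[:, 1:] -= flux_x
        div[:-1, :] += flux_y
        div[1:, :] -= flux_y
        V = V + cfg.tau / (h * h) * div
    return ImageField(V)
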