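"""Interpolating scaling functions used as collocation bases.

Three families are supported, all satisfying the interpolation (cardinal)
property phi(0) = 1, phi(n) = 0 for every nonzero integer n, so that nodal
values of a field double as expansion coefficients:

``shannon``
    The band-limited cardinal function sin(pi x)/(pi x).  Globally supported;
    it decays only like 1/x, so in practice it is truncated beyond a
    configurable radius (an approximation knob, not part of the math).

``shannon_gabor``
    The sinc windowed by a Gaussian exp(-x^2 / (2 sigma^2)).  The window
    localizes derivative stencils at the price of the sinc's orthogonality.

``daub_autocorr``
    The autocorrelation of the orthonormal Daubechies scaling function with
    M vanishing moments, i.e. the Deslauriers-Dubuc fundamental function of
    the 2M-point iterative interpolation scheme.  Compactly supported on
    [-(2M-1), 2M-1], symmetric, and it reproduces polynomials of degree
    <= 2M-1.  It has no closed form; it is evaluated from exact dyadic tables
    (see :func:`build_daub_autocorrelation`).

Evaluation accuracy for ``daub_autocorr``: values of phi and phi' at dyadic
points of resolution 2^-r are exact (refinement-equation subdivision); between
those points, and for the second derivative everywhere, evaluation goes
through the C^1 cubic Hermite interpolant of the (phi, phi') tables.  The
second derivative of a piecewise cubic is piecewise linear and only
approximates phi'' pointwise -- phi'' of the Deslauriers-Dubuc function is
barely continuous -- but the Hermite construction reproduces polynomials
(degree <= 3) with exact derivatives, which is the property the collocation
operators rely on.
"""

from __future__ import annotations

import dataclasses
import functools

import numpy as np
import pywt
from scipy.interpolate import CubicHermiteSpline

__all__ = [
    "FAMILIES",
    "ScalingFunctionSpec",
    "DyadicSamples",
    "eval_shannon",
    "eval_shannon_gabor",
    "build_daub_autocorrelation",
    "eval_basis_2d",
]

FAMILIES = ("shannon", "shannon_gabor", "daub_autocorr")

_DEFAULT_TRUNCATION = 40


# ---------------------------------------------------------------------------
# Shannon / Shannon-Gabor (closed forms)
# ---------------------------------------------------------------------------

def _sinc_derivs(x: np.ndarray, deriv: int) -> np.ndarray:
    """phi(x) = sin(pi x)/(pi x) and its first two derivatives.

    The removable singularity at x = 0 is handled by Taylor series on
    |x| < 1e-3 (truncation error far below machine epsilon there).
    """
    x = np.asarray(x, dtype=float)
    s = np.pi * x
    small = np.abs(x) < 1e-3
    s_safe = np.where(small, 1.0, s)
    sin_s, cos_s = np.sin(s), np.cos(s)
    s2 = s * s
    if deriv == 0:
        series = 1.0 - s2 / 6.0 + s2 * s2 / 120.0
        full = sin_s / s_safe
    elif deriv == 1:
        series = np.pi * (-s / 3.0 + s * s2 / 30.0)
        full = np.pi * (s_safe * cos_s - sin_s) / (s_safe * s_safe)
    elif deriv == 2:
        series = np.pi**2 * (-1.0 / 3.0 + s2 / 10.0 - s2 * s2 / 168.0)
        full = np.pi**2 * (-s2 * sin_s - 2.0 * s * cos_s + 2.0 * sin_s) / (s_safe**3)
    else:
        raise ValueError(f"unsupported derivative order {deriv}")
    return np.where(small, series, full)


def eval_shannon(x, deriv_order: int = 0, truncation_radius: int | None = None):
    """Shannon (sinc) scaling function or its first/second derivative.

    Total function of x; with a truncation radius supplied, values (and
    derivatives) are forced to zero for |x| > radius.
    """
    if deriv_order not in (0, 1, 2):
        raise ValueError("deriv_order must be 0, 1 or 2")
    x = np.asarray(x, dtype=float)
    out = _sinc_derivs(x, deriv_order)
    if truncation_radius is not None:
        out = np.where(np.abs(x) > truncation_radius, 0.0, out)
    return out if out.ndim else float(out)


def eval_shannon_gabor(x, sigma: float, deriv_order: int = 0,
                       truncation_radius: int | None = None):
    """Gaussian-windowed sinc w(x) = sinc(x) exp(-x^2/(2 sigma^2))."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if deriv_order not in (0, 1, 2):
        raise ValueError("deriv_order must be 0, 1 or 2")
    x = np.asarray(x, dtype=float)
    g = np.exp(-x * x / (2.0 * sigma**2))
    if deriv_order == 0:
        out = _sinc_derivs(x, 0) * g
    else:
        phi = _sinc_derivs(x, 0)
        dphi = _sinc_derivs(x, 1)
        dg = -(x / sigma**2) * g
        if deriv_order == 1:
            out = dphi * g + phi * dg
        else:
            d2phi = _sinc_derivs(x, 2)
            d2g = (x * x / sigma**4 - 1.0 / sigma**2) * g
            out = d2phi * g + 2.0 * dphi * dg + phi * d2g
    if truncation_radius is not None:
        out = np.where(np.abs(x) > truncation_radius, 0.0, out)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Daubechies autocorrelation (Deslauriers-Dubuc fundamental function)
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class DyadicSamples:
    """Exact dyadic samples of the Daubechies-M autocorrelation function.

    ``x`` covers the support [-(2M-1), 2M-1] with spacing 2^-level; ``phi``
    and ``dphi`` are exact values of the function and its first derivative
    there (refinement subdivision), ``d2phi`` is the second derivative of the
    Hermite interpolant at the same abscissae.
    """

    M: int
    level: int
    x: np.ndarray
    phi: np.ndarray
    dphi: np.ndarray
    d2phi: np.ndarray
    _spline: CubicHermiteSpline = dataclasses.field(repr=False)

    @property
    def support(self) -> int:
        return 2 * self.M - 1

    def evaluate(self, u, deriv: int = 0) -> np.ndarray:
        """phi^(deriv)(u); exactly zero outside the compact support."""
        if deriv not in (0, 1, 2):
            raise ValueError("deriv must be 0, 1 or 2")
        u = np.atleast_1d(np.asarray(u, dtype=float))
        pp = self._spline if deriv == 0 else self._spline.derivative(deriv)
        out = pp(u)
        out = np.where(np.isfinite(out), out, 0.0)
        return out


def _dd_refinement_mask(M: int) -> np.ndarray:
    """Refinement mask a_n, n = -(2M-1)..(2M-1), of the autocorrelation.

    If the Daubechies scaling function satisfies phi(x) = sqrt(2) sum h_k
    phi(2x-k) with sum h_k^2 = 1, its autocorrelation satisfies
    Phi(x) = sum_n a_n Phi(2x-n) with a_n = sum_k h_k h_{k-n}: a_0 = 1 and
    a_n = 0 at even n by orthonormality of integer shifts.
    """
    h = np.asarray(pywt.Wavelet(f"db{M}").dec_lo, dtype=float)
    a = np.correlate(h, h, mode="full")  # length 4M-1, centre index 2M-1
    a = 0.5 * (a + a[::-1])  # enforce symmetry
    # offset n = index - (2M-1): even offsets vanish by orthonormality of
    # integer shifts (they sit at odd indices because the centre is odd)
    a[1::2] = 0.0
    a[2 * M - 1] = 1.0       # a_0
    return a


def _subdivide(int_values: np.ndarray, mask: np.ndarray, kappa: float,
               level: int, S: int) -> np.ndarray:
    """Dyadic subdivision f(x) = kappa * sum_n a_n f(2x - n) down to 2^-level.

    ``int_values`` holds f at the integers -S..S.  Returns values on the grid
    of spacing 2^-level over [-S, S]; dyadic values are exact because each
    refinement evaluates the two-scale relation, never an approximation.
    """
    vals = np.asarray(int_values, dtype=float)
    for rho in range(level):
        n_old = vals.size
        new = np.zeros(2 * n_old - 1)
        new[::2] = vals
        q = np.arange(1, new.size, 2)
        acc = np.zeros(q.size)
        for off, a_n in zip(range(-S, S + 1), mask):
            if a_n == 0.0:
                continue
            # new index q sits at x* = (q - S 2^{rho+1}) 2^-(rho+1); the
            # argument 2x* - off lands on old index q - (S + off) 2^rho
            p = q - (S + off) * (2**rho)
            valid = (p >= 0) & (p < n_old)
            acc[valid] += a_n * vals[p[valid]]
        new[1::2] = kappa * acc
        vals = new
    return vals


def _dphi_integer_values(mask: np.ndarray, S: int) -> np.ndarray:
    """Exact phi' at the integers -S..S via the refinement eigenproblem.

    phi'(x) = 2 sum a_n phi'(2x-n); the integer values form the eigenvector
    of T_{ik} = 2 a_{2i-k} with eigenvalue 1, normalized by the derivative of
    the linear-reproduction identity: sum_k k phi'(k) = -1.
    """
    idx = np.arange(-(S - 1), S)  # interior integers; phi' vanishes at +-S
    T = np.zeros((idx.size, idx.size))
    for ii, i in enumerate(idx):
        for kk, k in enumerate(idx):
            off = 2 * i - k
            if -S <= off <= S:
                T[ii, kk] = 2.0 * mask[off + S]
    w, V = np.linalg.eig(T)
    pos = int(np.argmin(np.abs(w - 1.0)))
    v = np.real(V[:, pos])
    v = 0.5 * (v - v[::-1])  # phi' is odd
    scale = np.dot(idx, v)
    v = -v / scale
    out = np.zeros(2 * S + 1)
    out[1:-1] = v
    return out


@functools.lru_cache(maxsize=8)
def build_daub_autocorrelation(M: int, dyadic_resolution: int = 10) -> DyadicSamples:
    """Tabulate the Daubechies-M autocorrelation on a 2^-r dyadic grid.

    Exact dyadic values of phi (from the cardinal data phi(n) = delta_n) and
    of phi' (from the refinement eigenproblem) are produced by subdivision;
    the attached C^1 Hermite interpolant provides off-dyadic values and the
    second derivative.
    """
    if M < 2:
        raise ValueError("M must be >= 2")
    if dyadic_resolution < 8:
        raise ValueError("dyadic_resolution must be >= 8")
    S = 2 * M - 1
    mask = _dd_refinement_mask(M)

    phi_int = np.zeros(2 * S + 1)
    phi_int[S] = 1.0
    phi = _subdivide(phi_int, mask, 1.0, dyadic_resolution, S)
    dphi = _subdivide(_dphi_integer_values(mask, S), mask, 2.0,
                      dyadic_resolution, S)
    x = np.linspace(-S, S, phi.size)
    spline = CubicHermiteSpline(x, phi, dphi, extrapolate=False)
    d2 = spline.derivative(2)(x)
    d2[~np.isfinite(d2)] = 0.0
    return DyadicSamples(M=M, level=dyadic_resolution, x=x, phi=phi,
                         dphi=dphi, d2phi=d2, _spline=spline)


# ---------------------------------------------------------------------------
# Unified spec
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ScalingFunctionSpec:
    """Which interpolating scaling function is in play, with its parameters.

    family : "shannon" | "shannon_gabor" | "daub_autocorr"
    M : vanishing-moment order (daub_autocorr only, >= 2)
    sigma : Gaussian window width (shannon_gabor only, > 0)
    truncation_radius : support cut-off in grid units (shannon families)
    dyadic_resolution : r >= 8; daub table spacing is 2^-r
    """

    family: str
    M: int | None = None
    sigma: float | None = None
    truncation_radius: int | None = None
    dyadic_resolution: int = 10

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "daub_autocorr":
            if self.M is None or self.M < 2:
                raise ValueError("daub_autocorr requires M >= 2")
            if self.sigma is not None or self.truncation_radius is not None:
                raise ValueError("sigma/truncation_radius do not apply to daub_autocorr")
            if self.dyadic_resolution < 8:
                raise ValueError("dyadic_resolution must be >= 8")
        else:
            if self.M is not None:
                raise ValueError("M applies to daub_autocorr only")
            if self.family == "shannon_gabor":
                if self.sigma is None or self.sigma <= 0:
                    raise ValueError("shannon_gabor requires sigma > 0")
            elif self.sigma is not None:
                raise ValueError("sigma applies to shannon_gabor only")
            if self.truncation_radius is None:
                object.__setattr__(self, "truncation_radius", _DEFAULT_TRUNCATION)
            elif self.truncation_radius <= 0:
                raise ValueError("truncation_radius must be positive")

    @property
    def support_radius(self) -> int:
        """Half-width in grid units beyond which the basis is exactly zero."""
        if self.family == "daub_autocorr":
            return 2 * self.M - 1
        return self.truncation_radius

    def evaluate(self, u, deriv: int = 0) -> np.ndarray:
        """phi^(deriv)(u) for this family, vectorized over u."""
        if self.family == "shannon":
            return np.atleast_1d(eval_shannon(u, deriv, self.truncation_radius))
        if self.family == "shannon_gabor":
            return np.atleast_1d(
                eval_shannon_gabor(u, self.sigma, deriv, self.truncation_radius))
        table = build_daub_autocorrelation(self.M, self.dyadic_resolution)
        return table.evaluate(u, deriv)


def eval_basis_2d(spec: ScalingFunctionSpec, j: int, k1: int, k2: int,
                  x, y, m: int = 0, n: int = 0,
                  domain=((0.0, 1.0), (0.0, 1.0))):
    """Tensor-product 2-D basis d^m/dx^m d^n/dy^n [phi(2^j x'-k1) phi(2^j y'-k2)].

    x', y' are the coordinates normalized to [0, 1] on ``domain``; the chain
    rule contributes a factor (2^j / span)^(m+n).
    """
    if m + n > 2 or m < 0 or n < 0:
        raise ValueError("mixed derivative order m+n must be <= 2")
    (xmin, xmax), (ymin, ymax) = domain
    sx = (np.asarray(x, dtype=float) - xmin) / (xmax - xmin)
    sy = (np.asarray(y, dtype=float) - ymin) / (ymax - ymin)
    fx = spec.evaluate(2.0**j * sx - k1, m) * (2.0**j / (xmax - xmin)) ** m
    fy = spec.evaluate(2.0**j * sy - k2, n) * (2.0**j / (ymax - ymin)) ** n
    out = fx * fy
    return float(out[0]) if out.size == 1 else out
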