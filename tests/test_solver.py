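"""Diffusion solver: diffusivities, RHS limits, time stepping, FD baseline."""

import math

import numpy as np
import pytest

from pmwave.sparse_grid import MultilevelGrid2D, decompose
from pmwave.solver import (DiffusionConfig, HPMStepState, ImageField,
                           diffusivity, fd_reference_solve, homotopy_parameter,
                           hpm_step, pm_rhs, solve)


def _grid_fields(J):
    grid = MultilevelGrid2D(2, J)
    xs = grid.nodes_1d(J, 0)
    X, Y = np.meshgrid(xs, xs)
    return grid, X, Y


def test_diffusivity_values():
    cfg = DiffusionConfig(k=0.1)
    assert diffusivity(0.0, cfg) == 1.0
    assert diffusivity(0.1, cfg) == pytest.approx(0.5)      # 1/(1+1)
    cfge = DiffusionConfig(c_type="exponential", k=0.1)
    assert diffusivity(0.0, cfge) == 1.0
    assert diffusivity(0.1, cfge) == pytest.approx(math.exp(-1.0))
    with pytest.raises(ValueError):
        diffusivity(-1.0, cfg)


def test_rhs_constant_field_is_zero(daub_spec):
    grid, X, Y = _grid_fields(5)
    cfg = DiffusionConfig(k=0.1, j0=2, L=4, threshold=None)
    coeffs = decompose(np.full((33, 33), 0.5), grid, daub_spec, L=4)
    assert np.max(np.abs(pm_rhs(None, coeffs, cfg))) < 1e-6


def test_rhs_reduces_to_laplacian_for_unit_diffusivity(daub_spec):
    # u = x^2 + y^2 with k -> infinity: F = laplacian = 4
    grid, X, Y = _grid_fields(5)
    cfg = DiffusionConfig(k=1e12, j0=2, L=4, threshold=None)
    coeffs = decompose(X**2 + Y**2, grid, daub_spec, L=4)
    F = pm_rhs(None, coeffs, cfg)
    assert np.max(np.abs(F - 4.0)) < 1e-3


def test_rhs_matches_finite_difference_discretization(daub_spec, rng):
    # dense 2nd-order FD oracle for div(c(h|grad u|) grad u) on the same grid
    grid, X, Y = _grid_fields(6)
    N, h = 65, 1.0 / 64
    k = 0.1
    V = 0.5 + 0.05 * np.sin(np.pi * X) * np.cos(np.pi * Y) \
        + 0.02 * np.sin(2 * np.pi * X + 0.3) * np.sin(np.pi * Y)
    cfg = DiffusionConfig(k=k, j0=2, L=4, threshold=None)
    coeffs = decompose(V, grid, daub_spec, L=4)
    F = pm_rhs(None, coeffs, cfg)

    P = np.pad(V, 1, mode="reflect")
    gx = (P[1:-1, 2:] - P[1:-1, :-2]) / (2 * h)
    gy = (P[2:, 1:-1] - P[:-2, 1:-1]) / (2 * h)
    c = 1.0 / (1.0 + (h * np.hypot(gx, gy) / k) ** 2)
    cfx = 0.5 * (c[:, 1:] + c[:, :-1])
    cfy = 0.5 * (c[1:, :] + c[:-1, :])
    flux_x = cfx * (V[:, 1:] - V[:, :-1])
    flux_y = cfy * (V[1:, :] - V[:-1, :])
    F_fd = np.zeros_like(V)
    F_fd[:, :-1] += flux_x
    F_fd[:, 1:] -= flux_x
    F_fd[:-1, :] += flux_y
    F_fd[1:, :] -= flux_y
    F_fd /= h * h
    interior = (slice(2, -2), slice(2, -2))
    assert np.max(np.abs(F[interior] - F_fd[interior])) < 10 * h * h


def test_homotopy_parameter():
    assert homotopy_parameter(0.0, 0.0, 1.0) == 0.0
    assert homotopy_parameter(1.0, 0.0, 1.0) == 1.0
    assert homotopy_parameter(0.5, 0.0, 1.0) == 0.5
    with pytest.raises(ValueError):
        homotopy_parameter(2.0, 0.0, 1.0)


def test_step_is_identity_for_zero_rhs(daub_spec):
    cfg = DiffusionConfig(j0=2, L=4, threshold=None, tau=1e-3, t_end=1e-3)
    grid = MultilevelGrid2D(2, 4)
    V = np.full((17, 17), 0.42)
    coeffs = decompose(V, grid, daub_spec, L=4)
    zero_rhs = lambda field, c, cfg_: np.zeros_like(V)
    state = HPMStepState(0.0, V, zero_rhs(None, None, None), coeffs)
    new = hpm_step(state, cfg, grid, rhs=zero_rhs)
    assert np.array_equal(new.phi_n, V)


def test_step_matches_scalar_closed_form():
    # phi' = lam phi: predictor-corrector gives phi (1 + z + z^2/2), z = lam tau
    lam, tau = -7.0, 1e-2
    cfg = DiffusionConfig(j0=2, tau=tau, t_end=tau, threshold=None, L=4)
    rhs = lambda field, coeffs, cfg_: lam * (field.values if isinstance(field, ImageField)
                                             else np.asarray(field))
    out, _ = solve(np.ones((17, 17)), cfg, rhs=rhs)
    z = lam * tau
    assert np.max(np.abs(out.values - (1 + z + z * z / 2))) < 1e-14


def test_heun_temporal_order_against_fine_reference(daub_spec):
    # c == 1 heat equation; reference = RK4 at 8x finer steps on the same
    # spatial operator isolates the time-stepping error
    grid, X, Y = _grid_fields(5)
    u0 = 0.5 + 0.25 * np.sin(np.pi * X) * np.sin(np.pi * Y)
    t_end = 4e-4

    def rhs_vec(V, cfg):
        return pm_rhs(None, decompose(V, grid, daub_spec, L=4), cfg)

    cfg_ref = DiffusionConfig(k=1e12, j0=2, L=4, threshold=None, tau=1e-5, t_end=t_end)
    V = u0.copy()
    n_ref, hr = 320, t_end / 320
    for _ in range(n_ref):
        k1 = rhs_vec(V, cfg_ref)
        k2 = rhs_vec(V + hr / 2 * k1, cfg_ref)
        k3 = rhs_vec(V + hr / 2 * k2, cfg_ref)
        k4 = rhs_vec(V + hr * k3, cfg_ref)
        V = V + hr / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    reference = V

    taus = [4e-5, 2e-5, 1e-5]
    errs = []
    for tau in taus:
        cfg = DiffusionConfig(k=1e12, j0=2, L=4, threshold=None, tau=tau, t_end=t_end)
        out, _ = solve(u0, cfg)
        errs.append(np.max(np.abs(out.values - reference)))
    slope = np.polyfit(np.log(taus), np.log(errs), 1)[0]
    assert 1.7 <= slope <= 2.3


def test_heat_limit_matches_crank_nicolson(daub_spec):
    # both solvers approximate the same analytic decay of one Fourier mode
    grid, X, Y = _grid_fields(5)
    u0 = 0.5 + 0.25 * np.sin(np.pi * X) * np.sin(np.pi * Y)
    t_end, tau = 4e-4, 1e-5
    cfg = DiffusionConfig(k=1e12, j0=2, L=4, threshold=None, tau=tau, t_end=t_end)
    out, _ = solve(u0, cfg)
    # dense Crank-Nicolson on the 5-point Laplacian with Dirichlet edges
    # (the mode vanishes on the boundary)
    N = 33
    h = 1.0 / 32
    n_int = N - 2
    main = -4.0 * np.ones(n_int * n_int)
    A = np.diag(main)
    for r in range(n_int):
        for c in range(n_int):
            i = r * n_int + c
            if c + 1 < n_int:
                A[i, i + 1] = A[i + 1, i] = 1.0
            if r + 1 < n_int:
                A[i, i + n_int] = A[i + n_int, i] = 1.0
    A /= h * h
    I = np.eye(n_int * n_int)
    left = I - 0.5 * tau * A
    right = I + 0.5 * tau * A
    U = (u0[1:-1, 1:-1] - 0.5).ravel()
    for _ in range(int(round(t_end / tau))):
        U = np.linalg.solve(left, right @ U)
    cn = U.reshape(n_int, n_int) + 0.5
    # agreement within the spatial discretization gap of the two methods
    assert np.max(np.abs(out.values[1:-1, 1:-1] - cn)) < 5e-4


def test_solve_constant_image_fixed_point(daub_spec):
    cfg = DiffusionConfig(j0=2, L=4, tau=1e-5, t_end=3e-5)
    out, diag = solve(np.full((33, 33), 0.4), cfg)
    assert np.max(np.abs(out.values - 0.4)) < 1e-12
    assert len(set(diag["active_points"])) == 1


def test_solve_rejects_unstable_blowup(daub_spec):
    cfg = DiffusionConfig(k=1e12, j0=2, L=4, threshold=None, tau=5e-3, t_end=5e-2)
    with np.errstate(over="ignore", invalid="ignore"):
        with pytest.raises(RuntimeError):
            solve(np.random.default_rng(0).random((33, 33)), cfg)


def test_fd_reference_properties(rng):
    cfg = DiffusionConfig(tau=2e-5, t_end=1e-4, k=0.1)
    const = np.full((33, 33), 0.3)
    assert np.array_equal(fd_reference_solve(const, cfg).values, const)
    V = rng.random((33, 33))
    out = fd_reference_solve(V, cfg)
    assert abs(out.values.sum() - V.sum()) < 1e-10          # conservation
    grid, X, Y = _grid_fields(5)
    quad = X**2 + Y**2
    cfg1 = DiffusionConfig(tau=1e-5, t_end=1e-5, k=1e12)
    one = fd_reference_solve(quad, cfg1)
    inner = (slice(1, -1), slice(1, -1))
    assert np.max(np.abs(one.values[inner] - quad[inner] - 4e-5)) < 1e-12


def test_fd_warns_on_cfl_violation():
    cfg = DiffusionConfig(tau=1e-3, t_end=1e-3, k=1e12)
    with pytest.warns(RuntimeWarning):
        fd_reference_solve(np.zeros((33, 33)), cfg)


def test_edge_gradient_preserved_better_than_fd(daub_spec):
    # step-edge phantom: after 5 steps the mean absolute gradient across the
    # true edge stays higher for the wavelet solver than for the FD baseline
    from pmwave.imaging import PhantomSpec, generate_phantom
    spec = PhantomSpec(size=(65, 65), scene="step_edge", contrast=0.6,
                       noise_sigma=0.02, seed=5)
    clean, noisy = generate_phantom(spec)
    cfg = DiffusionConfig(k=0.1, tau=1e-5, t_end=5e-5, j0=4, threshold=1e-3)
    wave, _ = solve(noisy, cfg)
    fd = fd_reference_solve(noisy, cfg)
    col = 32  # the edge sits between columns 31 and 32 (x = 0.5)
    def edge_grad(img):
        return np.mean(np.abs(img[:, col + 1] - img[:, col - 1]))
    assert edge_grad(wave.values) > edge_grad(fd.values)


def test_stability_envelope_on_seeded_phantom(daub_spec):
    from pmwave.imaging import PhantomSpec, generate_phantom
    spec = PhantomSpec(size=(65, 65), scene="microgrooves", contrast=0.3,
                       noise_sigma=0.03, seed=11)
    _, noisy = generate_phantom(spec)
    cfg = DiffusionConfig(k=0.1, tau=1e-5, t_end=5e-5, j0=4, threshold=1e-3)
    out, _ = solve(noisy, cfg)
    assert out.values.min() >= noisy.min() - 0.01
    assert out.values.max() <= noisy.max() + 0.01
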