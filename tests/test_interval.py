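"""Interval basis: Lagrange extension, divided differences, dynamic order."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pmwave.interval import (DynamicLConfig, NewtonExtrapolator,
                             divided_differences, extrapolate_external_lagrange,
                             extrapolate_external_newton, interval_interpolant,
                             lagrange_extension_coeffs, make_interval_grid,
                             select_L_dynamic)


def test_interval_grid_nodes():
    assert np.allclose(make_interval_grid(0, 1, 2).nodes, [0, 0.25, 0.5, 0.75, 1])
    assert np.allclose(make_interval_grid(0, 1, 0).nodes, [0, 1])
    assert np.allclose(make_interval_grid(-1, 1, 1).nodes, [-1, 0, 1])
    with pytest.raises(ValueError):
        make_interval_grid(1, 0, 2)


def test_extension_weights():
    g = make_interval_grid(0, 4, 2)  # unit spacing
    c1 = lagrange_extension_coeffs(g, 1)
    assert c1.left_weights[0, 0] == pytest.approx(1.0)  # constant extrapolation
    c2 = lagrange_extension_coeffs(g, 2)
    # two-point linear weights for x_{-1}: (x-x1)/(x0-x1), (x-x0)/(x1-x0)
    assert np.allclose(c2.left_weights[0], [2.0, -1.0])
    for L in range(1, 5):
        c = lagrange_extension_coeffs(g, L)
        assert np.allclose(c.left_weights.sum(axis=1), 1.0)
        assert np.allclose(c.right_weights.sum(axis=1), 1.0)
    with pytest.raises(ValueError):
        lagrange_extension_coeffs(g, 5)


def test_extrapolation_polynomial_reproduction():
    g = make_interval_grid(0, 1, 2)
    const = np.full(5, 5.0)
    for L in range(1, 5):
        left, right = extrapolate_external_lagrange(const, g, L)
        assert np.allclose(left, 5.0) and np.allclose(right, 5.0)
    lin = g.nodes.copy()
    left, right = extrapolate_external_lagrange(lin, g, 2)
    assert left[0] == pytest.approx(-0.25)
    # degree-2 exactness with L = 3: oracle is the polynomial itself
    sq = g.nodes**2
    left, right = extrapolate_external_lagrange(sq, g, 3)
    assert np.allclose(left, [(-0.25)**2, (-0.5)**2, (-0.75)**2], atol=1e-13)
    assert np.allclose(right, [1.25**2, 1.5**2, 1.75**2], atol=1e-13)
    with pytest.raises(ValueError):
        extrapolate_external_lagrange(np.ones(4), g, 2)


def test_divided_difference_table():
    t = divided_differences([0, 1, 2], [0, 1, 4])
    assert np.allclose(t.top_row, [0, 1, 1])  # f[x0,x1]=1, f[x0,x1,x2]=(3-1)/2
    tc = divided_differences(np.arange(5), np.full(5, 3.3))
    assert np.allclose(tc.top_row[1:], 0.0)
    with pytest.raises(ValueError):
        divided_differences([0, 0, 1], [1, 2, 3])


@settings(deadline=None, max_examples=30)
@given(st.lists(st.floats(-5, 5), min_size=4, max_size=8, unique=True),
       st.data())
def test_newton_form_matches_lagrange_interpolant(xs, data):
    xs = np.sort(np.asarray(xs))
    if np.min(np.diff(xs)) < 1e-3:
        return
    vals = [data.draw(st.floats(-10, 10)) for _ in xs]
    table = divided_differences(xs, vals)
    x_eval = data.draw(st.floats(float(xs[0]) - 1, float(xs[-1]) + 1))
    L = len(xs)
    newton = extrapolate_external_newton(table, x_eval, L)
    # Lagrange oracle
    lag = 0.0
    for k in range(L):
        others = np.delete(xs, k)
        lag += vals[k] * np.prod((x_eval - others) / (xs[k] - others))
    assert newton == pytest.approx(lag, rel=1e-9, abs=1e-9)


def test_newton_equals_lagrange_extrapolation(rng):
    worst = 0.0
    for _ in range(100):
        g = make_interval_grid(0, 1, 3)
        v = rng.normal(size=g.n_nodes)
        for L in range(1, 7):
            lag, _ = extrapolate_external_lagrange(v, g, L)
            table = divided_differences(g.nodes[:L], v[:L])
            for i in range(L):
                nv = extrapolate_external_newton(table, g.node(-(i + 1)), L)
                worst = max(worst, abs(nv - lag[i]))
    assert worst < 1e-10


def test_newton_inheritance_and_linear_cost(rng):
    # raising L by one adds exactly one product term; the incremental
    # operation count is O(L), not O(L^2)
    x_ext = -0.2
    ne = NewtonExtrapolator(x_ext)
    xs = np.linspace(0, 1, 9)
    vals = rng.normal(size=9)
    values_by_L, ops_by_L = [], []
    for x, f in zip(xs, vals):
        values_by_L.append(ne.add_point(x, f))
        ops_by_L.append(ne.ops)
    for L in range(2, 9):
        table = divided_differences(xs[:L], vals[:L])
        prod = np.prod(x_ext - xs[:L - 1])
        reconstructed = values_by_L[L - 2] + table.top_row[L - 1] * prod
        assert reconstructed == pytest.approx(values_by_L[L - 1], rel=1e-10, abs=1e-12)
    increments = np.diff(ops_by_L)
    assert np.all(np.diff(increments) == 1)  # linear growth in L


def test_dynamic_L_selection_cases():
    cfg = DynamicLConfig(T_a=1e-3, L_max=6)
    assert select_L_dynamic(np.ones(7), cfg) == 1           # constant boundary
    assert select_L_dynamic(0.5 * np.arange(7), cfg) == 2   # linear, slope >= T_a
    probe = {1: 5.0, 2: 10.0, 3: 200.0}
    # growing-then-small differences would pick L=3, but cond ratio 20 >= 10
    vals = np.cumsum(np.exp(np.arange(7)))
    assert select_L_dynamic(vals, cfg, cond_probe=lambda L: probe.get(L, 1e6)) == 2
    with pytest.raises(ValueError):
        select_L_dynamic([1.0], cfg)


def test_dynamic_L_monotone_in_tolerance(rng):
    v = np.cumsum(rng.normal(size=8))
    previous = None
    for T_a in [1e-6, 1e-4, 1e-2, 1.0, 100.0]:
        L = select_L_dynamic(v, DynamicLConfig(T_a=T_a, L_max=6))
        if previous is not None:
            assert L <= previous
        previous = L


def test_interval_interpolant_properties(daub_spec):
    g = make_interval_grid(0, 1, 5)
    vals = g.nodes**3
    itp = interval_interpolant(vals, g, 4, daub_spec)
    assert np.max(np.abs(itp(g.nodes) - vals)) < 1e-10   # nodal interpolation
    const = interval_interpolant(np.full(g.n_nodes, 0.7), g, 4, daub_spec)
    xf = np.linspace(0, 1, 1001)
    assert np.max(np.abs(const(xf) - 0.7)) < 1e-8        # constant reproduction
    # higher extension order beats L=1 near the boundary on a cubic
    e4 = np.max(np.abs(itp(xf) - xf**3))
    e1 = np.max(np.abs(interval_interpolant(vals, g, 1, daub_spec)(xf) - xf**3))
    assert e4 < e1
    with pytest.raises(ValueError):
        itp(1.5)
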