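import mpmath
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from layerfluence import (DomainError, QUAD, build_medium, greens_bottom,
                          greens_top, layer_wavenumbers, slab_greens)


def _equal_stack(thicknesses, radius=20.0, mu_a=0.1, mu_sp=10.0):
    n = len(thicknesses)
    return build_medium([mu_a] * n, [mu_sp] * n, thicknesses, radius=radius)


S_GRID = np.array([0.05, 0.3, 1.0, 2.5, 5.0])


class TestSlabOracle:
    """Equal-property stacks must reproduce the single-slab closed form."""

    @pytest.mark.parametrize("thicknesses", [
        (10.0,), (5.0, 5.0), (2.0, 3.0, 5.0), (1.25,) * 8,
    ])
    @pytest.mark.parametrize("z", [0.0, 0.07, 1.1])
    def test_top(self, thicknesses, z):
        m = _equal_stack(thicknesses)
        if z > m.thicknesses[0]:
            pytest.skip("z outside layer 1 for this split")
        b = m.boundary
        got = greens_top(m, S_GRID, z).value
        want = np.array([slab_greens(0.1, 10.0, 10.0, b.z_b_top, b.z0, s, z)
                         for s in S_GRID])
        assert np.max(np.abs(got / want - 1)) < 1e-13

    @pytest.mark.parametrize("z", [5.5, 9.0, 10.0])
    def test_bottom(self, z):
        m = _equal_stack((2.0, 3.0, 5.0))
        b = m.boundary
        got = greens_bottom(m, S_GRID, z).value
        want = np.array([slab_greens(0.1, 10.0, 10.0, b.z_b_top, b.z0, s, z)
                         for s in S_GRID])
        assert np.max(np.abs(got / want - 1)) < 1e-13

    def test_underflow_regime_exact_zero(self):
        m = _equal_stack((5.0, 5.0))
        got = greens_bottom(m, np.array([500.0, 5000.0]), 10.0).value
        assert np.all(got == 0.0)


def test_extrapolated_boundary_condition():
    m = _equal_stack((5.0, 5.0))
    g = greens_top(m, S_GRID, -m.boundary.z_b_top).value
    scale = greens_top(m, S_GRID, 0.0).value
    assert np.max(np.abs(g) / np.abs(scale)) < 1e-12


def test_semiinfinite_bottom_limit():
    """A 100 cm bottom layer already is the infinite-bottom limit."""
    s = S_GRID
    a = build_medium([0.1, 0.2], [10.0, 12.0], [1.0, 100.0], radius=10.0)
    b = build_medium([0.1, 0.2], [10.0, 12.0], [1.0, 1000.0], radius=10.0)
    assert np.array_equal(greens_top(a, s, 0.0).value, greens_top(b, s, 0.0).value)


def test_no_overflow_high_scatter_thick_layers():
    """mu_s' = 80 with a 30 cm bottom layer at 50,000 roots stays finite."""
    from layerfluence import compute_roots
    m = build_medium([0.1] * 4, [80.0] * 4, [0.5, 1.5, 3.5, 30.0], radius=15.0)
    s = compute_roots(50000).roots / m.boundary.a_prime
    with np.errstate(over="raise"):
        g_top = greens_top(m, s, 0.0).value
        g_bot = greens_bottom(m, s, m.total_thickness_L).value
    assert np.all(np.isfinite(g_top)) and np.all(np.isfinite(g_bot))


def test_flux_continuity_at_interfaces():
    """D_k dG/dz is continuous across each interface (finite differences)."""
    m = build_medium([0.1, 0.3, 0.05], [10.0, 15.0, 8.0], [1.0, 2.0, 7.0],
                     radius=12.0)
    # evaluate just above/below the first interface using interior-capable
    # kernels: top layer handles z <= 1.0; use a 2-layer equivalent check
    s = 1.3
    eps = 1e-6
    z_if = 1.0
    g_above = greens_top(m, s, z_if - eps).value
    g_at = greens_top(m, s, z_if).value
    # value continuity comes from the construction; check the flux ratio via
    # the impedance recursion by comparing one-sided derivative of layer 1 to
    # the sweep's Z_2 prediction
    from layerfluence.greens import _sweep
    from layerfluence.precision import DOUBLE
    alpha, beta, E, rho = _sweep(m, s, 0.0, DOUBLE)
    x = rho[1] * E[1] * E[1]
    Z2 = beta[1] * (x - 1.0) / (1.0 + x)
    dG = (g_at - g_above) / eps
    D1 = m.layers[0].D
    assert np.abs(D1 * dG / g_at - Z2) / np.abs(Z2) < 1e-4


def test_reciprocity_equal_property_stack():
    """Slab form is symmetric under source/detector exchange."""
    b = _equal_stack((5.0, 5.0)).boundary
    for s in S_GRID:
        g1 = slab_greens(0.1, 10.0, 10.0, b.z_b_top, 0.3, s, 4.0)
        g2 = slab_greens(0.1, 10.0, 10.0, b.z_b_top, 4.0, s, 0.3)
        assert g1 == pytest.approx(g2, rel=1e-13)


@given(s=st.floats(min_value=0.01, max_value=50.0),
       re=st.floats(min_value=-30.0, max_value=5.0),
       im=st.floats(min_value=0.1, max_value=50.0))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_conjugate_symmetry(s, re, im):
    m = _equal_stack((2.0, 8.0))
    sb = complex(re, im)
    g = greens_top(m, np.array([s]), 0.0, sb).value[0]
    gc = greens_top(m, np.array([s]), 0.0, np.conj(sb)).value[0]
    assert g == pytest.approx(np.conj(gc), rel=1e-14, abs=1e-300)


def test_wavenumber_limits():
    m = _equal_stack((5.0, 5.0))
    wn = layer_wavenumbers(m, 0.0)
    assert wn.alpha[0] == pytest.approx(np.sqrt(3 * 0.1 * 10), rel=1e-14)
    big = layer_wavenumbers(m, 1e4).alpha[0]
    assert abs(big / 1e4 - 1) < 1e-4
    shifted = layer_wavenumbers(m, 1.0, 50.0 + 0j).alpha[0]
    assert shifted.real > layer_wavenumbers(m, 1.0, 0.0).alpha[0].real


def test_z_domain_errors():
    m = _equal_stack((5.0, 5.0))
    with pytest.raises(DomainError):
        greens_top(m, 1.0, 7.0)
    with pytest.raises(DomainError):
        greens_bottom(m, 1.0, 1.0)


def test_extended_precision_path_matches_double():
    m = _equal_stack((2.0, 8.0))
    with mpmath.workprec(113):
        for s in [0.5, 3.0]:
            gq = greens_top(m, mpmath.mpf(s), 0.0, ctx=QUAD).value
            gd = greens_top(m, np.array([s]), 0.0).value[0]
            assert abs(float(gq.real) / gd - 1) < 1e-13
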