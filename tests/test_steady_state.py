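import numpy as np
import pytest

from layerfluence import (ConvergenceControl, DomainError, SemiInfiniteModel,
                          approx_reflectance_ss, build_medium, fluence_ss,
                          reflectance_ss, ss_semiinf, transmittance_ss)


def test_matches_semiinfinite_closed_form(homog2):
    si = SemiInfiniteModel.from_medium(homog2)
    got = fluence_ss(homog2, 1.0, 0.0, ConvergenceControl(n_terms=1500))
    assert abs(got.values[0] - float(ss_semiinf(si, 1.0))) < 1e-12


def test_layering_invariance(homog2, homog8, rho_grid):
    ctrl = ConvergenceControl(n_terms=2000)
    a = fluence_ss(homog2, rho_grid, 0.0, ctrl).values
    b = fluence_ss(homog8, rho_grid, 0.0, ctrl).values
    assert np.max(np.abs(a / b - 1)) < 1e-13


def test_reflectance_close_to_semiinfinite_over_range(homog2):
    si = SemiInfiniteModel.from_medium(homog2)
    rho = np.linspace(0.5, 8.0, 16)
    got = reflectance_ss(homog2, rho, ConvergenceControl(rel_tol=1e-13)).values
    assert np.max(np.abs(got / ss_semiinf(si, rho) - 1)) < 0.05


def test_dynamic_control_terms_monotone_in_rho(homog2):
    rho = np.array([0.5, 1.0, 2.0, 5.0, 8.0])
    cur = fluence_ss(homog2, rho, 0.0, ConvergenceControl(rel_tol=1e-12))
    assert np.all(np.diff(cur.terms_used) >= 0)
    assert cur.converged.all()


def test_larger_radius_needs_more_terms():
    ctrl = ConvergenceControl(rel_tol=1e-12)
    small = build_medium([0.1] * 2, [10.0] * 2, [1.0, 20.0], radius=10.0)
    large = build_medium([0.1] * 2, [10.0] * 2, [1.0, 20.0], radius=20.0)
    t_small = fluence_ss(small, 1.0, 0.0, ctrl).terms_used[0]
    t_large = fluence_ss(large, 1.0, 0.0, ctrl).terms_used[0]
    assert t_large >= t_small


def test_partial_sums_converged_at_3000_terms(homog2):
    half = fluence_ss(homog2, 1.0, 0.0, ConvergenceControl(n_terms=1500)).values[0]
    full = fluence_ss(homog2, 1.0, 0.0, ConvergenceControl(n_terms=3000)).values[0]
    assert abs(full - half) < 1e-12 * abs(full) + 1e-15


def test_transmittance_positive_decreasing(homog2):
    rho = np.array([0.5, 1.0, 2.0, 4.0])
    tr = transmittance_ss(homog2, rho, ConvergenceControl(rel_tol=1e-12)).values
    assert np.all(tr > 0)
    assert np.all(np.diff(tr) < 0)


def test_absorber_never_increases_transmittance():
    ctrl = ConvergenceControl(rel_tol=1e-12)
    base = build_medium([0.1, 0.1], [10.0, 10.0], [5.0, 5.0], radius=20.0)
    t0 = transmittance_ss(base, 1.0, ctrl).values[0]
    for k in range(2):
        mu = [0.1, 0.1]
        mu[k] = 0.3
        t1 = transmittance_ss(build_medium(mu, [10.0, 10.0], [5.0, 5.0],
                                           radius=20.0), 1.0, ctrl).values[0]
        assert t1 < t0


class TestApproxReflectance:
    def test_matches_exact_sum(self, homog2):
        rho = np.array([0.5, 1.0, 2.0])
        exact = fluence_ss(homog2, rho, 0.0,
                           ConvergenceControl(rel_tol=1e-14, n_max=20000)).values
        approx = approx_reflectance_ss(homog2, rho,
                                       ConvergenceControl(rel_tol=1e-14)).values
        assert np.max(np.abs(approx / exact - 1)) < 1e-11

    def test_term_count_advantage_high_scatter(self):
        m = build_medium([0.1] * 4, [80.0] * 4, [0.5, 1.5, 3.5, 30.0], radius=15.0)
        ctrl = ConvergenceControl(rel_tol=1e-12, n_max=50000)
        exact = fluence_ss(m, 1.0, 0.0, ctrl)
        fast = approx_reflectance_ss(m, 1.0, ctrl)
        assert exact.terms_used[0] >= 10 * fast.terms_used[0]
        assert abs(fast.values[0] / exact.values[0] - 1) < 1e-10

    def test_low_scatter_falls_back_with_warning(self):
        m = build_medium([0.05], [1.5], [5.0], radius=10.0)
        with pytest.warns(UserWarning, match="mu_sp_1 > 2"):
            cur = approx_reflectance_ss(m, 1.0)
        ref = reflectance_ss(m, 1.0)
        assert cur.values[0] == pytest.approx(ref.values[0], rel=1e-12)


def test_rho_zero_allowed_boundary_flagged(homog2):
    ctrl = ConvergenceControl(rel_tol=1e-10)
    cur = fluence_ss(homog2, 0.0, 0.0, ctrl)
    assert cur.values[0] > 0
    with pytest.warns(UserWarning, match="lateral boundary"):
        fluence_ss(homog2, homog2.radius_a, 0.0, ctrl)
    with pytest.raises(DomainError):
        fluence_ss(homog2, homog2.radius_a + 1.0, 0.0, ctrl)


def test_interior_depth_rejected_without_flag(homog2):
    with pytest.raises(DomainError):
        fluence_ss(homog2, 1.0, 3.0)
    cur = fluence_ss(homog2, 1.0, 0.05, allow_interior=True,
                     control=ConvergenceControl(rel_tol=1e-10))
    assert cur.values[0] > 0


def test_negative_noise_clamped_flagged(homog2):
    """Far-field values below the cancellation noise floor clamp to 0."""
    cur = fluence_ss(homog2, np.array([19.9]), 0.0,
                     ConvergenceControl(n_terms=60))
    assert np.all(cur.values >= 0)
    assert cur.clamped.dtype == bool
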