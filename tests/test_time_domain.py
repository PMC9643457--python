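import numpy as np
import pytest

from layerfluence import (ConvergenceControl, DomainError, SemiInfiniteModel,
                          build_contour, choose_N, fluence_ss, fluence_td,
                          invert_laplace, td_semiinf)


class TestContour:
    def test_rejects_bad_windows(self):
        with pytest.raises(DomainError):
            build_contour(24, 0.0, 1.0)
        with pytest.raises(DomainError):
            build_contour(24, 1.0, 0.5)
        with pytest.raises(DomainError):
            build_contour(1, 0.1, 1.0)

    def test_node_geometry(self):
        c = build_contour(24, 0.1, 5.0)
        assert c.Lambda == pytest.approx(50.0)
        assert len(c.nodes) == 24
        # upper half plane, left-opening: imaginary parts increase, the
        # extreme nodes head to Re -> -inf
        assert np.all(c.nodes.imag > 0)
        assert np.all(np.diff(c.nodes.imag) > 0)
        assert c.nodes.real[-1] < -10 * abs(c.nodes.real[0])

    def test_conjugate_reconstruction_is_real(self):
        """Folding the conjugate half as 2 Re reproduces a real signal."""
        c = build_contour(16, 0.5, 2.0)
        vals = invert_laplace(lambda s: 1.0 / (s + 1.0), c, [1.0])
        assert np.isrealobj(vals)
        assert vals[0] == pytest.approx(np.exp(-1.0), rel=1e-9)

    def test_unit_step_oracle(self):
        c = build_contour(24, 1.0 / np.sqrt(10), np.sqrt(10))
        err = abs(invert_laplace(lambda s: 1.0 / s, c, [1.0])[0] - 1.0)
        assert err < 1e-10

    def test_shifted_ramp_oracle(self):
        a = 2.0
        c = build_contour(24, 1.0 / np.sqrt(10), np.sqrt(10))
        ts = np.geomspace(c.t1 * 1.02, c.t2 * 0.98, 15)
        got = invert_laplace(lambda s: 1.0 / (s + a) ** 2, c, ts)
        assert np.max(np.abs(got / (ts * np.exp(-a * ts)) - 1.0)) < 1e-8


@pytest.fixture(scope="module")
def si_ref(four_layer):
    return SemiInfiniteModel.from_medium(four_layer)


def test_matches_semiinfinite_at_1ns(four_layer, si_ref, tight_control):
    ref = float(td_semiinf(si_ref, 1.0, 1.0))
    cur = fluence_td(four_layer, 1.0, 0.0, [1.0], N_evals=20,
                     control=tight_control, t_window=(0.1, 5.0))
    assert abs(float(cur.values[0, 0]) - ref) < 1e-10


def test_causality_before_first_arrival(four_layer, tight_control):
    cur = fluence_td(four_layer, 3.0, 0.0, [0.01], N_evals=24,
                     control=tight_control, t_window=(0.01, 1.0))
    assert abs(float(cur.values[0, 0])) < 1e-9


def test_time_integral_equals_steady_state(four_layer):
    """Total-energy identity: integral of Phi(t) dt == steady-state Phi.

    Two contour segments keep the early-time (rising-edge) part of the
    signal inside a narrow, accurately served window."""
    ctrl = ConvergenceControl(rel_tol=1e-13, n_max=4000)
    integral = 0.0
    for t_lo, t_hi, n in ((0.002, 1.0, 1200), (1.0, 18.0, 1500)):
        ts = np.linspace(t_lo, t_hi, n)
        cur = fluence_td(four_layer, 1.0, 0.0, ts, N_evals=48, control=ctrl,
                         t_window=(t_lo, t_hi))
        integral += np.trapezoid(cur.values[0], ts)
    ss = fluence_ss(four_layer, 1.0, 0.0, ctrl).values[0]
    assert integral == pytest.approx(ss, rel=1e-3)


def test_error_monotone_in_N(four_layer, si_ref, tight_control):
    """More Laplace evaluations never hurt (down to the precision floor)."""
    ref = float(td_semiinf(si_ref, 1.0, 1.0))
    errs = []
    for N in (8, 16, 24, 32):
        cur = fluence_td(four_layer, 1.0, 0.0, [1.0], N_evals=N,
                         control=tight_control, t_window=(0.1, 5.0))
        errs.append(abs(float(cur.values[0, 0]) - ref))
    floor = 5e-14
    for lo, hi in zip(errs[1:], errs[:-1]):
        assert lo <= hi * 3 + floor


def test_wider_window_equal_or_worse(four_layer, si_ref, tight_control):
    ref = float(td_semiinf(si_ref, 1.0, 1.0))
    errs = []
    for t1 in (1.0, 0.1, 0.01, 0.001):
        cur = fluence_td(four_layer, 1.0, 0.0, [1.0], N_evals=14,
                         control=tight_control, t_window=(t1, 5.0))
        errs.append(abs(float(cur.values[0, 0]) - ref))
    assert errs[-1] >= errs[0] / 3


def test_error_roughly_uniform_over_window(four_layer, si_ref, tight_control):
    """Absolute error is flat (< 3 decades spread) across the served interior
    of a Lambda = 5 window; the outermost few percent of the window, where
    quadrature accuracy rolls off, is excluded, and the precision floor caps
    the spread from below."""
    ts = np.linspace(1.2, 4.8, 10)
    cur = fluence_td(four_layer, 1.0, 0.0, ts, N_evals=16,
                     control=tight_control, t_window=(1.0, 5.0))
    refs = td_semiinf(si_ref, 1.0, ts)
    errs = np.maximum(np.abs(cur.values[0] - refs), 5e-14)
    assert errs.max() / errs.min() < 1e3


def test_deterministic_reconstruction(four_layer, tight_control):
    ts = np.linspace(0.5, 2.0, 5)
    a = fluence_td(four_layer, 1.0, 0.0, ts, N_evals=16, control=tight_control)
    b = fluence_td(four_layer, 1.0, 0.0, ts, N_evals=16, control=tight_control)
    assert np.array_equal(a.values, b.values)


def test_refuses_times_outside_window(four_layer, tight_control):
    c = build_contour(16, 0.5, 2.0)
    with pytest.raises(DomainError):
        fluence_td(four_layer, 1.0, 0.0, [3.0], contour=c, control=tight_control)
    with pytest.raises(DomainError):
        fluence_td(four_layer, 1.0, 0.0, [-1.0], control=tight_control)


def test_negative_noise_clamped(four_layer, tight_control):
    cur = fluence_td(four_layer, 1.0, 0.0, [0.02, 1.0], N_evals=8,
                     control=tight_control, t_window=(0.02, 5.0))
    assert np.all(cur.values >= 0)


@pytest.mark.parametrize("decades, expected", [(3, 12), (6, 24), (50, 200)])
def test_choose_N_anchors(decades, expected):
    got = choose_N(decades)
    assert got == expected
    assert got % 2 == 0


def test_choose_N_extreme_dynamic_range():
    assert choose_N(50) >= 168


def test_choose_N_rejects_nonpositive():
    with pytest.raises(DomainError):
        choose_N(0)
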