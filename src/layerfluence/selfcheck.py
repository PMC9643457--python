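"""Quick self-validation suites behind ``layerfluence validate``.

Each suite re-runs one of the package's oracle comparisons at reduced size
and reports pass/fail; the pytest suite performs the full versions.
"""

from __future__ import annotations

import numpy as np

from .media import build_medium
from .semiinfinite import SemiInfiniteModel, ss_semiinf, td_semiinf
from .steady_state import ConvergenceControl, fluence_ss
from .time_domain import build_contour, fluence_td, invert_laplace

__all__ = ["run_suite"]


def _laplace():
    """Contour inversion vs the 4-layer/semi-infinite comparison at t = 1 ns."""
    m = build_medium([0.1] * 4, [10.0] * 4, [0.5, 1.5, 3.0, 5.0], radius=15.0)
    ref = float(td_semiinf(SemiInfiniteModel.from_medium(m), 1.0, 1.0))
    lines = []
    ok = True
    for t1 in (1.0, 0.01):
        cur = fluence_td(m, 1.0, 0.0, [1.0], N_evals=20,
                         control=ConvergenceControl(rel_tol=1e-14, n_max=4000),
                         t_window=(t1, 5.0))
        err = abs(float(cur.values[0, 0]) - ref)
        good = err < 1e-8
        ok &= good
        lines.append(f"  Lambda={5.0 / t1:g}: |error| = {err:.3e} "
                     f"[{'ok' if good else 'FAIL'}]")
    c = build_contour(24, 1.0 / np.sqrt(10), np.sqrt(10))
    step = abs(invert_laplace(lambda s: 1.0 / s, c, [1.0])[0] - 1.0)
    good = step < 1e-9
    ok &= good
    lines.append(f"  unit step at t=1: |error| = {step:.3e} "
                 f"[{'ok' if good else 'FAIL'}]")
    return ok, "\n".join(lines)


def _slab():
    """Layered solver vs the equal-property slab/semi-infinite closed form."""
    m = build_medium([0.1] * 2, [10.0] * 2, [5.0, 5.0], radius=20.0)
    si = SemiInfiniteModel.from_medium(m)
    rhos = np.array([1.0])
    got = fluence_ss(m, rhos, 0.0, ConvergenceControl(n_terms=1500)).values
    want = ss_semiinf(si, rhos)
    err = float(np.max(np.abs(got - want)))
    ok = err < 1e-12
    return ok, f"  max |layered - semi-infinite| = {err:.3e} [{'ok' if ok else 'FAIL'}]"


def _semiinf():
    """Self-consistency of the closed forms (td integrates to ss)."""
    model = SemiInfiniteModel(0.1, 10.0, 1.4)
    ts = np.linspace(1e-4, 50.0, 60000)
    integral = float(np.trapezoid(td_semiinf(model, 1.0, ts), ts))
    target = float(ss_semiinf(model, 1.0))
    rel = abs(integral / target - 1.0)
    ok = rel < 1e-3
    return ok, f"  integral(td)/ss - 1 = {rel:.3e} [{'ok' if ok else 'FAIL'}]"


_SUITES = {"laplace": _laplace, "slab": _slab, "semiinf": _semiinf}


def run_suite(name: str):
    ok, body = _SUITES[name]()
    head = f"suite {name}: {'PASS' if ok else 'FAIL'}"
    return ok, head + "\n" + body
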