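"""Steady-state fluence by finite inverse Hankel transform over J0 roots.

The fluence at radial distance rho on the top (reflectance) or bottom
(transmittance) face of the layered cylinder is

    Phi_k(rho) = (1 / (pi a'^2)) sum_n G_k(s_n, z) J0(s_n rho) / J1(a' s_n)^2,

with ``s_n = s~_n / a'`` the scaled J0 roots.  The sum is truncated either at
a fixed term count or dynamically: it stops once the magnitudes of a run of
consecutive terms (default 10) each fall below ``rel_tol`` times the
magnitude of the accumulated sum — single-term tests are unsafe because the
J0 factor oscillates through zero.

``approx_reflectance_ss`` accelerates the z = 0 (reflectance) case, where the
source term ``exp(-alpha z0)/(2 D_1 alpha_1)`` of G_1 makes the sum converge
on the slow ``exp(-s z0)`` scale: the source term and its top-boundary image
are summed exactly in real space as infinite-medium dipole terms

    [exp(-mu_eff r1)/r1 - exp(-mu_eff r2)/r2] / (4 pi D_1),
    r1 = sqrt(rho^2 + z0^2),  r2 = sqrt(rho^2 + (z0 + 2 z_b)^2),

and only the layered remainder of G_1 — which decays on the far faster
``exp(-2 alpha l_1)`` scale — is left under the Hankel sum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import mpmath
import numpy as np

from .bessel import compute_roots
from .errors import DomainError
from .greens import _sweep, _top_coeffs
from .media import LayeredCylinder
from .precision import DOUBLE, Context, get_context

__all__ = [
    "ConvergenceControl", "FluenceCurve",
    "fluence_ss", "reflectance_ss", "transmittance_ss", "approx_reflectance_ss",
]

_CHUNK = 256


@dataclass(frozen=True)
class ConvergenceControl:
    """Truncation policy for the Hankel sum.

    Either ``n_terms`` fixes the number of roots, or the dynamic rule stops
    after ``run_length`` consecutive terms below ``rel_tol * |sum|``
    (bounded by ``n_min``/``n_max``).
    """

    n_terms: int | None = None
    rel_tol: float = 1e-12
    n_min: int = 50
    n_max: int = 50_000
    run_length: int = 10

    def cap(self) -> int:
        return int(self.n_terms) if self.n_terms is not None else int(self.n_max)


@dataclass(frozen=True)
class FluenceCurve:
    """Query points, fluence values and per-query convergence metadata."""

    rho: np.ndarray               # [cm]
    z: float                      # [cm]
    values: np.ndarray            # fluence [cm^-2]; extended precision: object array
    terms_used: np.ndarray
    converged: np.ndarray
    clamped: np.ndarray           # negative-noise values clamped to exactly 0
    control: ConvergenceControl = field(default_factory=ConvergenceControl)
    meta: dict = field(default_factory=dict)


class _KernelCache:
    """Chunked, lazily-grown evaluations of G(s_n) * weight_n, shared across rho."""

    def __init__(self, medium, z, s_bar, surface, ctx, table, kernel):
        self.medium, self.z, self.s_bar = medium, z, s_bar
        self.surface, self.ctx, self.table, self.kernel = surface, ctx, table, kernel
        self.chunks: list = []          # per chunk: (s_values, G*weight)

    def chunk(self, i: int):
        while len(self.chunks) <= i:
            j = len(self.chunks)
            lo, hi = j * _CHUNK, min((j + 1) * _CHUNK, self.table.n_max)
            if lo >= hi:
                return None
            ap = self.medium.boundary.a_prime
            if not self.ctx.is_mp:
                roots = self.table.roots[lo:hi]
                s = roots / ap
                g = self.kernel(self.medium, s, self.z, self.s_bar, self.ctx)
                self.chunks.append((s, g * self.table.weights[lo:hi]))
            else:
                s_list, gw = [], []
                for n in range(lo, hi):
                    s = self.table.roots[n] / ap
                    g = self.kernel(self.medium, s, self.z, self.s_bar, self.ctx)
                    s_list.append(s)
                    gw.append(g * self.table.weights[n])
                self.chunks.append((s_list, gw))
        return self.chunks[i] if i < len(self.chunks) else None


def _kernel_exact_top(medium, s, z, s_bar, ctx):
    from .greens import greens_top
    return greens_top(medium, s, z, s_bar, ctx).value


def _kernel_exact_bottom(medium, s, z, s_bar, ctx):
    from .greens import greens_bottom
    return greens_bottom(medium, s, z, s_bar, ctx).value


def _kernel_residual_top(medium, s, z, s_bar, ctx):
    """G_1(0) minus its source and top-image terms, computed in closed form
    (no cancellation): the part that remains after the dipole terms are summed
    exactly in real space."""
    alpha, beta, E, rho = _sweep(medium, s, s_bar, ctx)
    A, b, E1h, P_z1, P_mh, denom = _top_coeffs(medium, alpha, beta, E, rho, ctx)
    bnd = medium.boundary
    a1 = alpha[0]
    l1 = medium.thicknesses[0]
    eh = ctx.exp(-a1 * bnd.z_b_top)
    # A*exp(-a1*h) + image  ==  e^{-a1 h} rho_1 E1h (P_mh E1h - P_z1) / denom
    top_part = eh * rho[0] * E1h * (P_mh * E1h - P_z1) / denom
    return top_part + b * ctx.exp(-a1 * l1)


def _sum_one_rho(cache: _KernelCache, rho, control: ConvergenceControl):
    """Dynamic/fixed Hankel summation for a single rho; returns
    (raw complex/real sum excluding prefactor, terms_used, converged)."""
    ctx = cache.ctx
    cap = min(control.cap(), cache.table.n_max)
    need = control.run_length
    n_min = min(control.n_min, cap)
    fixed = control.n_terms is not None

    total = 0.0 if not ctx.is_mp else mpmath.mpc(0)
    run = 0
    used = 0
    converged = False
    i = 0
    while used < cap:
        ch = cache.chunk(i)
        if ch is None:
            break
        s_vals, gw = ch
        if not ctx.is_mp:
            from scipy.special import j0 as _j0
            terms = gw * _j0(s_vals * rho)
            take = min(len(terms), cap - used)
            for t in range(take):
                total = total + terms[t]
                used += 1
                mag = abs(terms[t])
                run = run + 1 if mag <= control.rel_tol * abs(total) else 0
                if not fixed and used >= n_min and run >= need:
                    converged = True
                    break
        else:
            take = min(len(gw), cap - used)
            for t in range(take):
                term = gw[t] * ctx.j0(s_vals[t] * rho)
                total = total + term
                used += 1
                mag = abs(term)
                run = run + 1 if mag <= control.rel_tol * abs(total) else 0
                if not fixed and used >= n_min and run >= need:
                    converged = True
                    break
        if converged:
            break
        i += 1
    if fixed:
        converged = run >= need
    return total, used, converged


def _hankel_fluence(medium, rho, z, s_bar, control, ctx, surface, kernel):
    ctx = get_context(ctx)
    control = control or ConvergenceControl()
    table = compute_roots(min(control.cap(), control.n_max), ctx)
    cache = _KernelCache(medium, z, s_bar, surface, ctx, table, kernel)
    rhos = np.atleast_1d(np.asarray(rho, dtype=float))
    ap = medium.boundary.a_prime
    if np.any(rhos < 0) or np.any(rhos > medium.radius_a + 1e-12):
        raise DomainError("rho must lie in [0, radius_a]")
    if np.any(rhos == medium.radius_a):
        warnings.warn("rho at the lateral boundary: accuracy degrades near rho = a")
    out, used, conv = [], [], []
    with ctx.workprec():
        pref = 1.0 / (ctx.pi * ap * ap) if not ctx.is_mp else 1 / (ctx.pi * mpmath.mpf(ap) ** 2)
        for r in rhos:
            tot, n_used, ok = _sum_one_rho(cache, r if not ctx.is_mp else mpmath.mpf(r), control)
            out.append(pref * tot)
            used.append(n_used)
            conv.append(ok)
    return out, np.array(used), np.array(conv), rhos


def _realize(values, ctx, clamp_negative=True):
    """Drop the zero imaginary part of a steady-state sum, clamping the
    cancellation noise floor at 0 (flagged)."""
    clamped = np.zeros(len(values), dtype=bool)
    if ctx.is_mp:
        re = [v.real if isinstance(v, mpmath.mpc) else v for v in values]
        if clamp_negative:
            clamped = np.array([v < 0 for v in re])
            re = [v if v >= 0 else mpmath.mpf(0) for v in re]
        return np.array(re, dtype=object), clamped
    re = np.real(np.asarray(values))
    if clamp_negative:
        clamped = re < 0
        re = np.where(clamped, 0.0, re)
    return re, clamped


def fluence_ss(medium: LayeredCylinder, rho, z=0.0,
               control: ConvergenceControl | None = None,
               s_bar=0.0, ctx: Context = DOUBLE,
               allow_interior: bool = False) -> FluenceCurve:
    """Steady-state fluence [cm^-2] at the top (z=0) or bottom (z=L) face.

    Depths strictly inside the medium are rejected unless ``allow_interior``
    is set, in which case ``z`` may lie anywhere within the top or bottom
    layer (used for registering against Monte Carlo depth bins).
    """
    ctx = get_context(ctx)
    L = medium.total_thickness_L
    z = float(z)
    top_l = medium.thicknesses[0]
    bot_top = L - medium.thicknesses[-1]
    if z == 0.0 or (allow_interior and 0.0 <= z <= top_l):
        kernel, surface = _kernel_exact_top, "top"
    elif z == L or (allow_interior and bot_top <= z <= L):
        kernel, surface = _kernel_exact_bottom, "bottom"
    else:
        raise DomainError(
            f"z={z} is not a surface query (z=0 or z=L={L}); interior depths "
            "require allow_interior=True and must lie in the top or bottom layer")
    control = control or ConvergenceControl()
    vals, used, conv, rhos = _hankel_fluence(medium, rho, z, s_bar, control,
                                             ctx, surface, kernel)
    if s_bar == 0:
        values, clamped = _realize(vals, ctx)
    else:
        values = np.asarray(vals, dtype=object if ctx.is_mp else complex)
        clamped = np.zeros(len(vals), dtype=bool)
    return FluenceCurve(rhos, z, values, used, conv, clamped, control,
                        meta={"s_bar": s_bar, "precision": ctx.name})


def reflectance_ss(medium, rho, control=None, ctx: Context = DOUBLE) -> FluenceCurve:
    """Phi_1 at z = 0 (diffuse reflectance proxy)."""
    return fluence_ss(medium, rho, 0.0, control, 0.0, ctx)


def transmittance_ss(medium, rho, control=None, ctx: Context = DOUBLE) -> FluenceCurve:
    """Phi_N at z = L (diffuse transmittance proxy)."""
    return fluence_ss(medium, rho, medium.total_thickness_L, control, 0.0, ctx)


def approx_reflectance_ss(medium, rho, control=None, ctx: Context = DOUBLE) -> FluenceCurve:
    """Fast z=0 reflectance: dipole source terms summed exactly in real space
    plus a rapidly-converging residual Hankel sum (valid for mu_sp_1 > 2 cm^-1)."""
    ctx = get_context(ctx)
    top = medium.layers[0]
    if top.mu_sp <= 2.0:
        warnings.warn("approx_reflectance_ss is accurate for mu_sp_1 > 2 cm^-1; "
                      "falling back to the exact sum")
        return reflectance_ss(medium, rho, control, ctx)
    control = control or ConvergenceControl()
    vals, used, conv, rhos = _hankel_fluence(medium, rho, 0.0, 0.0, control,
                                             ctx, "top", _kernel_residual_top)
    bnd = medium.boundary
    D1 = top.D
    with ctx.workprec():
        if not ctx.is_mp:
            mu_eff = np.sqrt(top.mu_a / D1)
            r1 = np.sqrt(rhos**2 + bnd.z0**2)
            r2 = np.sqrt(rhos**2 + (bnd.z0 + 2.0 * bnd.z_b_top) ** 2)
            dipole = (np.exp(-mu_eff * r1) / r1 - np.exp(-mu_eff * r2) / r2) \
                / (4.0 * np.pi * D1)
            values = dipole + np.real(np.asarray(vals))
        else:
            mu_eff = mpmath.sqrt(mpmath.mpf(top.mu_a) / D1)
            values = []
            for r, v in zip(rhos, vals):
                r1 = mpmath.sqrt(mpmath.mpf(r) ** 2 + mpmath.mpf(bnd.z0) ** 2)
                r2 = mpmath.sqrt(mpmath.mpf(r) ** 2
                                 + (mpmath.mpf(bnd.z0) + 2 * bnd.z_b_top) ** 2)
                dip = (mpmath.exp(-mu_eff * r1) / r1
                       - mpmath.exp(-mu_eff * r2) / r2) / (4 * ctx.pi * D1)
                vv = v.real if isinstance(v, mpmath.mpc) else v
                values.append(dip + vv)
            values = np.array(values, dtype=object)
    values, clamped = _realize(values, ctx)
    return FluenceCurve(rhos, 0.0, values, used, conv, clamped, control,
                        meta={"approx": "source+image dipole split",
                              "precision": ctx.name})
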