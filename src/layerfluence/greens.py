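"""Spatial-frequency-domain Green's function of the N-layered cylinder.

For one transverse frequency ``s`` (a J0 root divided by the extrapolated
radius ``a'``) and a complex absorption shift ``s_bar`` (the Laplace
variable; 0 for steady state), the axial profile ``G_k(s, z, s_bar)`` solves
the two-point boundary-value problem

    G'' - alpha_k^2 G = -delta(z - z0) / D_1   in layer k,
    alpha_k = sqrt((mu_a_k + s_bar/c)/D_k + s^2),

with extrapolated boundaries ``G = 0`` at ``z = -z_b_top`` and
``z = L + z_b_bottom`` and continuity of ``G`` and ``D_k dG/dz`` at every
interface.

The assembly is an impedance (reflection-coefficient) sweep from the bottom
boundary upward.  Within layer k the solution is written as

    G_k(z) = A_k exp(-alpha_k (z - z_{k-1})) + b_k exp(-alpha_k (z_k - z)),

so every stored exponential has a non-positive real exponent: the recursion
is overflow-free for arbitrarily thick or scattering layers, and exponentials
that underflow simply evaluate to 0.  The per-interface reflection recursion

    rho_k = (dB + sB * x) / (sB + dB * x),   x = rho_{k+1} E_{k+1}^2,
    dB = beta_k - beta_{k+1},  sB = beta_k + beta_{k+1},  beta = D alpha,

terminates at the bottom boundary with ``rho_N = -exp(-2 alpha_N z_b_bot)``.

All routines accept numpy arrays of frequencies (double precision) or mpmath
scalars (quad/octuple precision) through the shared Context interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError
from .media import LayeredCylinder
from .precision import DOUBLE, Context, get_context

__all__ = [
    "LayerWavenumbers", "GreensEval", "layer_wavenumbers",
    "greens_top", "greens_bottom", "slab_greens",
]


@dataclass(frozen=True)
class LayerWavenumbers:
    """Per-layer axial attenuation alpha_k [cm^-1] (complex-capable)."""

    alpha: tuple
    c: float  # speed of light in the medium [cm/ns]


@dataclass(frozen=True)
class GreensEval:
    """Green's function value(s) at (s, z, s_bar) in one layer."""

    value: object
    layer_index: int


def _principal_sqrt(ctx: Context, x):
    w = ctx.sqrt(x)
    if ctx.is_mp:
        return -w if w.real < 0 else w
    w = np.asarray(w)
    flip = w.real < 0
    if np.any(flip):
        w = np.where(flip, -w, w)
    return w


def layer_wavenumbers(medium: LayeredCylinder, s, s_bar=0.0,
                      ctx: Context = DOUBLE) -> LayerWavenumbers:
    """alpha_k = sqrt((mu_a_k + s_bar/c)/D_k + s^2), principal branch, Re > 0."""
    ctx = get_context(ctx)
    c = medium.c_medium
    alphas = []
    for layer in medium.layers:
        arg = (layer.mu_a + s_bar / c) / layer.D + s * s
        alphas.append(_principal_sqrt(ctx, arg))
    return LayerWavenumbers(tuple(alphas), c)


def _sweep(medium: LayeredCylinder, s, s_bar, ctx: Context):
    """Shared geometry/recursion: returns (alpha, beta, E, rho) per layer."""
    wn = layer_wavenumbers(medium, s, s_bar, ctx)
    alpha = wn.alpha
    D = medium.D
    ells = medium.thicknesses
    beta = [D[k] * alpha[k] for k in range(medium.n_layers)]
    E = [ctx.exp(-alpha[k] * ells[k]) for k in range(medium.n_layers)]
    K = medium.n_layers
    rho = [None] * K
    rho[K - 1] = -ctx.exp(-2.0 * alpha[K - 1] * medium.boundary.z_b_bottom)
    for k in range(K - 2, -1, -1):
        x = rho[k + 1] * E[k + 1] * E[k + 1]
        dB = beta[k] - beta[k + 1]
        sB = beta[k] + beta[k + 1]
        rho[k] = (dB + sB * x) / (sB + dB * x)
    return alpha, beta, E, rho


def _top_coeffs(medium, alpha, beta, E, rho, ctx):
    """Homogeneous amplitudes (A, b) of layer 1 and the source terms.

    Geometry sums (z0 + z_b etc.) are performed in the arithmetic context:
    pre-rounding them to double would put an eps_double-relative floor under
    extended-precision exponents."""
    bnd = medium.boundary
    z0, h = ctx.real(bnd.z0), ctx.real(bnd.z_b_top)
    l1 = ctx.real(float(medium.thicknesses[0]))
    a1, b1 = alpha[0], beta[0]
    E1h = ctx.exp(-a1 * (l1 + h))
    P_z1 = ctx.exp(-a1 * (l1 - z0)) / (2.0 * b1)   # particular sol. at z_1
    P_mh = ctx.exp(-a1 * (z0 + h)) / (2.0 * b1)    # particular sol. at -z_b
    denom = 1.0 + rho[0] * E1h * E1h
    A = -(P_mh + rho[0] * E1h * P_z1) / denom
    b = rho[0] * (P_z1 + A * E1h)
    return A, b, E1h, P_z1, P_mh, denom


def greens_top(medium: LayeredCylinder, s, z, s_bar=0.0,
               ctx: Context = DOUBLE) -> GreensEval:
    """G_1 at depth ``z`` in the top layer (analytic continuation down to
    ``z = -z_b_top`` is admitted so the boundary condition itself is testable)."""
    ctx = get_context(ctx)
    bnd = medium.boundary
    l1 = medium.thicknesses[0]
    if not (-bnd.z_b_top - 1e-12 <= z <= l1 + 1e-12):
        raise DomainError(f"z={z} outside layer 1 [{-bnd.z_b_top}, {l1}]")
    alpha, beta, E, rho = _sweep(medium, s, s_bar, ctx)
    A, b, _, _, _, _ = _top_coeffs(medium, alpha, beta, E, rho, ctx)
    a1, b1 = alpha[0], beta[0]
    zc = ctx.real(float(z))
    z0 = ctx.real(bnd.z0)
    val = (ctx.exp(-a1 * abs(zc - z0)) / (2.0 * b1)
           + A * ctx.exp(-a1 * (zc + ctx.real(bnd.z_b_top)))
           + b * ctx.exp(-a1 * (ctx.real(float(l1)) - zc)))
    return GreensEval(val, 0)


def greens_bottom(medium: LayeredCylinder, s, z, s_bar=0.0,
                  ctx: Context = DOUBLE) -> GreensEval:
    """G_N at depth ``z`` in the bottom layer (continuation up to L + z_b_bot)."""
    ctx = get_context(ctx)
    K = medium.n_layers
    if K == 1:
        return greens_top(medium, s, z, s_bar, ctx)
    depths = medium.interface_depths
    z_top_N = depths[-2]
    if not (z_top_N - 1e-12 <= z <= depths[-1] + medium.boundary.z_b_bottom + 1e-12):
        raise DomainError(f"z={z} outside layer {K} [{z_top_N}, {depths[-1]}]")
    alpha, beta, E, rho = _sweep(medium, s, s_bar, ctx)
    A, b, E1h, P_z1, _, _ = _top_coeffs(medium, alpha, beta, E, rho, ctx)
    # G at the bottom of layer 1
    G_if = P_z1 + A * E1h + b
    # propagate the interface value down through interior layers
    for k in range(1, K - 1):
        A_k = G_if / (1.0 + rho[k] * E[k] * E[k])
        G_if = A_k * E[k] * (1.0 + rho[k])
    A_N = G_if / (1.0 + rho[K - 1] * E[K - 1] * E[K - 1])
    aN = alpha[K - 1]
    zc = ctx.real(float(z))
    val = A_N * (ctx.exp(-aN * (zc - ctx.real(float(z_top_N))))
                 + rho[K - 1] * E[K - 1] * ctx.exp(-aN * (ctx.real(float(depths[-1])) - zc)))
    return GreensEval(val, K - 1)


def slab_greens(mu_a: float, mu_sp: float, L: float, z_b: float, z0: float,
                s, z, s_bar=0.0, c: float | None = None, ctx: Context = DOUBLE):
    """Closed-form single-slab Green's function (validation oracle).

    G(s, z) = sinh(alpha (z0 + z_b)) sinh(alpha (L + z_b - z))
              / (D alpha sinh(alpha (L + 2 z_b)))        for z >= z0,

    and with z and z0 exchanged for z < z0.  Evaluated in hyperbolic form on
    purpose (the thing the exponential sweep is checked against); overflows
    at large alpha*L, which the tests confine to the non-underflow regime.
    """
    ctx = get_context(ctx)
    D = 1.0 / (3.0 * mu_sp)
    shift = 0.0 if s_bar == 0 else s_bar / c
    alpha = _principal_sqrt(ctx, (mu_a + shift) / D + s * s)
    lo, hi = (z0, z) if z >= z0 else (z, z0)

    def sh(x):
        return (ctx.exp(x) - ctx.exp(-x)) / 2.0

    return (sh(alpha * (lo + z_b)) * sh(alpha * (L + z_b - hi))
            / (D * alpha * sh(alpha * (L + 2.0 * z_b))))
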