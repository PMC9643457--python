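"""Closed-form semi-infinite extrapolated-boundary solutions (validation oracles).

Dipole construction: an isotropic source at depth ``z0 = 1/mu_sp`` plus a
negative image mirrored about the extrapolated plane ``z = -z_b``.  At the
surface (z = 0):

    steady state:  Phi(rho) = [exp(-mu_eff r1)/r1 - exp(-mu_eff r2)/r2] / (4 pi D)
    time domain:   Phi(rho, t) = c (4 pi D c t)^{-3/2} exp(-mu_a c t)
                                 [exp(-r1^2/(4 D c t)) - exp(-r2^2/(4 D c t))]

with ``r1 = sqrt(rho^2 + z0^2)``, ``r2 = sqrt(rho^2 + (z0 + 2 z_b)^2)``,
``mu_eff = sqrt(mu_a / D)``, ``c = c0 / n_r``.  The same Fresnel-integral
``A`` as the layered solver is reused so both share identical boundary
parameters (required for the 1e-12-level agreement tests).

Fluence (not surface flux) is the compared quantity throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import mpmath
import numpy as np

from .errors import DomainError
from .media import C0_CM_PER_NS, a_coefficient
from .precision import DOUBLE, Context, get_context

__all__ = ["SemiInfiniteModel", "ss_semiinf", "td_semiinf"]


@dataclass(frozen=True)
class SemiInfiniteModel:
    """Homogeneous semi-infinite medium with extrapolated-boundary parameters."""

    mu_a: float               # [cm^-1]
    mu_sp: float              # [cm^-1]
    n_rel: float = 1.4        # internal/external refractive-index ratio
    A_override: float | None = None
    D: float = field(init=False)
    z0: float = field(init=False)
    z_b: float = field(init=False)
    mu_eff: float = field(init=False)

    def __post_init__(self):
        if not (self.mu_sp > 0 and self.mu_a >= 0):
            raise DomainError("need mu_sp > 0 and mu_a >= 0")
        D = 1.0 / (3.0 * self.mu_sp)
        A = self.A_override if self.A_override is not None else a_coefficient(self.n_rel)
        object.__setattr__(self, "D", D)
        object.__setattr__(self, "z0", 1.0 / self.mu_sp)
        object.__setattr__(self, "z_b", 2.0 * A * D)
        object.__setattr__(self, "mu_eff", float(np.sqrt(self.mu_a / D)))

    @property
    def c(self) -> float:
        """Speed of light in the medium [cm/ns]."""
        return C0_CM_PER_NS / self.n_rel

    @classmethod
    def from_medium(cls, medium) -> "SemiInfiniteModel":
        """Semi-infinite equivalent of (the top layer of) a layered medium."""
        top = medium.layers[0]
        return cls(top.mu_a, top.mu_sp, top.n_r / medium.n_out,
                   A_override=medium.boundary.A_coeff)


def _radii(model, rho, ctx):
    if ctx.is_mp:
        rho = mpmath.mpf(rho)
        r1 = mpmath.sqrt(rho**2 + mpmath.mpf(model.z0) ** 2)
        r2 = mpmath.sqrt(rho**2 + (mpmath.mpf(model.z0) + 2 * model.z_b) ** 2)
    else:
        rho = np.asarray(rho, dtype=float)
        r1 = np.sqrt(rho**2 + model.z0**2)
        r2 = np.sqrt(rho**2 + (model.z0 + 2.0 * model.z_b) ** 2)
    return r1, r2


def ss_semiinf(model: SemiInfiniteModel, rho, ctx: Context = DOUBLE):
    """Steady-state surface fluence [cm^-2] at radial distance rho [cm]."""
    ctx = get_context(ctx)
    with ctx.workprec():
        r1, r2 = _radii(model, rho, ctx)
        mu_eff = model.mu_eff if not ctx.is_mp else \
            mpmath.sqrt(mpmath.mpf(model.mu_a) / model.D)
        return (ctx.exp(-mu_eff * r1) / r1 - ctx.exp(-mu_eff * r2) / r2) \
            / (4.0 * ctx.pi * model.D)


def td_semiinf(model: SemiInfiniteModel, rho, t, ctx: Context = DOUBLE):
    """Time-resolved surface fluence [cm^-2 ns^-1] at rho [cm], t [ns] (t > 0)."""
    ctx = get_context(ctx)
    if np.any(np.asarray(t, dtype=float) <= 0):
        raise DomainError("td_semiinf requires t > 0")
    with ctx.workprec():
        r1, r2 = _radii(model, rho, ctx)
        c = model.c
        if ctx.is_mp:
            t = mpmath.mpf(t)
            four_Dct = 4 * mpmath.mpf(model.D) * c * t
            # mu_a * c must not be pre-rounded to double: its product sets an
            # exponential rate whose eps-double perturbation grows as eps * t
            pref = c * (ctx.pi * four_Dct) ** mpmath.mpf("-1.5") \
                * ctx.exp(-(mpmath.mpf(model.mu_a) * c) * t)
        else:
            t = np.asarray(t, dtype=float)
            four_Dct = 4.0 * model.D * c * t
            pref = c * (np.pi * four_Dct) ** -1.5 * np.exp(-model.mu_a * c * t)
        return pref * (ctx.exp(-(r1 * r1) / four_Dct) - ctx.exp(-(r2 * r2) / four_Dct))
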