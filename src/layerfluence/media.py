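"""Layered-cylinder medium description and derived boundary parameters.

The model geometry is a finite cylinder of radius ``a`` made of ``N``
homogeneous slabs stacked along ``z`` (layer 1 on top).  Each layer has an
absorption coefficient ``mu_a`` [cm^-1], a reduced scattering coefficient
``mu_sp`` [cm^-1], a refractive index and a thickness [cm].  A pencil beam
incident on the centre of the top face is represented by an isotropic point
source at depth ``z0 = 1/mu_sp_1`` on the axis.

Extrapolated boundary conditions put the zero-fluence plane a distance
``z_b = 2*A*D`` outside each external face, where ``A`` accounts for internal
Fresnel reflection at the refractive-index mismatch and ``D = 1/(3*mu_sp)``
is the diffusion coefficient.  The lateral boundary enters through the
extrapolated radius ``a' = a + z_b``.

Units are fixed package-wide: lengths cm, coefficients cm^-1, time ns.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate

from .errors import InvalidMediumError, UnsupportedGeometryError, UnsupportedMediumError

__all__ = [
    "C0_CM_PER_NS", "Layer", "LayeredCylinder", "BoundaryParams",
    "diffusion_coefficient", "a_coefficient", "build_medium",
]

#: vacuum speed of light [cm/ns]
C0_CM_PER_NS = 29.9792458


@dataclass(frozen=True)
class Layer:
    """One homogeneous slab: mu_a, mu_sp [cm^-1], refractive index, thickness [cm]."""

    mu_a: float
    mu_sp: float
    n_r: float
    thickness: float

    def __post_init__(self):
        if not (self.mu_a >= 0.0):
            raise InvalidMediumError(f"mu_a must be >= 0, got {self.mu_a}")
        if not (self.mu_sp > 0.0):
            raise InvalidMediumError(f"mu_sp must be > 0, got {self.mu_sp}")
        if not (self.n_r >= 1.0):
            raise InvalidMediumError(f"n_r must be >= 1, got {self.n_r}")
        if not (self.thickness > 0.0):
            raise InvalidMediumError(f"thickness must be > 0, got {self.thickness}")

    @property
    def D(self) -> float:
        return diffusion_coefficient(self)


def diffusion_coefficient(layer) -> float:
    """D = 1/(3*mu_sp) [cm]; the absorption-free convention used throughout."""
    mu_sp = layer.mu_sp if isinstance(layer, Layer) else float(layer)
    if not (mu_sp > 0.0):
        raise InvalidMediumError(f"mu_sp must be > 0, got {mu_sp}")
    return 1.0 / (3.0 * mu_sp)


def _fresnel_unpolarized(cos_i: np.ndarray, n_rel: float) -> np.ndarray:
    """Unpolarized Fresnel reflection coefficient for light inside a medium of
    relative index ``n_rel`` hitting the boundary at incidence cosine ``cos_i``.
    Total internal reflection beyond the critical angle."""
    cos_i = np.asarray(cos_i, dtype=float)
    sin_i = np.sqrt(np.clip(1.0 - cos_i**2, 0.0, 1.0))
    sin_t = n_rel * sin_i
    R = np.ones_like(cos_i)
    prop = sin_t < 1.0
    cos_t = np.sqrt(1.0 - sin_t[prop] ** 2)
    ci, ct = cos_i[prop], cos_t
    rs = (n_rel * ci - ct) / (n_rel * ci + ct)
    rp = (n_rel * ct - ci) / (n_rel * ct + ci)
    R[prop] = 0.5 * (rs**2 + rp**2)
    return R


@functools.lru_cache(maxsize=None)
def a_coefficient(n_rel: float) -> float:
    """Internal-reflection coefficient A for the extrapolated boundary.

    Computed from the first two angular moments of the unpolarized Fresnel
    reflection coefficient over the hemisphere (the standard extrapolated-
    boundary construction):

        R_phi = int_0^{pi/2} 2 sin(t) cos(t)   R_F(t) dt
        R_j   = int_0^{pi/2} 3 sin(t) cos(t)^2 R_F(t) dt
        R_eff = (R_phi + R_j) / (2 - R_phi + R_j)
        A     = (1 + R_eff) / (1 - R_eff)

    ``A = 1`` exactly for a matched boundary; ``A ~ 2.95`` at n_rel = 1.4.
    Results are cached per ``n_rel``.
    """
    n_rel = float(n_rel)
    if not (n_rel > 0.0):
        raise InvalidMediumError(f"n_rel must be > 0, got {n_rel}")
    if n_rel == 1.0:
        return 1.0

    def integrand_phi(theta):
        return 2.0 * np.sin(theta) * np.cos(theta) * _fresnel_unpolarized(np.cos(theta), n_rel)

    def integrand_j(theta):
        return 3.0 * np.sin(theta) * np.cos(theta) ** 2 * _fresnel_unpolarized(np.cos(theta), n_rel)

    # split at the critical angle where R_F has a kink (n_rel > 1 only)
    pts = [np.arcsin(1.0 / n_rel)] if n_rel > 1.0 else None
    kw = dict(limit=200, epsabs=1e-13, epsrel=1e-13)
    r_phi = integrate.quad(integrand_phi, 0.0, np.pi / 2, points=pts, **kw)[0]
    r_j = integrate.quad(integrand_j, 0.0, np.pi / 2, points=pts, **kw)[0]
    r_eff = (r_phi + r_j) / (2.0 - r_phi + r_j)
    return (1.0 + r_eff) / (1.0 - r_eff)


@dataclass(frozen=True)
class BoundaryParams:
    """Derived extrapolated-boundary quantities for a LayeredCylinder."""

    A_coeff: float        # internal-reflection coefficient [-]
    z_b_top: float        # extrapolation length above z=0 [cm]
    z_b_bottom: float     # extrapolation length below z=L [cm]
    a_prime: float        # extrapolated radius a + z_b_top [cm]
    z0: float             # isotropic source depth 1/mu_sp_1 [cm]


@dataclass(frozen=True)
class LayeredCylinder:
    """Full geometry + optics of the layered cylinder, with derived parameters."""

    layers: tuple[Layer, ...]
    radius_a: float
    n_out: float = 1.0
    _A_override: float | None = None
    total_thickness_L: float = field(init=False)
    interface_depths: tuple[float, ...] = field(init=False)
    boundary: BoundaryParams = field(init=False)

    def __post_init__(self):
        if len(self.layers) < 1:
            raise InvalidMediumError("need at least one layer")
        if not (self.radius_a > 0.0):
            raise InvalidMediumError(f"radius_a must be > 0, got {self.radius_a}")
        n_set = {layer.n_r for layer in self.layers}
        if len(n_set) > 1:
            raise UnsupportedMediumError(
                "all internal layers must share one refractive index; "
                f"got {sorted(n_set)} (interface continuity conditions assume "
                "matched internal indices)")
        depths = tuple(np.cumsum([layer.thickness for layer in self.layers]).tolist())
        object.__setattr__(self, "interface_depths", depths)
        object.__setattr__(self, "total_thickness_L", depths[-1])
        top, bottom = self.layers[0], self.layers[-1]
        z0 = 1.0 / top.mu_sp
        if not (z0 < top.thickness):
            raise UnsupportedGeometryError(
                f"source depth z0 = 1/mu_sp_1 = {z0:g} cm must lie strictly "
                f"inside layer 1 (thickness {top.thickness:g} cm)")
        A = self._A_override
        if A is None:
            A = a_coefficient(top.n_r / self.n_out)
        z_bt = 2.0 * A * top.D
        z_bb = 2.0 * A * bottom.D
        object.__setattr__(self, "boundary", BoundaryParams(
            A_coeff=A, z_b_top=z_bt, z_b_bottom=z_bb,
            a_prime=self.radius_a + z_bt, z0=z0))

    # convenience accessors used by the numerical kernels -------------
    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def mu_a(self) -> np.ndarray:
        return np.array([layer.mu_a for layer in self.layers])

    @property
    def mu_sp(self) -> np.ndarray:
        return np.array([layer.mu_sp for layer in self.layers])

    @property
    def D(self) -> np.ndarray:
        return np.array([layer.D for layer in self.layers])

    @property
    def thicknesses(self) -> np.ndarray:
        return np.array([layer.thickness for layer in self.layers])

    @property
    def n_r(self) -> float:
        return self.layers[0].n_r

    @property
    def c_medium(self) -> float:
        """Speed of light in the medium [cm/ns]."""
        return C0_CM_PER_NS / self.n_r


def build_medium(mu_a, mu_sp, thickness, n_r: float = 1.4, radius: float = 10.0,
                 n_out: float = 1.0, A_override: float | None = None) -> LayeredCylinder:
    """Assemble a :class:`LayeredCylinder` from per-layer coefficient lists.

    Parameters
    ----------
    mu_a, mu_sp, thickness : sequence of float
        Per-layer absorption / reduced scattering [cm^-1] and thickness [cm],
        top layer first.
    n_r : float
        Internal refractive index shared by every layer.
    radius : float
        Cylinder radius ``a`` [cm].
    n_out : float
        External refractive index (air = 1.0).
    A_override : float, optional
        Pin the internal-reflection coefficient ``A`` to a literature value
        instead of the Fresnel-integral computation.
    """
    mu_a = np.atleast_1d(np.asarray(mu_a, dtype=float))
    mu_sp = np.atleast_1d(np.asarray(mu_sp, dtype=float))
    thickness = np.atleast_1d(np.asarray(thickness, dtype=float))
    if not (len(mu_a) == len(mu_sp) == len(thickness)):
        raise InvalidMediumError(
            f"per-layer lists must have equal length, got "
            f"{len(mu_a)}/{len(mu_sp)}/{len(thickness)}")
    layers = tuple(Layer(a, s, float(n_r), t) for a, s, t in zip(mu_a, mu_sp, thickness))
    return LayeredCylinder(layers, float(radius), float(n_out),
                           None if A_override is None else float(A_override))
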