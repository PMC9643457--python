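"""Layered-slab photon Monte Carlo (validation oracle for the diffusion solver).

Weighted photon random walk through the layer stack: exponential free-path
sampling against mu_t = mu_a + mu_s (mu_s = mu_s' / (1 - g)), partial
absorption w * mu_a/mu_t at each collision, Henyey-Greenstein scattering with
anisotropy g, Fresnel reflection/refraction at the external top/bottom faces
(internal interfaces are index-matched, as all layers share one n_r), and
Russian roulette below a weight threshold.

Fluence is scored with the collision estimator: each collision deposits
w / mu_t into its (rho, z) bin — the expected track length per collision —
so the bin sum divided by (photons x bin volume) estimates the fluence per
unit source power [cm^-2]; time-domain scoring adds the arrival-time bin
(t = geometric path x n_r / c0) and divides by dt as well [cm^-2 ns^-1].
The lateral geometry is an infinite slab: the cylindrical side wall of the
diffusion model is neglected, which is exactly why comparisons use large
radii.

Runs are split into batches; per-bin standard errors come from the batch
means.  A fixed seed reproduces histograms bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import DomainError
from .media import C0_CM_PER_NS, LayeredCylinder

__all__ = ["MCConfig", "MCResult", "run_mc", "compare_rel_error", "sample_hg"]


@dataclass(frozen=True)
class MCConfig:
    """Monte Carlo run parameters (bin widths follow the validation setup:
    d_rho = 0.99 mm, d_z = 0.27 mm, d_t = 0.02 ns)."""

    n_photons: int = 1_000_000
    g: float = 0.8
    rng_seed: int = 12345
    d_rho: float = 0.099            # [cm]
    d_z: float = 0.027              # [cm]
    d_t: float = 0.02               # [ns]
    rho_max: float = 10.0           # [cm]
    z_max: float = 4.0              # depth extent of the (rho, z) histogram [cm]
    t_max: float = 6.0              # [ns]
    roulette_threshold: float = 1e-4
    roulette_survive: float = 0.1
    n_batches: int = 32
    record_td: bool = True

    def __post_init__(self):
        if not (0.0 <= self.g < 1.0):
            raise DomainError("need 0 <= g < 1")
        if min(self.d_rho, self.d_z, self.d_t) <= 0:
            raise DomainError("bin widths must be > 0")
        if self.n_photons < 1:
            raise DomainError("n_photons must be >= 1")


@dataclass(frozen=True)
class MCResult:
    """Histograms (per batch) plus normalization metadata."""

    config: MCConfig
    ss_batches: np.ndarray      # (B, n_rho, n_z) collision-estimator sums
    td_batches: np.ndarray      # (B, n_rho, n_t) surface-bin sums
    totals: dict                # launched/absorbed/reflected/transmitted/...
    n_photons: int

    # --- bin geometry -------------------------------------------------
    @property
    def rho_edges(self) -> np.ndarray:
        n = self.ss_batches.shape[1]
        return np.arange(n + 1) * self.config.d_rho

    @property
    def rho_centers(self) -> np.ndarray:
        e = self.rho_edges
        return 0.5 * (e[:-1] + e[1:])

    @property
    def z_centers(self) -> np.ndarray:
        n = self.ss_batches.shape[2]
        return (np.arange(n) + 0.5) * self.config.d_z

    @property
    def t_centers(self) -> np.ndarray:
        n = self.td_batches.shape[2]
        return (np.arange(n) + 0.5) * self.config.d_t

    def _shell_volumes(self) -> np.ndarray:
        e = self.rho_edges
        return np.pi * (e[1:] ** 2 - e[:-1] ** 2) * self.config.d_z

    # --- estimates ----------------------------------------------------
    def fluence_ss(self) -> np.ndarray:
        """Steady-state fluence [cm^-2] per (rho, z) bin, per launched photon."""
        vol = self._shell_volumes()[:, None]
        return self.ss_batches.sum(axis=0) / (self.n_photons * vol)

    def stderr_ss(self) -> np.ndarray:
        B = self.ss_batches.shape[0]
        per = self.ss_batches / (self.n_photons / B * self._shell_volumes()[None, :, None])
        return per.std(axis=0, ddof=1) / math.sqrt(B)

    def fluence_td(self) -> np.ndarray:
        """Surface-bin time-resolved fluence [cm^-2 ns^-1] per (rho, t) bin."""
        vol = self._shell_volumes()[:, None] * self.config.d_t
        return self.td_batches.sum(axis=0) / (self.n_photons * vol)

    def stderr_td(self) -> np.ndarray:
        B = self.td_batches.shape[0]
        vol = self._shell_volumes()[:, None] * self.config.d_t
        per = self.td_batches / (self.n_photons / B * vol[None])
        return per.std(axis=0, ddof=1) / math.sqrt(B)

    def energy_balance(self) -> float:
        """|launched - (absorbed + escaped + roulette residual)| / launched."""
        t = self.totals
        acc = (t["absorbed"] + t["reflected"] + t["transmitted"]
               + t["roulette_killed"] - t["roulette_gain"])
        return abs(acc - t["launched"]) / t["launched"]


@njit(cache=False)
def _fresnel_internal(cos_i, n_rel):
    """Unpolarized reflectance hitting the boundary from inside (n_rel>=1)."""
    if n_rel == 1.0:
        return 0.0
    sin_i = math.sqrt(max(0.0, 1.0 - cos_i * cos_i))
    sin_t = n_rel * sin_i
    if sin_t >= 1.0:
        return 1.0
    cos_t = math.sqrt(1.0 - sin_t * sin_t)
    rs = (n_rel * cos_i - cos_t) / (n_rel * cos_i + cos_t)
    rp = (n_rel * cos_t - cos_i) / (n_rel * cos_t + cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=False)
def _hg_cos(g):
    if g == 0.0:
        return 1.0 - 2.0 * np.random.random()
    f = (1.0 - g * g) / (1.0 - g + 2.0 * g * np.random.random())
    return (1.0 + g * g - f * f) / (2.0 * g)


@njit(cache=False)
def _sample_hg_many(g, n, seed):
    np.random.seed(seed)
    out = np.empty(n)
    for i in range(n):
        out[i] = _hg_cos(g)
    return out


def sample_hg(g: float, n: int, seed: int = 0) -> np.ndarray:
    """Draw n Henyey-Greenstein deflection cosines (moment tests)."""
    return _sample_hg_many(float(g), int(n), int(seed))


@njit(cache=False)
def _simulate(seed, n_photons, mu_a, mu_s, z_edges, g, n_rel, z0, uz0_pencil,
              d_rho, n_rho, d_z, n_z, d_t, n_t, c_scale,
              roulette_threshold, roulette_survive, n_batches, record_td):
    """Photon loop.  Returns per-batch (rho,z) and (rho,t) histograms and the
    weight bookkeeping counters (Kahan-compensated)."""
    np.random.seed(seed)
    K = len(mu_a)
    L = z_edges[K]
    ss = np.zeros((n_batches, n_rho, n_z))
    td = np.zeros((n_batches, n_rho, n_t))
    # counters: absorbed, reflected, transmitted, roulette_killed, roulette_gain
    tot = np.zeros(5)
    comp = np.zeros(5)

    for ip in range(n_photons):
        b = ip % n_batches
        x = 0.0
        y = 0.0
        z = z0
        if uz0_pencil:
            ux, uy, uz = 0.0, 0.0, 1.0
        else:
            uz = 1.0 - 2.0 * np.random.random()
            psi = 2.0 * math.pi * np.random.random()
            sr = math.sqrt(max(0.0, 1.0 - uz * uz))
            ux = sr * math.cos(psi)
            uy = sr * math.sin(psi)
        w = 1.0
        path = 0.0
        # locate layer
        k = 0
        for kk in range(K):
            if z >= z_edges[kk + 1]:
                k = kk + 1
        alive = True
        while alive:
            tau = -math.log(np.random.random())
            while tau > 0.0:
                mt = mu_a[k] + mu_s[k]
                step = tau / mt if mt > 0.0 else 1e30
                if uz > 0.0:
                    db = (z_edges[k + 1] - z) / uz
                elif uz < 0.0:
                    db = (z_edges[k] - z) / uz
                else:
                    db = 1e30
                if step < db:
                    x += ux * step
                    y += uy * step
                    z += uz * step
                    path += step
                    tau = 0.0
                else:
                    x += ux * db
                    y += uy * db
                    z += uz * db
                    path += db
                    tau -= db * mt
                    if uz < 0.0 and k == 0:
                        # top external boundary
                        if np.random.random() < _fresnel_internal(-uz, n_rel):
                            uz = -uz
                            z = z_edges[0]
                        else:
                            d = w - comp[1]
                            t_ = tot[1] + d
                            comp[1] = (t_ - tot[1]) - d
                            tot[1] = t_
                            alive = False
                            break
                    elif uz > 0.0 and k == K - 1:
                        # bottom external boundary
                        if np.random.random() < _fresnel_internal(uz, n_rel):
                            uz = -uz
                            z = z_edges[K]
                        else:
                            d = w - comp[2]
                            t_ = tot[2] + d
                            comp[2] = (t_ - tot[2]) - d
                            tot[2] = t_
                            alive = False
                            break
                    elif uz > 0.0:
                        k += 1
                        z = z_edges[k]
                    else:
                        z = z_edges[k]
                        k -= 1
                if mt <= 0.0:
                    # vacuum-like layer: no collision possible
                    tau = 0.0
            if not alive:
                break
            # collision: score, absorb, scatter
            mt = mu_a[k] + mu_s[k]
            rho = math.sqrt(x * x + y * y)
            ir = int(rho / d_rho)
            iz = int(z / d_z)
            if ir < n_rho and iz < n_z:
                ss[b, ir, iz] += w / mt
            if record_td and iz == 0 and ir < n_rho:
                it = int(path * c_scale / d_t)
                if it < n_t:
                    td[b, ir, it] += w / mt
            dw = w * mu_a[k] / mt
            w -= dw
            d = dw - comp[0]
            t_ = tot[0] + d
            comp[0] = (t_ - tot[0]) - d
            tot[0] = t_
            if mu_s[k] <= 0.0:
                # pure absorber: the full weight is deposited
                d = w - comp[0]
                t_ = tot[0] + d
                comp[0] = (t_ - tot[0]) - d
                tot[0] = t_
                w = 0.0
                alive = False
                break
            ct = _hg_cos(g)
            st = math.sqrt(max(0.0, 1.0 - ct * ct))
            psi = 2.0 * math.pi * np.random.random()
            cp = math.cos(psi)
            sp = math.sin(psi)
            if abs(uz) > 0.99999:
                ux = st * cp
                uy = st * sp
                uz = ct * (1.0 if uz >= 0.0 else -1.0)
            else:
                den = math.sqrt(1.0 - uz * uz)
                ux_n = st * (ux * uz * cp - uy * sp) / den + ux * ct
                uy_n = st * (uy * uz * cp + ux * sp) / den + uy * ct
                uz_n = -den * st * cp + uz * ct
                ux, uy, uz = ux_n, uy_n, uz_n
            norm = math.sqrt(ux * ux + uy * uy + uz * uz)
            ux /= norm
            uy /= norm
            uz /= norm
            # roulette
            if w < roulette_threshold:
                if np.random.random() < roulette_survive:
                    gain = w / roulette_survive - w
                    w = w / roulette_survive
                    d = gain - comp[4]
                    t_ = tot[4] + d
                    comp[4] = (t_ - tot[4]) - d
                    tot[4] = t_
                else:
                    d = w - comp[3]
                    t_ = tot[3] + d
                    comp[3] = (t_ - tot[3]) - d
                    tot[3] = t_
                    w = 0.0
                    alive = False
    return ss, td, tot


def run_mc(config: MCConfig, medium: LayeredCylinder,
           mu_sp_override=None, pencil: bool = False) -> MCResult:
    """Run the layered Monte Carlo for the given medium.

    ``mu_sp_override`` substitutes per-layer reduced scattering values for
    the Monte Carlo only (e.g. the raw CSF mu_s' where the diffusion model
    uses a transport-corrected value).  ``pencil`` launches a collimated
    downward beam at the surface instead of the isotropic source at z0
    (used by attenuation oracles)."""
    mu_sp = np.asarray(mu_sp_override if mu_sp_override is not None
                       else medium.mu_sp, dtype=float)
    mu_s = mu_sp / (1.0 - config.g) if config.g < 1.0 else mu_sp
    mu_a = medium.mu_a
    z_edges = np.concatenate([[0.0], np.asarray(medium.interface_depths)])
    n_rho = int(round(config.rho_max / config.d_rho))
    n_z = int(round(min(config.z_max, medium.total_thickness_L) / config.d_z))
    n_t = int(round(config.t_max / config.d_t)) if config.record_td else 1
    z0 = 1e-9 if pencil else medium.boundary.z0
    c_scale = medium.n_r / C0_CM_PER_NS      # ns per cm of path
    ss, td, tot = _simulate(
        config.rng_seed, config.n_photons, mu_a, mu_s, z_edges,
        config.g, medium.n_r / medium.n_out, z0, pencil,
        config.d_rho, n_rho, config.d_z, n_z, config.d_t, n_t, c_scale,
        config.roulette_threshold, config.roulette_survive,
        config.n_batches, config.record_td)
    totals = {"launched": float(config.n_photons),
              "absorbed": tot[0], "reflected": tot[1], "transmitted": tot[2],
              "roulette_killed": tot[3], "roulette_gain": tot[4]}
    return MCResult(config, ss, td, totals, config.n_photons)


def compare_rel_error(mc_values, mc_stderr, dt_values, stderr_limit=0.01,
                      min_value=0.0):
    """Per-bin |1 - Phi_DT / Phi_MC| where the MC is well sampled.

    Returns (rel_error array, mask of compared bins).  Bins that are empty
    or whose relative standard error exceeds ``stderr_limit`` are excluded.
    """
    mc_values = np.asarray(mc_values, dtype=float)
    dt_values = np.asarray(dt_values, dtype=float)
    mc_stderr = np.asarray(mc_stderr, dtype=float)
    mask = (mc_values > min_value) & (mc_stderr <= stderr_limit * np.abs(mc_values))
    rel = np.full(mc_values.shape, np.nan)
    rel[mask] = np.abs(1.0 - dt_values[mask] / mc_values[mask])
    return rel, mask
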