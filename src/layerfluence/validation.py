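"""Monte Carlo vs diffusion comparison harness.

Shared by the test suite and the acceptance script.  Conventions:

* The Monte Carlo surface tally uses a thicker shell (default 1 mm) than the
  native depth binning so the collision estimator is well sampled at desk
  photon counts; the diffusion side computes the matching *shell average*
  (midpoint rule over sub-depths), so the registration is unbiased rather
  than relying on a thin-bin/boundary-value approximation.
* Comparisons are made per rho bin (bin centers) where the Monte Carlo
  relative standard error is below ``stderr_limit``; the first half
  millimetre of rho is always excluded (diffusion theory is invalid there).
* Time-domain histograms are scored at the native 0.02 ns resolution and
  aggregated in blocks of ``t_rebin`` bins before comparison; the diffusion
  curve is averaged over the same sub-bin centers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .montecarlo import MCConfig, MCResult, compare_rel_error, run_mc
from .steady_state import ConvergenceControl, fluence_ss
from .time_domain import choose_N, fluence_td

__all__ = ["surface_mc", "ss_comparison", "td_comparison", "ComparisonResult"]

RHO_MIN_VALID = 0.5   # cm; diffusion theory breaks down closer to the source
#: time-domain validity: compare only where c*t >= this multiple of rho
#: (photons must have scattered over several ballistic distances before
#: diffusion theory describes the rising edge)
BALLISTIC_PATH_FACTOR = 3.0


@dataclass(frozen=True)
class ComparisonResult:
    """Per-bin relative errors |1 - Phi_DT/Phi_MC| over the well-sampled range."""

    axis: np.ndarray          # rho [cm] or t [ns] bin centers compared
    rel_error: np.ndarray
    mc_values: np.ndarray
    dt_values: np.ndarray
    mc_stderr: np.ndarray

    @property
    def max_rel_error(self) -> float:
        return float(np.max(self.rel_error)) if len(self.rel_error) else float("nan")


def surface_mc(medium, n_photons, seed, *, shell=0.1, rho_max=8.0,
               t_max=4.0, record_td=True, g=0.8,
               mu_sp_override=None) -> MCResult:
    """Run the layered MC with a single surface tally shell of depth ``shell``."""
    cfg = MCConfig(n_photons=int(n_photons), g=g, rng_seed=int(seed),
                   d_z=float(shell), z_max=float(shell), rho_max=float(rho_max),
                   t_max=float(t_max), record_td=record_td)
    return run_mc(cfg, medium, mu_sp_override=mu_sp_override)


def _shell_depths(shell: float, n_sub: int = 5) -> np.ndarray:
    return (np.arange(n_sub) + 0.5) * (shell / n_sub)


def _dt_shell_average_ss(medium, rho, shell, control) -> np.ndarray:
    vals = [fluence_ss(medium, rho, z, control, allow_interior=True).values
            for z in _shell_depths(shell)]
    return np.mean(vals, axis=0)


def ss_comparison(mc: MCResult, medium, stderr_limit=0.01,
                  rho_min=RHO_MIN_VALID, rho_max=None,
                  control: ConvergenceControl | None = None) -> ComparisonResult:
    """Steady-state surface fluence comparison per rho bin."""
    control = control or ConvergenceControl(rel_tol=1e-10, n_max=20000)
    shell = mc.config.d_z
    rc = mc.rho_centers
    f_mc = mc.fluence_ss()[:, 0]
    se = mc.stderr_ss()[:, 0]
    dt = _dt_shell_average_ss(medium, rc, shell, control)
    rel, mask = compare_rel_error(f_mc, se, dt, stderr_limit=stderr_limit)
    mask &= rc >= rho_min
    if rho_max is not None:
        mask &= rc <= rho_max
    return ComparisonResult(rc[mask], rel[mask], f_mc[mask], dt[mask], se[mask])


def td_comparison(mc: MCResult, medium, rho, stderr_limit=0.01,
                  t_rebin=5, rho_rebin=3, N_evals=None,
                  control: ConvergenceControl | None = None) -> ComparisonResult:
    """Time-domain surface fluence comparison around one rho, rebinned.

    Adjacent native bins are aggregated (``t_rebin`` in time, ``rho_rebin``
    annuli around the requested rho) so the collision tally is well sampled
    at desk photon counts; the diffusion side averages over the same
    sub-bins (area-weighted in rho), keeping the registration unbiased."""
    control = control or ConvergenceControl(rel_tol=1e-10, n_max=20000)
    shell = mc.config.d_z
    rc = mc.rho_centers
    ir0 = int(np.argmin(np.abs(rc - rho))) - rho_rebin // 2
    ir0 = max(0, min(ir0, len(rc) - rho_rebin))
    irs = np.arange(ir0, ir0 + rho_rebin)
    tc = mc.t_centers
    n_blocks = len(tc) // t_rebin
    B = mc.td_batches.shape[0]
    # aggregate raw batch sums, then renormalize per aggregated bin
    raw = mc.td_batches[:, irs, :n_blocks * t_rebin].sum(axis=1) \
        .reshape(B, n_blocks, t_rebin).sum(axis=2)
    edges = mc.rho_edges
    areas = np.pi * (edges[irs + 1] ** 2 - edges[irs] ** 2)
    vol = areas.sum() * shell * (mc.config.d_t * t_rebin)
    f_mc = raw.sum(axis=0) / (mc.n_photons * vol)
    per = raw / (mc.n_photons / B * vol)
    se = per.std(axis=0, ddof=1) / np.sqrt(B)
    t_blocks = tc[:n_blocks * t_rebin].reshape(n_blocks, t_rebin)

    if N_evals is None:
        N_evals = choose_N(6.0)
    # diffusion: average over shell depths, sub-annuli (area weights) and
    # the sub-bin times
    times = t_blocks.ravel()
    vals = []
    for z in _shell_depths(shell):
        curve = fluence_td(medium, rc[irs], z, times, N_evals=N_evals,
                           control=control, allow_interior=True)
        vals.append(np.average(curve.values, axis=0, weights=areas))
    dt = np.mean(vals, axis=0).reshape(n_blocks, t_rebin).mean(axis=1)

    rel, mask = compare_rel_error(f_mc, se, dt, stderr_limit=stderr_limit)
    centers = t_blocks.mean(axis=1)
    # diffusion-validity floor in time: photon paths must be several times
    # the ballistic distance (the rising edge is outside diffusion theory,
    # the time-domain analogue of excluding rho < 0.5 cm)
    t_min = BALLISTIC_PATH_FACTOR * rc[irs].mean() / medium.c_medium
    mask &= centers >= t_min
    return ComparisonResult(centers[mask], rel[mask], f_mc[mask], dt[mask], se[mask])
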