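"""Named tissue models and validation scenarios, ready to run.

Each scenario bundles the optical properties, layer thicknesses and query
grids of one published validation configuration: homogeneous stacks used to
emulate a semi-infinite medium, the convergence/contour study setups, and
three clinically motivated tissue models (a 2-layer model, skin/fat/muscle,
and a 5-layer scalp/skull/CSF/gray/white head model).

All media share n_r = 1.4 inside with air (n = 1.0) outside, and the Monte
Carlo arm uses Henyey-Greenstein anisotropy g = 0.8 in every layer.  The
head model's cerebrospinal-fluid layer scatters far too weakly for diffusion
theory; the diffusion arm substitutes a transport-corrected mu_s' = 3.5
cm^-1 there while the Monte Carlo arm keeps the raw 0.25 cm^-1
(``mc_mu_sp``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .media import LayeredCylinder, build_medium

__all__ = ["NamedScenario", "scenario", "scenario_names"]


@dataclass(frozen=True)
class NamedScenario:
    """A fully specified medium plus the query grids used in validation."""

    name: str
    mu_a: tuple            # per-layer absorption [cm^-1] (diffusion arm)
    mu_sp: tuple           # per-layer reduced scattering [cm^-1] (diffusion arm)
    thickness: tuple       # [cm]
    radius: float          # [cm]
    n_r: float = 1.4
    n_out: float = 1.0
    g: float = 0.8
    mc_mu_sp: tuple | None = None    # Monte Carlo overrides (e.g. raw CSF)
    queries: dict = field(default_factory=dict)
    notes: str = ""

    def build(self) -> LayeredCylinder:
        return build_medium(self.mu_a, self.mu_sp, self.thickness,
                            n_r=self.n_r, radius=self.radius, n_out=self.n_out)

    def as_config(self) -> str:
        """The flat key=value medium configuration the CLI consumes."""
        lines = [
            f"mu_a = {', '.join(repr(v) for v in self.mu_a)}",
            f"mu_sp = {', '.join(repr(v) for v in self.mu_sp)}",
            f"thickness = {', '.join(repr(v) for v in self.thickness)}",
            f"n_r = {self.n_r}",
            f"radius = {self.radius}",
            f"n_out = {self.n_out}",
        ]
        return "\n".join(lines) + "\n"


def _homog(n_layers, total_L, mu_a, mu_sp, radius):
    per = total_L / n_layers
    return dict(mu_a=(mu_a,) * n_layers, mu_sp=(mu_sp,) * n_layers,
                thickness=(per,) * n_layers, radius=radius)


_SCENARIOS: dict[str, NamedScenario] = {}


def _register(s: NamedScenario):
    _SCENARIOS[s.name] = s


_register(NamedScenario(
    name="semiinf_2layer", **_homog(2, 10.0, 0.1, 10.0, 20.0),
    queries={"rho": (0.5, 10.0), "t": (0.0, 6.0)},
    notes="two equal 5 cm layers, a=20 cm: emulates a semi-infinite medium "
          "for the homogeneous-limit and Monte Carlo comparisons"))
_register(NamedScenario(
    name="semiinf_8layer", **_homog(8, 10.0, 0.1, 10.0, 20.0),
    queries={"rho": (0.5, 10.0), "t": (0.0, 6.0)},
    notes="eight equal 1.25 cm layers; must agree with semiinf_2layer to "
          "floating-point accuracy (layering invariance)"))
_register(NamedScenario(
    name="fig3_baseline",
    mu_a=(0.1, 0.1), mu_sp=(10.0, 10.0), thickness=(1.0, 20.0), radius=10.0,
    queries={"rho": 1.0, "z": 0.0},
    notes="2-layer baseline for the root-count convergence study (vary "
          "mu_s1', mu_a1, mu_s2', mu_a2, z, a around this point)"))
_register(NamedScenario(
    name="fig4_contour",
    mu_a=(0.1,) * 4, mu_sp=(10.0,) * 4, thickness=(0.5, 1.5, 3.0, 5.0),
    radius=15.0,
    queries={"rho": 1.0, "t_windows": [(1.0, 5.0), (0.1, 5.0), (0.01, 5.0),
                                       (0.001, 5.0)], "t_wide": (0.03, 6.0)},
    notes="4-layer equal-property medium for the Laplace contour accuracy "
          "and dynamic-range studies"))
_register(NamedScenario(
    name="fig5a_high_scatter",
    mu_a=(0.1,) * 4, mu_sp=(80.0,) * 4, thickness=(0.5, 1.5, 3.5, 30.0),
    radius=15.0,
    queries={"rho": (0.2, 3.5), "t": (0.004, 6.0)},
    notes="high scattering + 30 cm bottom layer: the overflow stress test "
          "(double precision must stay finite at 50,000 roots)"))
_register(NamedScenario(
    name="fig5b_high_abs",
    mu_a=(0.6,) * 4, mu_sp=(10.0,) * 4, thickness=(0.5, 1.5, 3.5, 30.0),
    radius=15.0,
    queries={"rho": (3.0, 6.0), "t": (0.1, 6.0), "N_evals": 168, "n_terms": 600,
             "precision": "oct"},
    notes="high absorption, octuple precision: extreme-dynamic-range "
          "time-domain reconstruction"))
_register(NamedScenario(
    name="two_layer",
    mu_a=(0.2, 0.1), mu_sp=(13.0, 12.0), thickness=(0.6, 9.0), radius=20.0,
    queries={"rho": (0.15, 10.0), "td_rho": (0.45, 1.45, 3.05)},
    notes="published 2-layer tissue model; radius chosen large so the side "
          "wall is negligible against the laterally infinite Monte Carlo"))
_register(NamedScenario(
    name="skin_fat_muscle",
    mu_a=(0.15, 0.02, 0.2), mu_sp=(15.0, 12.0, 5.0),
    thickness=(0.12, 0.38, 10.0), radius=20.0,
    queries={"rho": (0.15, 10.0), "td_rho": (0.45, 1.45, 3.05)},
    notes="3-layer skin/fat/muscle model; diffusion is expected to hold to "
          "rel. error < 0.1 for rho < 6 cm (thin top layer limits accuracy)"))
_register(NamedScenario(
    name="brain_5layer",
    mu_a=(0.18, 0.16, 0.04, 0.36, 0.14),
    mu_sp=(19.0, 16.0, 3.5, 22.0, 9.1),
    thickness=(0.5, 0.8, 0.2, 0.5, 4.0), radius=20.0,
    mc_mu_sp=(19.0, 16.0, 0.25, 22.0, 9.1),
    queries={"rho": (0.15, 10.0), "td_rho": (0.45, 1.45, 3.05)},
    notes="scalp/skull/CSF/gray/white head model; the diffusion arm uses "
          "mu_s' = 3.5 cm^-1 in the CSF layer in place of the raw 0.25 "
          "(mc_mu_sp), and the white-matter layer is taken semi-infinite "
          "at 4 cm"))


def scenario_names() -> list[str]:
    return sorted(_SCENARIOS)


def scenario(name: str) -> NamedScenario:
    """Look up a named validation scenario; unknown names list the options."""
    try:
        return _SCENARIOS[name]
    except KeyError:
        raise KeyError(f"unknown scenario {name!r}; valid names: "
                       f"{', '.join(scenario_names())}") from None
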