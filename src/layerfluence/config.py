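"""Flat key=value configuration parsing and tabular output helpers.

The medium configuration format is intentionally minimal: one ``key =
value`` pair per line, ``#`` comments, comma-separated lists for per-layer
quantities.  The same parser backs the CLI ``--config`` flag and the library
``load_medium_config`` entry point, so both resolve identically; CLI flags
override file values which override defaults.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .errors import DomainError
from .media import build_medium

__all__ = ["parse_config", "load_medium_config", "write_curve"]

_LIST_KEYS = {"mu_a", "mu_sp", "thickness", "rho", "times"}
_SCALAR_KEYS = {"n_r", "radius", "n_out", "t1", "t2", "tol", "g"}
_INT_KEYS = {"n_terms", "n_laplace", "photons", "seed"}


def parse_config(path_or_text) -> dict:
    """Parse the flat key=value format into typed values."""
    text = Path(path_or_text).read_text() if Path(str(path_or_text)).is_file() \
        else str(path_or_text)
    out: dict = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise DomainError(f"config line {lineno}: expected key = value, got {raw!r}")
        key, _, val = line.partition("=")
        key = key.strip()
        val = val.strip()
        if key in _LIST_KEYS:
            out[key] = [float(v) for v in val.split(",") if v.strip()]
        elif key in _INT_KEYS:
            out[key] = int(val)
        elif key in _SCALAR_KEYS:
            out[key] = float(val)
        else:
            out[key] = val
    return out


def load_medium_config(path_or_text):
    """Build a LayeredCylinder from a flat config file or string."""
    cfg = parse_config(path_or_text)
    missing = {"mu_a", "mu_sp", "thickness"} - cfg.keys()
    if missing:
        raise DomainError(f"medium config missing keys: {sorted(missing)}")
    return build_medium(cfg["mu_a"], cfg["mu_sp"], cfg["thickness"],
                        n_r=cfg.get("n_r", 1.4), radius=cfg.get("radius", 10.0),
                        n_out=cfg.get("n_out", 1.0))


def _curve_frame(curve) -> pd.DataFrame:
    from .steady_state import FluenceCurve
    from .time_domain import TDFluenceCurve
    if isinstance(curve, FluenceCurve):
        return pd.DataFrame({
            "rho_cm": curve.rho,
            "fluence_per_cm2": [float(v) for v in curve.values],
            "terms_used": curve.terms_used,
            "converged": curve.converged,
        })
    if isinstance(curve, TDFluenceCurve):
        rows = []
        for i, r in enumerate(curve.rho):
            for j, t in enumerate(curve.times):
                rows.append((r, t, float(curve.values[i, j]),
                             int(curve.n_terms[i].max())))
        return pd.DataFrame(rows, columns=["rho_cm", "t_ns",
                                           "fluence_per_cm2_ns", "n_terms"])
    raise TypeError(f"cannot serialize {type(curve).__name__}")


def write_curve(curve, path, metadata: dict | None = None) -> Path:
    """Write a fluence curve as CSV (full float precision) plus a JSON
    metadata sidecar (<path>.meta.json)."""
    path = Path(path)
    frame = _curve_frame(curve)
    frame.to_csv(path, index=False, float_format=None)
    meta = dict(metadata or {})
    meta.setdefault("columns", list(frame.columns))
    meta.setdefault("n_rows", int(len(frame)))
    if hasattr(curve, "meta"):
        meta.update({k: v for k, v in curve.meta.items()
                     if isinstance(v, (str, int, float, bool))})
    if hasattr(curve, "contour"):
        c = curve.contour
        meta.update({"N_evals": c.N_evals, "t1": c.t1, "t2": c.t2,
                     "Lambda": c.Lambda})
    side = path.with_suffix(path.suffix + ".meta.json")
    side.write_text(json.dumps(meta, indent=2, default=float) + "\n")
    return path
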