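"""Zeros of J0 and fast J0/J1 evaluation in double or extended precision.

The finite Hankel inversion expands the fluence on Bessel modes whose
dimensionless frequencies are the positive zeros ``s~_n`` of J0 (divided by
the extrapolated radius ``a'`` at use sites).  Roots are computed by a
McMahon asymptotic initial guess polished with Newton iterations at the
target precision, and cached on disk as plain text keyed by
``(n_max, precision_bits)``.

Double-precision J0/J1 go through scipy.special.  Extended precision uses an
in-package evaluator (Taylor series with guard digits for small arguments,
Hankel asymptotic expansion for large ones) because generic multiprecision
Bessel routines are orders of magnitude too slow for 50,000-root reference
sums; the evaluator is validated against mpmath.besselj in the test suite.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import mpmath
import numpy as np
from scipy import special as _sp

from .errors import DomainError
from .precision import DOUBLE, Context, get_context

__all__ = ["RootTable", "compute_roots", "j0", "j1", "mcmahon_j0_zero"]


# ----------------------------------------------------------------- J0 / J1

def _check_domain(x):
    xf = np.asarray(x, dtype=float) if not isinstance(x, (mpmath.mpf, mpmath.mpc)) else x
    if isinstance(xf, np.ndarray):
        if np.any(np.isnan(xf)) or np.any(xf < 0):
            raise DomainError("j0/j1 require finite x >= 0")
    else:
        if mpmath.isnan(xf) or xf < 0:
            raise DomainError("j0/j1 require finite x >= 0")


def _hankel_pq(nu: int, x, prec_bits: int):
    """P, Q of the large-argument expansion J_nu = sqrt(2/pi x)(P cos chi - Q sin chi),
    chi = x - (nu/2 + 1/4) pi, summed to its optimal truncation."""
    four_nu2 = 4 * nu * nu
    one = mpmath.mpf(1)
    P = one
    Q = mpmath.mpf(0)
    a = one
    inv_x = 1 / mpmath.mpf(x)
    tiny = mpmath.mpf(2) ** (-(prec_bits + 10))
    prev = mpmath.inf
    for k in range(1, 4 * prec_bits):
        a = a * (four_nu2 - (2 * k - 1) ** 2) / (8 * k)
        term = a * inv_x**k
        if abs(term) > prev:        # asymptotic floor reached
            break
        prev = abs(term)
        j = k // 2
        sign = -1 if j % 2 else 1
        if k % 2:
            Q += sign * term
        else:
            P += sign * term
        if abs(term) < tiny:
            break
    return P, Q


def _mp_bessel(nu: int, x, bits: int):
    """J0 or J1 for real x >= 0, accurate to ~``bits`` bits (rounded to bits)."""
    bits = int(bits)
    x = mpmath.mpf(x)
    if x == 0:
        return mpmath.mpf(1 if nu == 0 else 0)
    switch = 0.37 * bits + 15.0
    if x < switch:
        # Taylor series with guard digits against the e^{2x} cancellation
        guard = int(3.0 * float(x)) + 30
        with mpmath.workprec(bits + guard):
            xh = mpmath.mpf(x) / 2
            q = -(xh * xh)
            term = xh**nu / mpmath.factorial(nu)
            total = term
            tiny = mpmath.mpf(2) ** (-(bits + 20))
            k = 1
            while True:
                term = term * q / (k * (k + nu))
                total += term
                if abs(term) < tiny * max(1, abs(total)):
                    break
                k += 1
        with mpmath.workprec(bits):
            return +total
    with mpmath.workprec(bits + 30):
        P, Q = _hankel_pq(nu, x, bits)
        chi = x - (2 * nu + 1) * mpmath.pi / 4
        val = mpmath.sqrt(2 / (mpmath.pi * x)) * (P * mpmath.cos(chi) - Q * mpmath.sin(chi))
    with mpmath.workprec(bits):
        return +val


def j0(x, ctx: Context = DOUBLE):
    """Bessel J0(x) for x >= 0 in the given arithmetic context."""
    _check_domain(x)
    ctx = get_context(ctx)
    if not ctx.is_mp:
        return _sp.j0(x)
    return _mp_bessel(0, x, ctx.bits)


def j1(x, ctx: Context = DOUBLE):
    """Bessel J1(x) for x >= 0 in the given arithmetic context."""
    _check_domain(x)
    ctx = get_context(ctx)
    if not ctx.is_mp:
        return _sp.j1(x)
    return _mp_bessel(1, x, ctx.bits)


# ----------------------------------------------------------------- roots

def mcmahon_j0_zero(n):
    """McMahon asymptotic approximation of the n-th positive zero of J0."""
    b = (np.asarray(n, dtype=float) - 0.25) * np.pi
    u = 1.0 / (8.0 * b)
    return (b + u * (1.0 + u * u * (-124.0 / 3.0
            + u * u * (120928.0 / 15.0 - u * u * 401743168.0 / 105.0))))


@dataclass(frozen=True)
class RootTable:
    """Positive zeros of J0 with the 1/J1(root)^2 Hankel weights.

    ``roots``/``weights`` are float ndarrays in double precision and lists of
    mpmath numbers in extended precision; ``precision_bits`` records the
    working precision of the root computation.
    """

    roots: object
    weights: object          # 1 / J1(root)^2
    n_max: int
    precision_bits: int

    def __len__(self):
        return self.n_max


def _roots_double(n_max: int) -> np.ndarray:
    x = mcmahon_j0_zero(np.arange(1, n_max + 1))
    for _ in range(4):
        x = x + _sp.j0(x) / _sp.j1(x)
    return x


def _roots_mp(n_max: int, ctx: Context) -> list:
    bits = ctx.bits
    work = bits + 40
    guesses = _roots_double(n_max)
    with mpmath.workprec(work):
        tol = mpmath.mpf(2) ** (-(bits + 10))
        roots = []
        for g in guesses:
            x = mpmath.mpf(g)
            # start is already ~double-accurate; Newton doubles digits per step
            for _ in range(10):
                dx = _mp_bessel(0, x, work) / _mp_bessel(1, x, work)
                x += dx
                if abs(dx) < tol * x:
                    break
            roots.append(x)
    with mpmath.workprec(bits):
        return [+r for r in roots]


def _cache_dir() -> Path:
    base = os.environ.get("XDG_CACHE_HOME", os.path.join(os.path.expanduser("~"), ".cache"))
    return Path(base) / "layerfluence"


def _cache_path(n_max: int, bits: int) -> Path:
    return _cache_dir() / f"j0_roots_n{n_max}_p{bits}.txt"


def _write_cache(path: Path, table: RootTable):
    try:
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            fh.write(f"# n_max={table.n_max} precision_bits={table.precision_bits}\n")
            if table.precision_bits <= 53:
                for r in table.roots:
                    fh.write(f"{r!r}\n")
            else:
                digits = int(table.precision_bits * 0.302) + 5
                with mpmath.workprec(table.precision_bits):
                    for r in table.roots:
                        fh.write(mpmath.nstr(r, digits) + "\n")
    except OSError:
        pass  # caching is best-effort


def _read_cache(path: Path, n_max: int, bits: int):
    try:
        with open(path) as fh:
            header = fh.readline()
            if f"n_max={n_max}" not in header or f"precision_bits={bits}" not in header:
                return None
            lines = [line.strip() for line in fh if line.strip()]
        if len(lines) != n_max:
            return None
        if bits <= 53:
            return np.array([float(v) for v in lines])
        with mpmath.workprec(bits):
            return [mpmath.mpf(v) for v in lines]
    except (OSError, ValueError):
        return None


_MEM_CACHE: dict[tuple[int, int], RootTable] = {}


def compute_roots(n_max: int, precision_bits=53, use_disk_cache: bool = True) -> RootTable:
    """Zeros of J0 (and Hankel weights 1/J1^2) up to index ``n_max``.

    ``precision_bits`` may be an int or a precision Context/name.  Results are
    memoized in memory and, best-effort, on disk as plain text.
    """
    if n_max < 1:
        raise DomainError("n_max must be >= 1")
    ctx = get_context(precision_bits)
    bits = ctx.bits
    key = (int(n_max), bits)
    hit = _MEM_CACHE.get(key)
    if hit is not None:
        return hit
    # a larger cached table also serves
    for (nm, b), tab in _MEM_CACHE.items():
        if b == bits and nm >= n_max:
            sub = RootTable(tab.roots[:n_max], tab.weights[:n_max], n_max, bits)
            _MEM_CACHE[key] = sub
            return sub

    roots = _read_cache(_cache_path(n_max, bits), n_max, bits) if use_disk_cache else None
    if roots is None:
        roots = _roots_double(n_max) if not ctx.is_mp else _roots_mp(n_max, ctx)

    if not ctx.is_mp:
        w = 1.0 / _sp.j1(roots) ** 2
    else:
        with mpmath.workprec(bits):
            w = [1 / _mp_bessel(1, r, bits) ** 2 for r in roots]
    table = RootTable(roots, w, int(n_max), bits)
    _MEM_CACHE[key] = table
    if use_disk_cache and not _cache_path(n_max, bits).exists():
        _write_cache(_cache_path(n_max, bits), table)
    return table
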