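"""Arithmetic contexts: double precision (numpy) and extended precision (mpmath).

Every numerical kernel in this package (Green's functions, Hankel sums,
Laplace contours, closed-form references) is written against the small
:class:`Context` interface below rather than a fixed float type, so the same
code runs in double, quadruple (113-bit) or octuple (237-bit) arithmetic.
The context is always passed explicitly; nothing mutates global state except
inside a ``with ctx.workprec()`` block wrapping an mpmath computation.
"""

from __future__ import annotations

import contextlib

import mpmath
import numpy as np
from scipy import special as _sp

__all__ = ["Context", "DOUBLE", "QUAD", "OCT", "get_context"]

QUAD_BITS = 113
OCT_BITS = 237


class Context:
    """Base interface; see :class:`NumpyContext` and :class:`MPContext`."""

    name: str
    bits: int
    is_mp: bool

    def workprec(self):
        raise NotImplementedError

    # conversions -----------------------------------------------------
    def real(self, x):
        raise NotImplementedError

    def to_complex(self, re, im=0.0):
        raise NotImplementedError

    def to_float(self, x) -> float:
        raise NotImplementedError

    # elementary functions -------------------------------------------
    def exp(self, x):
        raise NotImplementedError

    def sqrt(self, x):
        raise NotImplementedError

    def __repr__(self):  # pragma: no cover - cosmetic
        return f"<Context {self.name} ({self.bits} bits)>"


class NumpyContext(Context):
    """IEEE double precision; scalars and ndarrays pass through numpy ufuncs."""

    name = "double"
    bits = 53
    is_mp = False
    eps = float(np.finfo(float).eps)

    def workprec(self):
        return contextlib.nullcontext()

    def real(self, x):
        return np.asarray(x, dtype=float) if np.ndim(x) else float(x)

    def to_complex(self, re, im=0.0):
        return re + 1j * im

    def to_float(self, x):
        return float(np.real(x))

    exp = staticmethod(np.exp)
    sqrt = staticmethod(lambda x: np.sqrt(np.asarray(x, dtype=complex))
                        if np.ndim(x) else np.sqrt(complex(x)))
    cos = staticmethod(np.cos)
    sin = staticmethod(np.sin)
    log = staticmethod(np.log)
    pi = float(np.pi)

    def j0(self, x):
        return _sp.j0(x)

    def j1(self, x):
        return _sp.j1(x)


class MPContext(Context):
    """mpmath arbitrary precision at a fixed bit count (scalar arithmetic)."""

    is_mp = True

    def __init__(self, bits: int, name: str | None = None):
        self.bits = int(bits)
        self.name = name or f"mp{bits}"
        with self.workprec():
            self.eps = float(mpmath.mpf(2) ** (1 - self.bits))
            self.pi = +mpmath.pi

    def workprec(self):
        return mpmath.workprec(self.bits)

    def real(self, x):
        return mpmath.mpf(x) if not isinstance(x, mpmath.mpf) else x

    def to_complex(self, re, im=0.0):
        return mpmath.mpc(re, im)

    def to_float(self, x):
        return float(mpmath.mpf(x.real) if isinstance(x, mpmath.mpc) else mpmath.mpf(x))

    exp = staticmethod(mpmath.exp)
    sqrt = staticmethod(mpmath.sqrt)
    cos = staticmethod(mpmath.cos)
    sin = staticmethod(mpmath.sin)
    log = staticmethod(mpmath.log)

    def j0(self, x):
        from .bessel import j0 as _j0
        return _j0(x, ctx=self)

    def j1(self, x):
        from .bessel import j1 as _j1
        return _j1(x, ctx=self)


DOUBLE = NumpyContext()
QUAD = MPContext(QUAD_BITS, "quad")
OCT = MPContext(OCT_BITS, "oct")

_BY_NAME = {"double": DOUBLE, "quad": QUAD, "oct": OCT, "octuple": OCT,
            "quadruple": QUAD}


def get_context(spec) -> Context:
    """Resolve ``"double" | "quad" | "oct" | int bits | Context`` to a Context."""
    if isinstance(spec, Context):
        return spec
    if isinstance(spec, str):
        try:
            return _BY_NAME[spec.lower()]
        except KeyError:
            raise ValueError(f"unknown precision {spec!r}; use double/quad/oct") from None
    bits = int(spec)
    if bits <= 53:
        return DOUBLE
    if bits == QUAD_BITS:
        return QUAD
    if bits == OCT_BITS:
        return OCT
    return MPContext(bits)
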