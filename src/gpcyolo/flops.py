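"""Closed-form FLOP counts for the convolution variants used in the model.

These are the per-layer cost laws (multiply-accumulate counts over one
output feature map) that motivate the lightweight design:

* standard convolution (SC):       ``W*H*K1*K2*C1*C2``
* grouped spatial convolution:     ``W*H*K1*K2*(C2/2)*(C1+1)``
* partial convolution (PConv):     ``W*H*K^2*Cp^2``

Everything is exact integer (or :class:`fractions.Fraction`) arithmetic so
the headline ratios — GSConv/SC -> 1/2 as the input width grows, and
PConv/SC = 1/16 at a partial ratio of 1/4 — hold identically, not just to
float precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional

__all__ = [
    "FlopsQuery",
    "flops_sc",
    "flops_gsconv",
    "flops_pconv",
    "gsconv_sc_ratio",
    "gsconv_sc_ratio_limit",
    "pconv_sc_ratio",
]


@dataclass(frozen=True)
class FlopsQuery:
    """Symbolic cost query for one convolution layer.

    ``W``/``H`` are the *output* feature-map width and height, ``K1``/``K2``
    the kernel size, ``C1``/``C2`` input/output channels and ``Cp`` the
    partial-channel count (PConv only, where ``C1 == C2``).
    """

    W: int
    H: int
    K1: int
    K2: int
    C1: int
    C2: int
    Cp: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("W", "H", "K1", "K2", "C1", "C2"):
            v = getattr(self, name)
            if not isinstance(v, int) or v <= 0:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.Cp is not None:
            if not isinstance(self.Cp, int) or self.Cp <= 0:
                raise ValueError(f"Cp must be a positive integer, got {self.Cp!r}")
            if self.Cp > self.C1:
                raise ValueError(f"Cp ({self.Cp}) cannot exceed C1 ({self.C1})")


def flops_sc(q: FlopsQuery) -> int:
    """Dense convolution cost: every input channel feeds every output channel."""
    return q.W * q.H * q.K1 * q.K2 * q.C1 * q.C2


def flops_gsconv(q: FlopsQuery) -> int:
    """GSConv cost: half the outputs from a dense convolution, half from a
    depthwise pass over them, hence the ``(C2/2)*(C1+1)`` factor."""
    if q.C2 % 2 != 0:
        raise ValueError(f"GSConv needs an even output-channel count, got C2={q.C2}")
    return q.W * q.H * q.K1 * q.K2 * (q.C2 // 2) * (q.C1 + 1)


def flops_pconv(q: FlopsQuery) -> int:
    """PConv cost: a K x K dense convolution restricted to ``Cp`` channels,
    the remaining ``C1 - Cp`` channels passing through for free.

    Requires a square kernel (``K1 == K2``) and ``Cp`` set on the query.
    """
    if q.Cp is None:
        raise ValueError("flops_pconv needs Cp set on the query")
    if q.K1 != q.K2:
        raise ValueError(f"PConv assumes a square kernel, got {q.K1}x{q.K2}")
    return q.W * q.H * q.K1 * q.K2 * q.Cp * q.Cp


def gsconv_sc_ratio(c1: int) -> Fraction:
    """Exact GSConv/SC cost ratio ``(C1 + 1) / (2*C1)`` for ``C1`` input
    channels; independent of the spatial size and kernel."""
    if c1 <= 0:
        raise ValueError("C1 must be positive")
    return Fraction(c1 + 1, 2 * c1)


def gsconv_sc_ratio_limit() -> Fraction:
    """Limit of :func:`gsconv_sc_ratio` as the input width grows, computed
    symbolically: ``lim_{C1 -> inf} (C1 + 1)/(2 C1) = 1/2``."""
    import sympy

    c1 = sympy.Symbol("C1", positive=True)
    lim = sympy.limit((c1 + 1) / (2 * c1), c1, sympy.oo)
    return Fraction(int(sympy.fraction(lim)[0]), int(sympy.fraction(lim)[1]))


def pconv_sc_ratio(c: int, cp: int) -> Fraction:
    """Exact PConv/SC cost ratio ``(Cp/C)^2`` at equal kernel and C1=C2=C;
    equals 1/16 at the default partial ratio Cp = C/4."""
    if c <= 0 or cp <= 0 or cp > c:
        raise ValueError("need 0 < Cp <= C")
    return Fraction(cp * cp, c * c)
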