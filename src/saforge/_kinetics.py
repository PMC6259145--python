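"""Numerically stable exponential building blocks for first-order chains.

The closed forms of the yield equations are differences of exponentials
divided by rate differences.  Near coinciding rates those expressions have
removable singularities; the helpers below evaluate them through
``expm1``-based quotients and confluent-limit branches so that callers get
full relative accuracy without special-casing degenerate inputs.
"""

from __future__ import annotations

import numpy as np

# Branch switch on |rate difference| * t.  Below this the confluent
# (midpoint) formula is used; its truncation error is O(threshold^2)
# while the cancellation error of the general branch is O(eps/threshold).
_CONFLUENT_TOL = 1.0e-7

# Series branch for the integrated kernel when rate * t is this small.
_SERIES_TOL = 1.0e-4


def _asarray(t):
    arr = np.asarray(t, dtype=float)
    return arr, arr.ndim == 0


def e2(a: float, b: float, t) -> np.ndarray | float:
    """(exp(-a t) - exp(-b t)) / (b - a), stable for b -> a.

    This is the two-rate Bateman kernel: the time profile of a species fed
    at unit rate from a pool depleting at ``a`` while itself being removed
    at ``b``.
    """
    tt, scalar = _asarray(t)
    lo, hi = (a, b) if a <= b else (b, a)  # factor out the slower rate
    x = (hi - lo) * tt
    safe_x = np.where(x == 0.0, 1.0, x)
    g = np.where(x == 0.0, 1.0, -np.expm1(-safe_x) / safe_x)
    out = np.exp(-lo * tt) * tt * g
    return float(out) if scalar else out


def e3(a: float, b: float, c: float, t) -> np.ndarray | float:
    """Three-rate Bateman kernel: second divided difference of exp(-x t).

    Equals ``sum_k exp(-x_k t) / prod_{j != k} (x_j - x_k)`` for distinct
    rates; symmetric in (a, b, c); handles any coincident rates.
    """
    tt, scalar = _asarray(t)
    # order nodes so the closest pair is (a, b)
    nodes = sorted([a, b, c])
    gaps = [nodes[1] - nodes[0], nodes[2] - nodes[1]]
    if gaps[0] <= gaps[1]:
        a_, b_, c_ = nodes[0], nodes[1], nodes[2]
    else:
        a_, b_, c_ = nodes[1], nodes[2], nodes[0]
    m = 0.5 * (a_ + b_)
    x_ab = np.abs((b_ - a_) * tt)
    x_cm = np.abs((c_ - m) * tt)

    small_ab = x_ab < _CONFLUENT_TOL
    small_all = small_ab & (x_cm < _CONFLUENT_TOL)

    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        denom_ab = b_ - a_ if b_ != a_ else 1.0
        general = (np.asarray(e2(a_, c_, tt)) - np.asarray(e2(b_, c_, tt))) / denom_ab
        denom_cm = c_ - m if c_ != m else 1.0
        pair = (tt * np.exp(-m * tt) - np.asarray(e2(m, c_, tt))) / denom_cm
        m3 = (a_ + b_ + c_) / 3.0
        triple = 0.5 * tt * tt * np.exp(-m3 * tt)

    out = np.where(small_all, triple, np.where(small_ab, pair, general))
    out = np.where(np.asarray(tt) == 0.0, 0.0, out)
    return float(out) if scalar else out


def _one_minus_exp_over(x: float, t):
    """(1 - exp(-x t)) / x, with the x -> 0 limit t."""
    tt = np.asarray(t, dtype=float)
    if x == 0.0:
        return tt.copy()
    return -np.expm1(-x * tt) / x


def int_e2(a: float, b: float, t) -> np.ndarray | float:
    """Integral of :func:`e2` from 0 to t (accumulated kernel exposure)."""
    tt, scalar = _asarray(t)
    m = 0.5 * (a + b)
    x_ab = np.abs((b - a) * tt)
    small_ab = x_ab < _CONFLUENT_TOL

    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        denom = b - a if b != a else 1.0
        general = (_one_minus_exp_over(a, tt) - _one_minus_exp_over(b, tt)) / denom
        # confluent limit: integral of s * exp(-m s)
        xm = m * tt
        small_m = np.abs(xm) < _SERIES_TOL
        safe_m = m if m != 0.0 else 1.0
        closed = np.where(
            small_m,
            tt * tt * (0.5 - xm / 3.0 + xm * xm / 8.0 - xm**3 / 30.0),
            (-np.expm1(-xm) - xm * np.exp(-xm)) / (safe_m * safe_m),
        )
        if m == 0.0:
            closed = 0.5 * tt * tt

    out = np.where(small_ab, closed, general)
    return float(out) if scalar else out
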