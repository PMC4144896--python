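"""Shared statistical primitives."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np


def benjamini_hochberg(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * n / j, capped at 1, returned in the
    input order.  Monotone in p by construction.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


def percentage(numerator: float, denominator: float, decimals: int) -> float:
    """100 * numerator / denominator, rounded half-up to ``decimals`` places.

    Half-up (not banker's) rounding matches the arithmetic of printed
    report tables such as "86 (3.1%)" or "32% (i.e. 880 ... regions)".
    """
    if denominator == 0:
        raise ValueError("percentage: denominator must be non-zero")
    value = Decimal(numerator) * 100 / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))
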