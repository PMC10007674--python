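"""The discrete Choquet integral and reference baselines.

For scores ``x = (x_1, ..., x_n)`` in the unit hypercube and a fuzzy
measure ``m``, the discrete Choquet integral is

    C_m(x) = sum_{i=1..n} (x_(i) - x_(i-1)) * m(A_(i)),

where ``x_(1) <= ... <= x_(n)`` is the increasing sort of ``x``, with the
convention ``x_(0) = 0``, and ``A_(i)`` is the index set of the ``n-i+1``
largest components; for a symmetric measure ``m(A_(i))`` depends only on
that cardinality.  The integral is an idempotent, monotone aggregation
function whose value always lies between ``min(x)`` and ``max(x)``.

``choquet_oracle`` evaluates the algebraically equivalent weighted form
``sum_i x_(i) * (m(A_(i)) - m(A_(i+1)))`` with an independent sort and
accumulation; it exists purely as a cross-check and is never used on the
production path.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np

from .measures import CardinalityMeasure

__all__ = ["choquet", "choquet_oracle", "baseline_aggregate", "clamp_unit"]

#: scores may stray outside [0,1] by at most this much before it is an
#: error rather than softmax rounding noise
CLAMP_TOL = 1e-9

BASELINE_KINDS = ("mean", "min", "max")


def clamp_unit(
    x: np.ndarray, tol: float = CLAMP_TOL, clamp: bool = True
) -> np.ndarray:
    """Validate that ``x`` lies in [0,1], clamping violations within ``tol``.

    Rounding in exported softmax columns can produce values like
    ``1.0000000001``; those are clamped with a warning.  Violations larger
    than ``tol`` (or any violation when ``clamp`` is False) raise.
    """
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(initial=0.0), x.max(initial=1.0)
    if lo >= 0.0 and hi <= 1.0:
        return x
    worst = max(-lo, hi - 1.0)
    if not clamp or worst > tol:
        raise ValueError(
            f"score out of range [0,1] by {worst:.3g} (tolerance {tol:g})"
        )
    warnings.warn(
        f"clamping scores to [0,1] (worst violation {worst:.3g})",
        stacklevel=3,
    )
    return np.clip(x, 0.0, 1.0)


def choquet(
    x: Sequence[float] | np.ndarray,
    m: CardinalityMeasure,
    *,
    clamp: bool = True,
) -> float:
    """Discrete Choquet integral of ``x`` with respect to measure ``m``.

    Parameters
    ----------
    x
        Per-view scores for one class, each in [0, 1]; length must equal
        ``m.n``.
    m
        A validated :class:`~choqfuse.measures.CardinalityMeasure`.
    clamp
        Permit (and clip) components outside [0,1] by at most 1e-9.

    Returns
    -------
    float
        ``C_m(x)``, guaranteed inside ``[min(x), max(x)]``.
    """
    x = clamp_unit(np.asarray(x, dtype=float), clamp=clamp)
    if x.ndim != 1 or len(x) != m.n:
        raise ValueError(f"expected {m.n} scores, got shape {x.shape}")
    xs = np.sort(x, kind="stable")
    # m(A_(i)) for i = 1..n is values[n - i + 1], i.e. values[n], ..., values[1]
    weights = m.values[:0:-1]
    acc = 0.0
    prev = 0.0
    for i in range(m.n):  # fixed ascending accumulation: bit-reproducible
        acc += (xs[i] - prev) * weights[i]
        prev = xs[i]
    return acc


def choquet_oracle(
    x: Sequence[float] | np.ndarray, m: CardinalityMeasure
) -> float:
    """Independent re-derivation of the Choquet integral, for testing only.

    Uses the weighted-sum form ``sum_i x_(i) * (m(A_(i)) - m(A_(i+1)))``
    with ``m(A_(n+1)) = 0``, sorted and accumulated separately from
    :func:`choquet`.  Limited to small ``n``; intentionally naive.
    """
    x = clamp_unit(np.asarray(x, dtype=float))
    n = m.n
    if len(x) != n:
        raise ValueError(f"expected {n} scores, got {len(x)}")
    if n > 12:
        raise ValueError("oracle restricted to n <= 12")
    ordered = sorted(float(v) for v in x)
    total = 0.0
    for i in range(1, n + 1):
        m_ai = float(m.values[n - i + 1])
        m_next = float(m.values[n - i]) if i < n else 0.0
        total += ordered[i - 1] * (m_ai - m_next)
    return total


def baseline_aggregate(
    x: Sequence[float] | np.ndarray, kind: str
) -> float:
    """Arithmetic mean, minimum or maximum of the per-view scores."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot aggregate an empty score vector")
    clamp_unit(x)
    if kind == "mean":
        return float(np.mean(x))
    if kind == "min":
        return float(np.min(x))
    if kind == "max":
        return float(np.max(x))
    raise ValueError(
        f"unknown baseline kind {kind!r}; expected one of {BASELINE_KINDS}"
    )
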