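"""Symmetric (cardinality-based) fuzzy measures.

A fuzzy measure (capacity) on a set of ``n`` views is a monotone set
function ``m`` with ``m(emptyset) = 0`` and ``m(full set) = 1``.  The
measures used here are *symmetric*: the value of ``m(X)`` depends only on
the cardinality ``|X|``, so the whole measure is stored as an
``(n + 1)``-vector indexed by subset size.  The only family shipped is the
power measure ``m_q(X) = (|X| / n) ** q`` with ``q > 0``; at ``q = 1`` the
Choquet integral with respect to it reduces to the arithmetic mean, while
``q -> 0`` and ``q -> inf`` approach the maximum and minimum respectively.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "CardinalityMeasure",
    "MeasureValidationError",
    "power_measure",
    "validate_measure",
]


class MeasureValidationError(ValueError):
    """Raised when a candidate measure violates a capacity axiom."""


@dataclass(frozen=True)
class CardinalityMeasure:
    """A symmetric fuzzy measure stored by subset cardinality.

    Parameters
    ----------
    n
        Number of elements (views) being aggregated.
    values
        ``n + 1`` reals with ``values[k]`` the measure of any subset of
        cardinality ``k``.  Must satisfy ``values[0] == 0``,
        ``values[n] == 1``, monotone non-decreasing, all entries in [0, 1].
    label
        Free-text provenance, e.g. ``"power(q=1)"``.
    """

    n: int
    values: np.ndarray
    label: str = ""
    q: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=float)
        )
        self.values.setflags(write=False)

    def __getitem__(self, cardinality: int) -> float:
        return float(self.values[cardinality])

    def to_dict(self) -> dict:
        d = {"n": self.n, "values": self.values.tolist(), "label": self.label}
        if self.q is not None:
            d["q"] = self.q
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "CardinalityMeasure":
        m = cls(
            n=int(d["n"]),
            values=np.asarray(d["values"], dtype=float),
            label=str(d.get("label", "")),
            q=d.get("q"),
        )
        return validate_measure(m)

    @classmethod
    def from_json(cls, source: str | Path) -> "CardinalityMeasure":
        p = Path(source)
        text = p.read_text(encoding="utf-8") if p.exists() else str(source)
        return cls.from_dict(json.loads(text))


def power_measure(q: float, n: int) -> CardinalityMeasure:
    """Build the power measure ``m_q(X) = (|X| / n) ** q``.

    The endpoints ``values[0]`` and ``values[n]`` are set to exact 0 and 1
    rather than computed through the power, so the boundary axioms hold
    without floating-point drift.

    Parameters
    ----------
    q
        Exponent, strictly positive.  ``q = 1`` gives the uniform
        (mean-inducing) measure; larger ``q`` shifts the Choquet integral
        toward the minimum, smaller toward the maximum.
    n
        Number of views, at least 1.
    """
    if not np.isfinite(q) or q <= 0:
        raise ValueError(f"power measure requires q > 0, got q={q!r}")
    if n < 1:
        raise ValueError(f"power measure requires n >= 1, got n={n!r}")
    k = np.arange(n + 1, dtype=float)
    values = (k / n) ** float(q)
    values[0] = 0.0
    values[n] = 1.0
    return CardinalityMeasure(
        n=int(n), values=values, label=f"power(q={q:g})", q=float(q)
    )


def validate_measure(m: CardinalityMeasure) -> CardinalityMeasure:
    """Check the capacity axioms; return ``m`` unchanged if they hold.

    Raises
    ------
    MeasureValidationError
        Naming the violated property and the offending index.
    """
    v = np.asarray(m.values, dtype=float)
    if v.ndim != 1 or len(v) != m.n + 1:
        raise MeasureValidationError(
            f"expected {m.n + 1} cardinality values, got shape {v.shape}"
        )
    if v[0] != 0.0:
        raise MeasureValidationError(f"m(∅) ≠ 0 (values[0] = {v[0]!r})")
    if v[m.n] != 1.0:
        raise MeasureValidationError(f"m(N) ≠ 1 (values[{m.n}] = {v[m.n]!r})")
    bad = np.flatnonzero((v < 0.0) | (v > 1.0))
    if bad.size:
        k = int(bad[0])
        raise MeasureValidationError(
            f"measure value out of [0,1] at k={k}: {v[k]!r}"
        )
    drops = np.flatnonzero(np.diff(v) < 0.0)
    if drops.size:
        k = int(drops[0]) + 1
        raise MeasureValidationError(f"non-monotone at k={k}")
    return m
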