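"""Precision, recall and F-beta evaluation for multi-class decisions.

Per class ``c`` (one-vs-rest): ``Prec = TP / (TP + FP)``,
``Rec = TP / (TP + FN)`` and

    F_beta = (1 + beta^2) * Prec * Rec / (beta^2 * Prec + Rec),

reported for ``beta = 0.5`` (precision-weighted) and ``beta = 1`` (the
harmonic mean).  Summary values are macro-averaged: the unweighted mean
of the per-class metrics, so every disease class counts equally
regardless of prevalence.  The 0/0 cases that arise when a class is
never predicted (or never occurs) are defined as 0 and logged rather
than propagated as NaN.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import multilabel_confusion_matrix

__all__ = ["ConfusionCounts", "EvaluationReport", "confusion", "f_beta", "evaluate"]

log = logging.getLogger(__name__)

DEFAULT_BETAS = (0.5, 1.0)


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest TP/FP/FN tallies per class (TN is never needed)."""

    class_labels: tuple[str, ...]
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn"):
            arr = np.asarray(getattr(self, name), dtype=np.int64)
            if (arr < 0).any():
                raise ValueError(f"negative {name} count")
            object.__setattr__(self, name, arr)
            arr.setflags(write=False)
        object.__setattr__(self, "class_labels", tuple(self.class_labels))
        if int(self.tp.sum()) > self.n_samples:
            raise ValueError("total TP exceeds sample count")


def confusion(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    class_labels: Sequence[str],
) -> ConfusionCounts:
    """Tally one-vs-rest TP/FP/FN for every class."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError(
            f"{len(true_labels)} true vs {len(predicted_labels)} predicted labels"
        )
    if len(true_labels) == 0:
        raise ValueError("no samples to evaluate")
    known = set(class_labels)
    for name, labs in (("true", true_labels), ("predicted", predicted_labels)):
        unknown = sorted(set(labs) - known)
        if unknown:
            raise ValueError(f"unknown {name} label(s): {unknown}")
    mcm = multilabel_confusion_matrix(
        list(true_labels), list(predicted_labels), labels=list(class_labels)
    )
    return ConfusionCounts(
        class_labels=tuple(class_labels),
        tp=mcm[:, 1, 1],
        fp=mcm[:, 0, 1],
        fn=mcm[:, 1, 0],
        n_samples=len(true_labels),
    )


def f_beta(prec: float, rec: float, beta: float) -> float:
    """The F_beta combination of one precision/recall pair.

    Returns 0 when the denominator vanishes (``prec == rec == 0``), the
    same convention used throughout the report.
    """
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta!r}")
    b2 = beta * beta
    denom = b2 * prec + rec
    if denom == 0.0:
        return 0.0
    return (1.0 + b2) * prec * rec / denom


def _beta_col(beta: float) -> str:
    return f"F{beta:g}"


@dataclass(frozen=True)
class EvaluationReport:
    """Per-class and macro-averaged Prec / Rec / F_beta table."""

    per_class: pd.DataFrame  # index = class label; columns Prec, Rec, F...
    macro: dict[str, float]
    betas: tuple[float, ...]
    n_samples: int
    mode: str = ""
    q: float | None = None

    def to_frame(self) -> pd.DataFrame:
        """Per-class rows plus a trailing 'macro' row."""
        macro_row = pd.DataFrame([self.macro], index=["macro"])
        return pd.concat([self.per_class, macro_row])

    def to_csv(self, path: str | Path) -> None:
        prov = {"mode": self.mode, "q": self.q, "n_samples": self.n_samples,
                "averaging": "macro"}
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(f"# {json.dumps(prov, sort_keys=True)}\n")
            self.to_frame().rename_axis("class").to_csv(fh)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "mode": self.mode,
            "q": self.q,
            "n_samples": self.n_samples,
            "averaging": "macro",
            "macro": self.macro,
            "per_class": self.per_class.rename_axis("class")
            .reset_index()
            .to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text


def evaluate(
    counts: ConfusionCounts,
    betas: Iterable[float] = DEFAULT_BETAS,
    mode: str = "",
    q: float | None = None,
) -> EvaluationReport:
    """Turn confusion counts into per-class and macro Prec/Rec/F_beta.

    Macro averaging (unweighted over classes) is used for the summary
    row; the report labels the averaging mode explicitly.
    """
    betas = tuple(sorted(float(b) for b in betas))
    if any(b <= 0 for b in betas):
        raise ValueError("all beta values must be positive")
    tp = counts.tp.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(tp + counts.fp > 0, tp / (tp + counts.fp), 0.0)
        rec = np.where(tp + counts.fn > 0, tp / (tp + counts.fn), 0.0)
    n_zero = int(((tp + counts.fp) == 0).sum() + ((tp + counts.fn) == 0).sum())
    if n_zero:
        log.info("0/0 precision or recall in %d class slot(s); defined as 0", n_zero)
    cols = {"Prec": prec, "Rec": rec}
    for b in betas:
        b2 = b * b
        denom = b2 * prec + rec
        cols[_beta_col(b)] = np.where(
            denom > 0, (1 + b2) * prec * rec / np.where(denom > 0, denom, 1.0), 0.0
        )
    per_class = pd.DataFrame(cols, index=list(counts.class_labels))
    macro = {c: float(per_class[c].mean()) for c in per_class.columns}
    return EvaluationReport(
        per_class=per_class,
        macro=macro,
        betas=betas,
        n_samples=counts.n_samples,
        mode=mode,
        q=q,
    )
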