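"""Per-class Choquet fusion across views and the consensus decision.

Each capture of a plant is a C x K matrix of class-membership
probabilities: one softmax column per view (camera), one row per disease
class (the reference instance is 38 classes x 4 cameras).  Fusion sorts
each class's K view scores increasingly, applies the Choquet integral,
and the consensus class is the one with the maximum fused response.

Fused score vectors are *not* renormalised to sum to one: the Choquet
integral of softmax columns is generally not a distribution, and only the
ordering matters for the argmax decision.  A display-time renormalisation
helper is provided; it never affects decisions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .aggregation import BASELINE_KINDS, clamp_unit
from .measures import CardinalityMeasure

__all__ = [
    "ViewScoreMatrix",
    "FusedScores",
    "fuse_views",
    "select_class",
    "predict_batch",
    "read_matrices_csv",
    "write_matrices_csv",
    "predictions_to_frame",
    "write_predictions",
]

#: softmax columns are expected to sum to 1 within this tolerance
COLUMN_SUM_TOL = 1e-4

#: fused responses closer than this are treated as tied
TIE_TOL = 1e-12

FUSION_MODES = ("choquet", "mean", "min", "max")  # plus "single_view:<k>"


@dataclass(frozen=True)
class ViewScoreMatrix:
    """C x K per-view class-probability matrix for one capture.

    ``scores[c, k]`` is the probability of class ``c`` reported by view
    ``k``.  Columns are softmax outputs and should each sum to 1; with
    ``strict_columns=False`` a deviant column only warns (real softmax
    exports are rounded).
    """

    scores: np.ndarray
    class_labels: tuple[str, ...]
    view_ids: tuple[str, ...]
    capture_id: str = ""
    strict_columns: bool = field(default=True, compare=False)

    def __post_init__(self) -> None:
        scores = clamp_unit(np.asarray(self.scores, dtype=float))
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "class_labels", tuple(self.class_labels))
        object.__setattr__(self, "view_ids", tuple(self.view_ids))
        scores.setflags(write=False)
        C, K = scores.shape
        if C < 2:
            raise ValueError(f"C ≥ 2 required, got {C} classes")
        if K < 1:
            raise ValueError("at least one view required")
        if len(self.class_labels) != C or len(set(self.class_labels)) != C:
            raise ValueError("class_labels must be C distinct strings")
        if len(self.view_ids) != K or len(set(self.view_ids)) != K:
            raise ValueError("view_ids must be K distinct strings")
        colsums = scores.sum(axis=0)
        off = np.abs(colsums - 1.0)
        if (off > COLUMN_SUM_TOL).any():
            k = int(np.argmax(off))
            msg = (
                f"capture {self.capture_id!r}: column {self.view_ids[k]!r} "
                f"sums to {colsums[k]:.6f}, not 1 (tolerance {COLUMN_SUM_TOL:g})"
            )
            if self.strict_columns:
                raise ValueError(msg)
            warnings.warn(msg, stacklevel=3)

    @property
    def n_classes(self) -> int:
        return self.scores.shape[0]

    @property
    def n_views(self) -> int:
        return self.scores.shape[1]


@dataclass(frozen=True)
class FusedScores:
    """Fused per-class responses and the consensus decision for one capture."""

    fused: np.ndarray
    decided_class: int
    decided_label: str
    tie_broken: bool
    capture_id: str = ""

    def __post_init__(self) -> None:
        fused = np.asarray(self.fused, dtype=float)
        object.__setattr__(self, "fused", fused)
        fused.setflags(write=False)

    def renormalised(self) -> np.ndarray:
        """Display-only rescaling of the fused vector to sum to 1."""
        total = self.fused.sum()
        return self.fused / total if total > 0 else self.fused.copy()


def select_class(
    fused: Sequence[float] | np.ndarray,
    labels: Sequence[str] | None = None,
) -> tuple[int, str, bool]:
    """Maximum-response decision with a deterministic tie-break.

    Returns ``(index, label, tie_broken)``.  When several classes attain
    the maximum within ``TIE_TOL``, the lowest class index wins and
    ``tie_broken`` is set.
    """
    fused = np.asarray(fused, dtype=float)
    if fused.size == 0:
        raise ValueError("cannot select a class from an empty vector")
    top = float(fused.max())
    contenders = np.flatnonzero(fused >= top - TIE_TOL)
    idx = int(contenders[0])
    label = labels[idx] if labels is not None else str(idx)
    return idx, label, len(contenders) > 1


def _fuse_matrix(
    scores: np.ndarray, m: CardinalityMeasure, mode: str
) -> np.ndarray:
    """Aggregate each row of a C x K matrix to a length-C fused vector."""
    if mode == "choquet":
        xs = np.sort(scores, axis=1, kind="stable")
        diffs = np.diff(xs, axis=1, prepend=0.0)
        return diffs @ m.values[:0:-1]
    if mode == "mean":
        return scores.mean(axis=1)
    if mode == "min":
        return scores.min(axis=1)
    if mode == "max":
        return scores.max(axis=1)
    if mode.startswith("single_view:"):
        k = int(mode.split(":", 1)[1])
        if not 0 <= k < scores.shape[1]:
            raise ValueError(f"view index {k} out of range (K={scores.shape[1]})")
        return scores[:, k].copy()
    raise ValueError(
        f"unknown fusion mode {mode!r}; expected 'choquet', "
        f"'single_view:<k>' or one of {BASELINE_KINDS}"
    )


def fuse_views(mat: ViewScoreMatrix, m: CardinalityMeasure) -> FusedScores:
    """Choquet-fuse one capture's views and decide its class.

    Each class's K view scores are aggregated independently; the decision
    is the maximum fused response.  The fused vector is not renormalised.
    """
    if m.n != mat.n_views:
        raise ValueError(
            f"measure is over n={m.n} elements but matrix has K={mat.n_views} views"
        )
    fused = _fuse_matrix(mat.scores, m, "choquet")
    idx, label, tie = select_class(fused, mat.class_labels)
    return FusedScores(
        fused=fused,
        decided_class=idx,
        decided_label=label,
        tie_broken=tie,
        capture_id=mat.capture_id,
    )


def predict_batch(
    matrices: Sequence[ViewScoreMatrix],
    m: CardinalityMeasure,
    mode: str = "choquet",
) -> list[FusedScores]:
    """Apply one fusion mode to every capture in a batch.

    ``mode`` is ``"choquet"`` (requires ``m.n == K``), ``"mean"``,
    ``"min"``, ``"max"``, or ``"single_view:<k>"`` which reproduces the
    one-camera baseline by passing column ``k`` through unchanged.
    """
    if not matrices:
        return []
    labels = matrices[0].class_labels
    K = matrices[0].n_views
    out: list[FusedScores] = []
    for mat in matrices:
        if mat.class_labels != labels:
            raise ValueError(
                f"capture {mat.capture_id!r} has inconsistent class labels"
            )
        if mat.n_views != K:
            raise ValueError(
                f"capture {mat.capture_id!r} has K={mat.n_views}, expected {K}"
            )
        if mode == "choquet" and m.n != mat.n_views:
            raise ValueError(
                f"measure n={m.n} does not match K={mat.n_views}"
            )
        fused = _fuse_matrix(mat.scores, m, mode)
        idx, label, tie = select_class(fused, labels)
        out.append(
            FusedScores(fused, idx, label, tie, capture_id=mat.capture_id)
        )
    return out


# ---------------------------------------------------------------------------
# CSV / JSON I/O
#
# Long-format dialect: columns  capture_id, class, <view_id_1>, ... ;
# per-capture files drop the capture_id column (the stem names the capture).

def read_matrices_csv(
    path: str | Path, strict_columns: bool = True
) -> list[ViewScoreMatrix]:
    """Read score matrices from the long-format CSV dialect."""
    path = Path(path)
    df = pd.read_csv(path, comment="#", dtype={"class": str})
    if "class" not in df.columns:
        raise ValueError(f"{path}: missing required 'class' column")
    single = "capture_id" not in df.columns
    if single:
        df = df.assign(capture_id=path.stem)
    view_ids = [c for c in df.columns if c not in ("capture_id", "class")]
    if not view_ids:
        raise ValueError(f"{path}: no view columns found")
    matrices = []
    for cap_id, grp in df.groupby("capture_id", sort=False):
        matrices.append(
            ViewScoreMatrix(
                scores=grp[view_ids].to_numpy(dtype=float),
                class_labels=grp["class"].tolist(),
                view_ids=view_ids,
                capture_id=str(cap_id),
                strict_columns=strict_columns,
            )
        )
    return matrices


def write_matrices_csv(
    matrices: Iterable[ViewScoreMatrix],
    path: str | Path,
    header_comment: str | None = None,
) -> None:
    """Write score matrices in the long-format CSV dialect."""
    frames = []
    for mat in matrices:
        df = pd.DataFrame(mat.scores, columns=list(mat.view_ids))
        df.insert(0, "class", list(mat.class_labels))
        df.insert(0, "capture_id", mat.capture_id)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        out.to_csv(fh, index=False)


def predictions_to_frame(
    predictions: Sequence[FusedScores], class_labels: Sequence[str]
) -> pd.DataFrame:
    """Tabulate predictions: capture_id, decision, tie flag, fused scores."""
    rows = []
    for p in predictions:
        row: dict = {
            "capture_id": p.capture_id,
            "decided_label": p.decided_label,
            "tie_broken": p.tie_broken,
        }
        row.update(
            {f"score_{lab}": s for lab, s in zip(class_labels, p.fused)}
        )
        rows.append(row)
    return pd.DataFrame(rows)


def write_predictions(
    predictions: Sequence[FusedScores],
    class_labels: Sequence[str],
    path: str | Path,
    provenance: dict | None = None,
    fmt: str = "csv",
) -> None:
    """Write predictions as CSV (with a provenance comment) or JSON."""
    path = Path(path)
    if fmt == "csv":
        frame = predictions_to_frame(predictions, class_labels)
        with open(path, "w", encoding="utf-8", newline="") as fh:
            if provenance:
                fh.write(f"# {json.dumps(provenance, sort_keys=True)}\n")
            frame.to_csv(fh, index=False)
    elif fmt == "json":
        payload = {
            "provenance": provenance or {},
            "class_labels": list(class_labels),
            "predictions": [
                {
                    "capture_id": p.capture_id,
                    "decided_class": p.decided_class,
                    "decided_label": p.decided_label,
                    "tie_broken": p.tie_broken,
                    "fused": p.fused.tolist(),
                }
                for p in predictions
            ],
        }
        path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown prediction format {fmt!r}")
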