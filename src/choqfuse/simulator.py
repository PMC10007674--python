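"""Synthetic multi-view classifier outputs and the robustness experiment.

No images or networks are involved: the simulator emulates the *outputs*
of a per-view softmax classifier directly on the probability simplex.
For each capture a true disease class is drawn uniformly; each of the K
views then reports a Dirichlet-distributed probability column.  An
informative view has concentration ``alpha_noise`` on every class plus
``alpha_signal`` added to the true class; with probability ``p_corrupt``
a view is corrupted and drawn with no boost at all, modelling total loss
of class information (occlusion, background confusion).

Two named regimes set the defaults:

* ``clean``    — high signal, rare corruption (homogeneous-background
  lab imagery): ``alpha_signal = 20``, ``p_corrupt = 0.05``.
* ``degraded`` — weaker signal, frequent corruption (leaves composited
  onto grass, field-like clutter): ``alpha_signal = 8``,
  ``p_corrupt = 0.35``.

Per-capture random streams are spawned deterministically from the root
seed, so batches are bit-reproducible under any iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .consensus import ViewScoreMatrix, predict_batch, write_matrices_csv
from .measures import power_measure
from .metrics import DEFAULT_BETAS, confusion, evaluate

__all__ = [
    "REGIME_DEFAULTS",
    "SimulationConfig",
    "LabeledBatch",
    "simulate_batch",
    "run_experiment",
    "export_batch",
]

#: regime-specific generator defaults: (alpha_signal, p_corrupt)
REGIME_DEFAULTS = {
    "clean": {"alpha_signal": 20.0, "p_corrupt": 0.05},
    "degraded": {"alpha_signal": 8.0, "p_corrupt": 0.35},
}


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of the synthetic multi-view generator.

    ``alpha_signal`` and ``p_corrupt`` default by ``regime`` (see module
    docstring); pass explicit values to override.
    """

    n_captures: int = 100
    C: int = 38
    K: int = 4
    regime: str = "clean"
    alpha_signal: float | None = None
    alpha_noise: float = 1.0
    p_corrupt: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIME_DEFAULTS:
            raise ValueError(
                f"unknown regime {self.regime!r}; "
                f"expected one of {sorted(REGIME_DEFAULTS)}"
            )
        defaults = REGIME_DEFAULTS[self.regime]
        if self.alpha_signal is None:
            object.__setattr__(self, "alpha_signal", defaults["alpha_signal"])
        if self.p_corrupt is None:
            object.__setattr__(self, "p_corrupt", defaults["p_corrupt"])
        if self.C < 2:
            raise ValueError("C >= 2 required")
        if self.K < 1:
            raise ValueError("K >= 1 required")
        if self.n_captures < 1:
            raise ValueError("n_captures >= 1 required")
        if self.alpha_signal <= 0 or self.alpha_noise <= 0:
            raise ValueError("concentration parameters must be positive")
        if not 0.0 <= self.p_corrupt <= 1.0:
            raise ValueError("p_corrupt must lie in [0, 1]")

    @property
    def class_labels(self) -> tuple[str, ...]:
        return tuple(f"class_{c:02d}" for c in range(self.C))

    @property
    def view_ids(self) -> tuple[str, ...]:
        return tuple(f"cam{k}" for k in range(self.K))


@dataclass(frozen=True)
class LabeledBatch:
    """Simulated captures together with their ground-truth classes."""

    matrices: tuple[ViewScoreMatrix, ...]
    true_labels: tuple[str, ...]
    config: SimulationConfig

    def __post_init__(self) -> None:
        object.__setattr__(self, "matrices", tuple(self.matrices))
        object.__setattr__(self, "true_labels", tuple(self.true_labels))
        if len(self.matrices) != len(self.true_labels):
            raise ValueError("one true label per capture required")


def simulate_batch(cfg: SimulationConfig) -> LabeledBatch:
    """Draw a reproducible batch of multi-view softmax outputs.

    Each capture gets its own random stream spawned from ``cfg.seed``, so
    the batch is identical regardless of generation order.
    """
    labels = cfg.class_labels
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_captures)
    matrices: list[ViewScoreMatrix] = []
    truths: list[str] = []
    base = np.full(cfg.C, cfg.alpha_noise, dtype=float)
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        true_c = int(rng.integers(cfg.C))
        corrupted = rng.random(cfg.K) < cfg.p_corrupt
        cols = np.empty((cfg.C, cfg.K))
        for k in range(cfg.K):
            alpha = base.copy()
            if not corrupted[k]:
                alpha[true_c] += cfg.alpha_signal
            cols[:, k] = rng.dirichlet(alpha)
        matrices.append(
            ViewScoreMatrix(
                scores=cols,
                class_labels=labels,
                view_ids=cfg.view_ids,
                capture_id=f"capture_{i:05d}",
            )
        )
        truths.append(labels[true_c])
    return LabeledBatch(tuple(matrices), tuple(truths), cfg)


def _metric_row(batch: LabeledBatch, preds, mode: str, q, betas) -> dict:
    decided = [p.decided_label for p in preds]
    counts = confusion(batch.true_labels, decided, batch.config.class_labels)
    rep = evaluate(counts, betas=betas, mode=mode, q=q)
    row = {"mode": mode, "q": q, "accuracy": counts.tp.sum() / counts.n_samples}
    row.update(rep.macro)
    return row


def run_experiment(
    cfg: SimulationConfig,
    q_values: Iterable[float] = (1.0,),
    modes: Iterable[str] = ("choquet",),
    betas: Iterable[float] = DEFAULT_BETAS,
) -> pd.DataFrame:
    """Single-view vs fused comparison on one simulated batch.

    Simulates a batch under ``cfg``, evaluates every requested fusion
    mode (one row per ``q`` for Choquet) against the true labels, and
    always appends the K single-view baselines plus their unweighted
    average row ``single_view_mean`` — the one-camera protocol the fused
    modes are compared against.

    Returns a tidy frame with columns ``mode``, ``q``, ``accuracy``,
    ``Prec``, ``Rec`` and one ``F{beta}`` column per beta, all
    macro-averaged.
    """
    q_values = sorted(set(float(q) for q in q_values))
    modes = list(dict.fromkeys(modes))
    if not q_values or not modes:
        raise ValueError("q_values and modes must be non-empty")
    batch = simulate_batch(cfg)
    rows: list[dict] = []
    for mode in modes:
        if mode == "choquet":
            for q in q_values:
                m = power_measure(q, cfg.K)
                preds = predict_batch(batch.matrices, m, "choquet")
                rows.append(_metric_row(batch, preds, "choquet", q, betas))
        else:
            m = power_measure(1.0, cfg.K)
            preds = predict_batch(batch.matrices, m, mode)
            rows.append(_metric_row(batch, preds, mode, None, betas))
    # one-camera baselines: each view separately, then their average
    m1 = power_measure(1.0, cfg.K)
    view_rows = []
    for k in range(cfg.K):
        preds = predict_batch(batch.matrices, m1, f"single_view:{k}")
        view_rows.append(
            _metric_row(batch, preds, f"single_view:{k}", None, betas)
        )
    rows.extend(view_rows)
    metric_cols = [c for c in view_rows[0] if c not in ("mode", "q")]
    mean_row: dict = {"mode": "single_view_mean", "q": None}
    mean_row.update(
        {c: float(np.mean([r[c] for r in view_rows])) for c in metric_cols}
    )
    rows.append(mean_row)
    return pd.DataFrame(rows)


def export_batch(
    batch: LabeledBatch, out_dir: str | Path, prefix: str = "batch"
) -> tuple[Path, Path]:
    """Write a batch as the score-matrix CSV dialect plus a labels CSV.

    Returns ``(matrices_path, labels_path)``.  This makes the simulator a
    fixture generator for the fuse/evaluate pipeline.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = batch.config
    prov = (
        f"simulated: regime={cfg.regime} C={cfg.C} K={cfg.K} "
        f"n={cfg.n_captures} alpha_signal={cfg.alpha_signal:g} "
        f"alpha_noise={cfg.alpha_noise:g} p_corrupt={cfg.p_corrupt:g} "
        f"seed={cfg.seed}"
    )
    mat_path = out_dir / f"{prefix}_scores.csv"
    lab_path = out_dir / f"{prefix}_labels.csv"
    write_matrices_csv(batch.matrices, mat_path, header_comment=prov)
    labels = pd.DataFrame(
        {
            "capture_id": [m.capture_id for m in batch.matrices],
            "true_label": list(batch.true_labels),
        }
    )
    with open(lab_path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# {prov}\n")
        labels.to_csv(fh, index=False)
    return mat_path, lab_path
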