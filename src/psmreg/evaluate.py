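"""Target-decoy evaluation: labels, TPR/FPR, ROC curves, AUC, lambda sweeps.

A PSM is labeled a false positive when its peptide belongs to a decoy
protein, otherwise a true positive.  Curves use ">= threshold"
semantics: at threshold delta, TPR is the fraction of target PSMs with
score >= delta and FPR the analogous decoy fraction.  Counting is per
peptide-spectrum pair, not per unique peptide.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigError, ContractError
from .io import PSMRecord
from .regularize import rerank


@dataclass(frozen=True)
class EvalResult:
    """ROC evaluation of one score vector under target/decoy labels."""

    labels: np.ndarray  # True = target (true-positive class)
    roc: list[tuple[float, float]]  # (FPR, TPR), from (0,0) to (1,1)
    auc: float
    threshold_grid: np.ndarray

    @property
    def n_target(self) -> int:
        return int(np.sum(self.labels))

    @property
    def n_decoy(self) -> int:
        return int(np.sum(~self.labels))


def label_psms(
    records: Sequence[PSMRecord],
    decoy_pattern: str = "DECOY_",
    mixed_policy: str = "decoy",
) -> np.ndarray:
    """Boolean labels, True = target PSM.

    With the default ``mixed_policy="decoy"``, membership in any decoy
    protein makes the PSM a false positive, even if target proteins also
    contain the peptide.  ``mixed_policy="target"`` flips that for users
    of the more common target-wins convention.
    """
    if mixed_policy not in ("decoy", "target"):
        raise ConfigError(f"mixed_policy must be 'decoy' or 'target', got {mixed_policy!r}")
    pattern = re.compile(decoy_pattern)
    labels = np.empty(len(records), dtype=bool)
    for k, rec in enumerate(records):
        is_decoy = [bool(pattern.match(acc)) for acc in rec.proteins]
        if mixed_policy == "decoy":
            labels[k] = not any(is_decoy)
        else:
            labels[k] = not all(is_decoy)
    return labels


def _as_arrays(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ContractError(f"scores {scores.shape} and labels {labels.shape} must be equal-length vectors")
    return scores, labels


def tpr(scores, labels, delta: float) -> float:
    """Fraction of target PSMs scoring >= delta."""
    scores, labels = _as_arrays(scores, labels)
    n_target = int(np.sum(labels))
    if n_target == 0:
        raise ConfigError("TPR undefined: no target PSMs")
    return float(np.sum(scores[labels] >= delta)) / n_target


def fpr(scores, labels, delta: float) -> float:
    """Fraction of decoy PSMs scoring >= delta."""
    scores, labels = _as_arrays(scores, labels)
    n_decoy = int(np.sum(~labels))
    if n_decoy == 0:
        raise ConfigError("FPR undefined: no decoy PSMs")
    return float(np.sum(scores[~labels] >= delta)) / n_decoy


def roc_and_auc(scores, labels) -> EvalResult:
    """ROC curve over the descending unique scores, AUC by trapezoid.

    Tied scores collapse to one threshold (>= semantics).  The curve is
    augmented with (0, 0) and, via the lowest threshold, reaches (1, 1).
    """
    scores, labels = _as_arrays(scores, labels)
    if np.all(labels) or not np.any(labels):
        raise ConfigError("ROC needs both target and decoy PSMs")
    thresholds = np.unique(scores)[::-1]
    points = [(0.0, 0.0)]
    for delta in thresholds:
        points.append((fpr(scores, labels, delta), tpr(scores, labels, delta)))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    xs = np.array([p[0] for p in points])
    ys = np.array([p[1] for p in points])
    auc = float(np.trapezoid(ys, xs))
    return EvalResult(labels=labels, roc=points, auc=auc, threshold_grid=thresholds)


def lambda_sweep(
    records: Sequence[PSMRecord],
    lambdas: Sequence[float] | None = None,
    decoy_pattern: str = "DECOY_",
    **rerank_kwargs,
) -> list[tuple[float, float]]:
    """AUC of the regularized scores at each lambda in the grid.

    Default grid 0.1 .. 0.9 in steps of 0.1.  The graph does not depend
    on lambda, but ``rerank`` is run per value for simplicity; the work
    is dominated by the solves anyway.
    """
    if lambdas is None:
        lambdas = np.round(np.arange(0.1, 1.0, 0.1), 10)
    labels = label_psms(records, decoy_pattern=decoy_pattern)
    out = []
    for lam in lambdas:
        _, result = rerank(records, lambda_=float(lam), **rerank_kwargs)
        out.append((float(lam), roc_and_auc(result.Y, labels).auc))
    return out


def minmax_normalize(scores) -> np.ndarray:
    """Affine map of scores onto [0, 1]; a constant vector maps to 0.5.

    Used to put initial and regularized score distributions on a common
    axis for comparison.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ConfigError("cannot min-max normalize an empty vector")
    lo, hi = float(scores.min()), float(scores.max())
    if hi == lo:
        return np.full_like(scores, 0.5)
    return (scores - lo) / (hi - lo)


def write_roc_table(result: EvalResult, path: str | Path) -> None:
    """Write (threshold, TPR, FPR) rows plus a trailing summary comment."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("threshold\ttpr\tfpr\n")
        # roc[0] is the augmented (0,0) point with no finite threshold
        for delta, (x, y) in zip(result.threshold_grid, result.roc[1:]):
            fh.write(f"{delta:.17g}\t{y:.17g}\t{x:.17g}\n")
        fh.write(
            f"# AUC={result.auc:.6f}\tn_target={result.n_target}\tn_decoy={result.n_decoy}\n"
        )
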