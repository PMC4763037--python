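"""Recall-precision evaluation of ranked regulation confidences.

Evaluation is directed — the regulation of gene n from gene m and its
reverse are distinct — and self-regulations are removed from both the
prediction and the gold standard before counting.

The curve has one point per distinct confidence value: at threshold v the
predicted network contains every regulation with confidence >= v, so a block
of tied regulations always enters as a whole.  The area under the curve
(AURPC) integrates the best precision achieved at each recall level by the
trapezoidal rule over recall, extends the curve horizontally from the
smallest achieved recall down to recall 0, and assigns precision 0 beyond
the largest achieved recall when it falls short of 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .confidence import ConfidenceMatrix
from .networks import DirectedNetwork

__all__ = [
    "EvaluationResult",
    "confusion",
    "recall_precision_curve",
    "aurpc",
]


@dataclass(frozen=True)
class EvaluationResult:
    """Threshold sweep: per-threshold confusion counts and the AURPC."""

    thresholds: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    recall: np.ndarray
    precision: np.ndarray
    aurpc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "TP": self.tp,
                "FP": self.fp,
                "FN": self.fn,
                "recall": self.recall,
                "precision": self.precision,
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    def plot(self, ax=None):
        """Recall-precision curve plot; needs matplotlib."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.step(self.recall, self.precision, where="post")
        ax.set_xlabel("recall")
        ax.set_ylabel("precision")
        ax.set_xlim(0, 1)
        ax.set_ylim(0, 1.05)
        ax.set_title(f"AURPC = {self.aurpc:.4f}")
        return ax


def _strip_self(pairs: Iterable[tuple[str, str]]) -> set[tuple[str, str]]:
    return {(m, n) for m, n in pairs if m != n}


def confusion(
    predicted: Iterable[tuple[str, str]], truth: DirectedNetwork
) -> tuple[int, int, int]:
    """(TP, FP, FN) for a predicted set of (regulator, target) pairs.

    Directed comparison; self-regulations are dropped from both sides.
    """
    pred = _strip_self(predicted)
    true = _strip_self(truth.regulations)
    tp = len(pred & true)
    return tp, len(pred) - tp, len(true) - tp


def _scores_from_conf(conf: ConfidenceMatrix) -> dict[tuple[str, str], float]:
    out = {}
    n = conf.n_genes
    for ti in range(n):
        for mi in range(n):
            if ti != mi:
                out[(conf.genes[mi], conf.genes[ti])] = float(conf.combined[ti, mi])
    return out


def recall_precision_curve(
    conf: ConfidenceMatrix | Mapping[tuple[str, str], float],
    truth: DirectedNetwork,
) -> EvaluationResult:
    """Sweep the confidence threshold and compute the recall-precision curve.

    ``conf`` is either a :class:`ConfidenceMatrix` (its combined values are
    used) or a mapping from (regulator, target) to a score.  A gold standard
    without edges leaves recall undefined and is an error.
    """
    scores = (
        _scores_from_conf(conf)
        if isinstance(conf, ConfidenceMatrix)
        else {k: float(v) for k, v in conf.items() if k[0] != k[1]}
    )
    true = _strip_self(truth.regulations)
    if not true:
        raise ValueError("gold standard has no regulations; recall is undefined")
    n_true = len(true)

    pairs = sorted(scores.items(), key=lambda kv: -kv[1])
    values = np.array([v for _, v in pairs])
    is_tp = np.array([k in true for k, _ in pairs], dtype=np.int64)
    cum_tp = np.cumsum(is_tp)
    cum_pred = np.arange(1, len(pairs) + 1)
    # one point per distinct value: the last index of each tie block
    last_of_block = np.nonzero(np.r_[values[1:] != values[:-1], True])[0]
    thresholds = values[last_of_block]
    tp = cum_tp[last_of_block]
    fp = cum_pred[last_of_block] - tp
    fn = n_true - tp
    recall = tp / n_true
    with np.errstate(invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 1.0)
    area = aurpc(recall, precision)
    return EvaluationResult(
        thresholds=thresholds,
        tp=tp,
        fp=fp,
        fn=fn,
        recall=recall,
        precision=precision,
        aurpc=area,
    )


def aurpc(recall: np.ndarray | "EvaluationResult", precision: np.ndarray | None = None) -> float:
    """Area under the recall-precision curve.

    Accepts either an :class:`EvaluationResult` or (recall, precision)
    arrays.  At each distinct recall the best achieved precision is used;
    the curve is continued at constant precision from the smallest achieved
    recall to 0 and contributes nothing beyond the largest achieved recall.
    """
    if isinstance(recall, EvaluationResult):
        return recall.aurpc
    recall = np.asarray(recall, dtype=float)
    precision = np.asarray(precision, dtype=float)
    if recall.size == 0:
        raise ValueError("cannot integrate an empty curve")
    best: dict[float, float] = {}
    for r, p in zip(recall, precision):
        if r not in best or p > best[r]:
            best[r] = p
    rs = np.array(sorted(best))
    ps = np.array([best[r] for r in rs])
    area = rs[0] * ps[0]  # horizontal extension down to recall 0
    if len(rs) > 1:
        area += float(np.trapezoid(ps, rs))
    return float(area)
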