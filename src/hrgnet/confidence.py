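"""Combining bootstrap and hierarchy probabilities into regulation confidences.

The final confidence of the regulation of gene n from gene m is the affine
mixture

    p[n, m] = eta * pB[n, m] + (1 - eta) * pH[n, m],      0 <= eta <= 1,

where pB is the (directed) bootstrap probability and pH the (direction-blind)
hierarchy probability.  With the default eta = 1 - 1/N_g the hierarchy term
is strictly a tie-breaker: two regulations whose bootstrap probabilities
differ by at least 2/N_g can never swap order, because
eta * 2/N_g > (1 - eta) * 1 whenever N_g >= 3 (and the grid spacing makes the
boundary case harmless for N_g in {1, 2}).

Self-regulations are carried through with their bootstrap value only (the
hierarchy model is undefined on the diagonal) and are excluded from ranking
and evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .networks import DirectedNetwork

__all__ = ["ConfidenceMatrix", "combine", "default_eta", "rank_regulations"]


@dataclass(frozen=True)
class ConfidenceMatrix:
    """pB, pH, and their eta-mixture over ordered gene pairs.

    All matrices are indexed ``[target, regulator]``.  ``pH`` is symmetric
    with a NaN diagonal; ``combined`` carries ``pB`` on the diagonal, and the
    diagonal is flagged excluded everywhere downstream.
    """

    genes: tuple[str, ...]
    pB: np.ndarray
    pH: np.ndarray
    eta: float
    combined: np.ndarray

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def value(self, regulator: str, target: str) -> float:
        gi = {g: i for i, g in enumerate(self.genes)}
        return float(self.combined[gi[target], gi[regulator]])

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: regulator, target, pB, pH, combined, rank."""
        ranked = rank_regulations(self)
        gi = {g: i for i, g in enumerate(self.genes)}
        rows = []
        for rank, (m, n, p) in enumerate(ranked, start=1):
            rows.append(
                {
                    "regulator": m,
                    "target": n,
                    "pB": self.pB[gi[n], gi[m]],
                    "pH": self.pH[gi[n], gi[m]],
                    "combined": p,
                    "rank": rank,
                }
            )
        return pd.DataFrame(rows, columns=["regulator", "target", "pB", "pH", "combined", "rank"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")

    def threshold_network(self, threshold: float) -> DirectedNetwork:
        """Directed network of regulations whose combined confidence exceeds
        the threshold (strictly); self-regulations never appear."""
        regs = [
            (m, n)
            for m, n, p in rank_regulations(self)
            if p > threshold
        ]
        return DirectedNetwork(self.genes, regs)


def default_eta(ng: int) -> float:
    """The recommended mixing weight eta = 1 - 1/N_g."""
    if ng < 1:
        raise ValueError("ensemble size N_g must be >= 1")
    return 1.0 - 1.0 / ng


def combine(
    pB: np.ndarray | pd.DataFrame,
    pH: np.ndarray | pd.DataFrame,
    eta: float,
    genes: tuple[str, ...] | None = None,
) -> ConfidenceMatrix:
    """Elementwise mixture eta*pB + (1-eta)*pH over ordered pairs.

    Diagonal entries of the result carry pB alone.  Gene labels are taken
    from a DataFrame argument when not passed explicitly.
    """
    if not (0.0 <= eta <= 1.0):
        raise ValueError(f"eta must lie in [0, 1], got {eta}")
    for name, mat in (("pB", pB), ("pH", pH)):
        if isinstance(mat, pd.DataFrame):
            labels = tuple(str(g) for g in mat.index)
            if genes is None:
                genes = labels
            elif labels != tuple(genes):
                raise ValueError(f"{name} labels disagree with the gene list")
    pB = np.asarray(pB, dtype=float)
    pH = np.asarray(pH, dtype=float)
    if pB.shape != pH.shape or pB.ndim != 2 or pB.shape[0] != pB.shape[1]:
        raise ValueError("pB and pH must be square matrices of identical shape")
    n = pB.shape[0]
    if genes is None:
        genes = tuple(f"G{i + 1}" for i in range(n))
    genes = tuple(genes)
    if len(genes) != n:
        raise ValueError("gene list length does not match the matrices")
    off = ~np.eye(n, dtype=bool)
    if np.any((pB < 0) | (pB > 1)):
        raise ValueError("pB entries must lie in [0, 1]")
    if np.any((pH[off] < 0) | (pH[off] > 1)):
        raise ValueError("off-diagonal pH entries must lie in [0, 1]")
    if not np.allclose(np.where(off, pH, 0.0), np.where(off, pH.T, 0.0), equal_nan=True):
        raise ValueError("pH must be symmetric")
    pHc = pH.copy()
    np.fill_diagonal(pHc, np.nan)
    combined = eta * pB + (1.0 - eta) * pHc
    np.fill_diagonal(combined, np.diag(pB))
    return ConfidenceMatrix(genes=genes, pB=pB, pH=pHc, eta=float(eta), combined=combined)


def rank_regulations(conf: ConfidenceMatrix) -> list[tuple[str, str, float]]:
    """All off-diagonal regulations, best first.

    Sorted by combined confidence (descending); ties broken by pB
    (descending), then regulator label, then target label — a deterministic
    repo convention for the residual ties the mixture cannot split.
    """
    n = conf.n_genes
    items = []
    for ti in range(n):
        for mi in range(n):
            if ti == mi:
                continue
            items.append(
                (
                    -conf.combined[ti, mi],
                    -conf.pB[ti, mi],
                    conf.genes[mi],
                    conf.genes[ti],
                )
            )
    items.sort()
    return [(m, t, -negp) for negp, _negb, m, t in items]
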