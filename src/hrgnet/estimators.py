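"""scikit-learn-style estimators wrapping the model-fitting stages.

These expose the hierarchy fit (and the full confidence pipeline) through
the familiar ``fit`` / fitted-attribute / ``get_params`` interface so they
compose with sklearn tooling.  The input "X" is domain data — a
:class:`~hrgnet.networks.NetworkEnsemble` or a sequence of
:class:`~hrgnet.networks.DirectedNetwork` — rather than a feature matrix.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .anneal import AnnealSchedule
from .anneal import anneal as _run_anneal
from .confidence import ConfidenceMatrix, combine, default_eta, rank_regulations
from .hrg import HRGModel
from .networks import (
    DirectedNetwork,
    NetworkEnsemble,
    bootstrap_probabilities,
    build_ensemble,
)

__all__ = ["HierarchicalRandomGraph", "HierarchyConfidenceScorer"]


def _as_ensemble(X) -> tuple[NetworkEnsemble, Sequence[DirectedNetwork] | None]:
    if isinstance(X, NetworkEnsemble):
        return X, None
    if isinstance(X, Sequence) and X and isinstance(X[0], DirectedNetwork):
        return build_ensemble(X), X
    raise TypeError(
        "X must be a NetworkEnsemble or a non-empty sequence of DirectedNetwork"
    )


class HierarchicalRandomGraph(BaseEstimator):
    """Maximum-likelihood hierarchical random graph fit to a network ensemble.

    Parameters mirror the annealing schedule: initial/final temperature,
    geometric cooling factor, and the per-temperature proposal budget
    (``n_max`` or, when None, ``n_max_factor * N``).  ``restart_from_best``
    resets the current tree to the best tree at every temperature epoch (the
    printed algorithm's behavior).  ``incremental=False`` switches the
    objective to full recomputation per proposal (testing aid).

    Attributes (after ``fit``): ``model_`` (:class:`HRGModel`), ``tree_``,
    ``theta_``, ``log_likelihood_``, ``trace_``, ``genes_``.
    """

    def __init__(
        self,
        t_start: float = 1000.0,
        t_end: float = 0.1,
        gamma: float = 0.99,
        n_max_factor: int = 1000,
        n_max: int | None = None,
        restart_from_best: bool = True,
        incremental: bool = True,
        random_state: int | None = None,
    ):
        self.t_start = t_start
        self.t_end = t_end
        self.gamma = gamma
        self.n_max_factor = n_max_factor
        self.n_max = n_max
        self.restart_from_best = restart_from_best
        self.incremental = incremental
        self.random_state = random_state

    def _schedule(self) -> AnnealSchedule:
        return AnnealSchedule(
            t_start=self.t_start,
            t_end=self.t_end,
            gamma=self.gamma,
            n_max_factor=self.n_max_factor,
            n_max=self.n_max,
            seed=self.random_state,
        )

    def fit(self, X, y=None):
        ens, _ = _as_ensemble(X)
        model, trace = _run_anneal(
            ens,
            self._schedule(),
            restart_from_best=self.restart_from_best,
            incremental=self.incremental,
        )
        self.model_ = model
        self.tree_ = model.tree
        self.theta_ = model.theta
        self.trace_ = trace
        self.genes_ = model.genes
        self.log_likelihood_ = trace.obj_best[-1] if trace.obj_best else 0.0
        return self

    def edge_probabilities(self) -> np.ndarray:
        """Symmetric p^H matrix (NaN diagonal)."""
        self._check_fitted()
        return self.model_.edge_probability_matrix()

    def sample(self, rng: np.random.Generator | None = None):
        self._check_fitted()
        return self.model_.sample(rng)

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("this estimator has not been fitted yet")


class HierarchyConfidenceScorer(BaseEstimator):
    """Full confidence pipeline: bootstrap p^B + hierarchy p^H -> combined p.

    Fit on a sequence of directed networks (the bootstrap ensemble).  ``eta``
    defaults to 1 - 1/N_g at fit time.  The fitted ``confidence_`` holds the
    combined matrix; ``rank()`` returns regulations best-first.
    """

    def __init__(
        self,
        eta: float | None = None,
        t_start: float = 1000.0,
        t_end: float = 0.1,
        gamma: float = 0.99,
        n_max_factor: int = 1000,
        n_max: int | None = None,
        random_state: int | None = None,
    ):
        self.eta = eta
        self.t_start = t_start
        self.t_end = t_end
        self.gamma = gamma
        self.n_max_factor = n_max_factor
        self.n_max = n_max
        self.random_state = random_state

    def fit(self, X: Sequence[DirectedNetwork], y=None):
        if not (isinstance(X, Sequence) and X and isinstance(X[0], DirectedNetwork)):
            raise TypeError("X must be a non-empty sequence of DirectedNetwork")
        pB = bootstrap_probabilities(X)
        hrg = HierarchicalRandomGraph(
            t_start=self.t_start,
            t_end=self.t_end,
            gamma=self.gamma,
            n_max_factor=self.n_max_factor,
            n_max=self.n_max,
            random_state=self.random_state,
        ).fit(X)
        self.hrg_ = hrg
        self.model_: HRGModel = hrg.model_
        self.eta_ = default_eta(len(X)) if self.eta is None else float(self.eta)
        pH = hrg.edge_probabilities()
        self.confidence_: ConfidenceMatrix = combine(
            pB.to_numpy(), np.nan_to_num(pH, nan=0.0), self.eta_, genes=tuple(pB.index)
        )
        return self

    def rank(self) -> list[tuple[str, str, float]]:
        if not hasattr(self, "confidence_"):
            raise RuntimeError("this estimator has not been fitted yet")
        return rank_regulations(self.confidence_)
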