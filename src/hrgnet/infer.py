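"""Bootstrap inference of a network ensemble from time-series data.

The hierarchy-detection stage only needs *some* method that produces N_g
networks from resampled data.  This confidence-combination approach was
developed around BS-LPM, a bootstrap wrapper around a linear-programming
machine; that method is specified elsewhere and is not part of this
package.  The registry below
makes the stage pluggable, and ships one clearly labelled baseline:

``baseline_bootstrap_regression``
    Per bootstrap replicate, resample whole experiment sets with
    replacement, estimate each gene's time derivative by finite differences,
    and regress it on the log-transformed expression of all candidate
    regulators.  A regulation m -> n enters the replicate's network iff the
    standardized regression coefficient of regulator m exceeds a magnitude
    threshold.  The log transform linearizes the power-law production term
    of S-system-like kinetics near steady state; it is a pragmatic choice,
    not a claim about the data.

Bootstrap frequencies from any registered method lie on the 1/N_g grid and
are reproducible given the seed.  Results produced by the baseline are not
comparable to published BS-LPM numbers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np

from .networks import DirectedNetwork
from .ssystem import TimeSeriesSet

__all__ = [
    "PriorKnowledgeMask",
    "InferenceConfig",
    "infer_ensemble",
    "baseline_bootstrap_regression",
    "register_method",
    "registered_methods",
]


@dataclass(frozen=True)
class PriorKnowledgeMask:
    """Hard constraints on inferable regulations.

    ``forbidden`` pairs never appear in any inferred network; ``forced``
    pairs appear in every network.  Pairs are (regulator, target).
    """

    forbidden: frozenset[tuple[str, str]] = frozenset()
    forced: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "forbidden", frozenset(tuple(p) for p in self.forbidden))
        object.__setattr__(self, "forced", frozenset(tuple(p) for p in self.forced))
        overlap = self.forbidden & self.forced
        if overlap:
            raise ValueError(f"pairs cannot be both forbidden and forced: {sorted(overlap)}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PriorKnowledgeMask":
        """Read rows ``regulator<TAB>target<TAB>allow|forbid|force``."""
        forbidden, forced = set(), set()
        for raw in Path(path).read_text().splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3 or parts[2] not in {"allow", "forbid", "force"}:
                raise ValueError(f"{path}: malformed mask row {line!r}")
            pair = (parts[0], parts[1])
            if parts[2] == "forbid":
                forbidden.add(pair)
            elif parts[2] == "force":
                forced.add(pair)
        return cls(frozenset(forbidden), frozenset(forced))

    def apply(self, net: DirectedNetwork) -> DirectedNetwork:
        regs = (set(net.regulations) - self.forbidden) | self.forced
        return DirectedNetwork(net.genes, regs)


@dataclass(frozen=True)
class InferenceConfig:
    """Settings for the ensemble-inference stage.

    ``threshold`` is the magnitude cutoff on standardized regression
    coefficients used by the baseline method; ``resample_unit`` fixes what
    the bootstrap resamples (whole experiment sets, preserving within-set
    dynamics).
    """

    ng: int = 100
    method: str = "baseline_bootstrap_regression"
    threshold: float = 0.2
    resample_unit: str = "sets"
    seed: int | None = None

    def __post_init__(self):
        if self.ng < 1:
            raise ValueError("N_g must be >= 1")
        if self.resample_unit != "sets":
            raise ValueError("only resample_unit='sets' is supported")


_METHODS: dict[str, Callable] = {}


def register_method(name: str):
    """Decorator registering an inference method under ``name``.

    A method has signature ``f(data, config, mask) -> list[DirectedNetwork]``
    and must return exactly ``config.ng`` networks over the data's genes.
    """

    def wrap(fn: Callable) -> Callable:
        _METHODS[name] = fn
        return fn

    return wrap


def registered_methods() -> tuple[str, ...]:
    return tuple(sorted(_METHODS))


def infer_ensemble(
    data: TimeSeriesSet,
    config: InferenceConfig,
    mask: PriorKnowledgeMask | None = None,
) -> list[DirectedNetwork]:
    """Run the configured inference method and enforce the knowledge mask."""
    if data.n_sets < 1 or data.n_obs < 2:
        raise ValueError("time-series data must have at least one set of >= 2 timepoints")
    if config.method not in _METHODS:
        raise ValueError(
            f"unknown inference method {config.method!r}; "
            f"registered methods: {', '.join(registered_methods())}"
        )
    mask = mask or PriorKnowledgeMask()
    nets = _METHODS[config.method](data, config, mask)
    if len(nets) != config.ng:
        raise RuntimeError(
            f"method {config.method!r} returned {len(nets)} networks, expected {config.ng}"
        )
    return [mask.apply(net) for net in nets]


def _derivatives(values: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Finite-difference dX/dt per set: central inside, one-sided at ends."""
    return np.gradient(values, times, axis=1)


@register_method("baseline_bootstrap_regression")
def baseline_bootstrap_regression(
    data: TimeSeriesSet,
    config: InferenceConfig,
    mask: PriorKnowledgeMask | None = None,
) -> list[DirectedNetwork]:
    """Baseline bootstrap stage: set resampling + thresholded regression."""
    mask = mask or PriorKnowledgeMask()
    rng = np.random.default_rng(config.seed)
    genes = data.genes
    n = len(genes)
    idx = {g: i for i, g in enumerate(genes)}
    x = data.noisy  # (S, T, N)
    dxdt = _derivatives(x, data.times)
    logx = np.log(x)

    forbidden = np.zeros((n, n), dtype=bool)  # [target, regulator]
    for m, t in mask.forbidden:
        forbidden[idx[t], idx[m]] = True

    nets = []
    warned = False
    for _ in range(config.ng):
        sets = rng.integers(0, data.n_sets, size=data.n_sets)
        design = logx[sets].reshape(-1, n)  # (S*T, N)
        response = dxdt[sets].reshape(-1, n)
        mu = design.mean(axis=0)
        sd = design.std(axis=0)
        degenerate = sd < 1e-12
        if np.any(degenerate) and not warned:
            warnings.warn(
                "constant regressor(s) dropped from the bootstrap regression: "
                + ", ".join(genes[i] for i in np.nonzero(degenerate)[0]),
                stacklevel=2,
            )
            warned = True
        z = (design - mu) / np.where(degenerate, 1.0, sd)
        z[:, degenerate] = 0.0
        regs = []
        for t in range(n):
            candidates = np.nonzero(~forbidden[t] & ~degenerate)[0]
            if candidates.size == 0:
                continue
            y = response[:, t]
            y_sd = y.std()
            if y_sd < 1e-12:
                continue
            yz = (y - y.mean()) / y_sd
            coef, *_ = np.linalg.lstsq(z[:, candidates], yz, rcond=None)
            for m_local, beta in zip(candidates, coef):
                if abs(beta) > config.threshold:
                    regs.append((genes[m_local], genes[t]))
        nets.append(DirectedNetwork(genes, regs))
    return nets
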