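"""S-system dynamics and the synthetic time-series protocol.

The S-system is the power-law ODE model

    dX_n/dt = alpha_n * prod_m X_m^{g_{n,m}} - beta_n * prod_m X_m^{h_{n,m}}

with positive rate constants alpha, beta and kinetic-order matrices g
(production) and h (degradation).  A network topology maps onto the model by
sampling g_{n,m} for every regulation m -> n uniformly from
[-1, -0.5] u [0.5, 1] (sign and magnitude independent), leaving the rest of
g at zero; h is the identity (first-order auto-degradation) and
alpha = beta = 1.

The data-generation protocol simulates many experiment sets from random
initial conditions in [0, 2]^N, observes each on a short regular grid
(11 observations, 0.4 time units apart by default), and corrupts the
observations with multiplicative Gaussian measurement noise (10% by
default).  With S sets of T observations each gene contributes K = S * T
measurements.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy.integrate import solve_ivp

from .networks import DirectedNetwork

__all__ = [
    "SSystemModel",
    "TimeSeriesSet",
    "derivative",
    "simulate",
    "sample_model_from_topology",
    "generate_dataset",
    "save_dataset",
    "load_dataset",
    "SimulationError",
]

#: Initial states closer to zero than this are redrawn: negative kinetic
#: orders make the vector field singular at zero.
MIN_INITIAL_VALUE = 1e-3
#: Noisy observations are floored here so log transforms stay finite.
NOISE_FLOOR = 1e-6


class SimulationError(RuntimeError):
    """Raised when the ODE solver fails or the trajectory degenerates."""


@dataclass(frozen=True)
class SSystemModel:
    """Parameters (alpha, beta, g, h) of an N-gene S-system."""

    alpha: np.ndarray
    beta: np.ndarray
    g: np.ndarray
    h: np.ndarray
    genes: tuple[str, ...]

    def __init__(self, alpha, beta, g, h, genes=None):
        alpha = np.asarray(alpha, dtype=float)
        beta = np.asarray(beta, dtype=float)
        g = np.asarray(g, dtype=float)
        h = np.asarray(h, dtype=float)
        n = alpha.shape[0]
        if beta.shape != (n,) or g.shape != (n, n) or h.shape != (n, n):
            raise ValueError("inconsistent parameter dimensions")
        if np.any(alpha <= 0) or np.any(beta <= 0):
            raise ValueError("rate constants alpha and beta must be positive")
        if genes is None:
            genes = tuple(f"G{i + 1}" for i in range(n))
        genes = tuple(str(x) for x in genes)
        if len(genes) != n:
            raise ValueError("gene list length does not match parameters")
        for name, val in (("alpha", alpha), ("beta", beta), ("g", g), ("h", h), ("genes", genes)):
            object.__setattr__(self, name, val)

    @property
    def n_genes(self) -> int:
        return self.alpha.shape[0]

    def topology(self) -> DirectedNetwork:
        """Regulations implied by nonzero off-diagonal g entries."""
        regs = [
            (self.genes[m], self.genes[n])
            for n in range(self.n_genes)
            for m in range(self.n_genes)
            if n != m and self.g[n, m] != 0.0
        ]
        return DirectedNetwork(self.genes, regs)


def derivative(model: SSystemModel, x: np.ndarray) -> np.ndarray:
    """Right-hand side of the S-system at state x (must be positive)."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        bad = int(np.argmin(np.where(np.isfinite(x), x, -np.inf)))
        raise ValueError(
            f"state of gene {model.genes[bad]!r} is nonpositive or non-finite "
            f"({x[bad]!r}); the power law is undefined there"
        )
    logx = np.log(x)
    production = model.alpha * np.exp(model.g @ logx)
    degradation = model.beta * np.exp(model.h @ logx)
    return production - degradation


def simulate(
    model: SSystemModel,
    x0: np.ndarray,
    times: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """Integrate the model from x0, returning a (len(times), N) trajectory.

    Integration uses an adaptive explicit Runge-Kutta scheme.  Inside solver
    steps the state is clipped away from zero for evaluating the power laws;
    if the reported solution itself leaves the positive orthant or the solver
    fails, a :class:`SimulationError` with the solver diagnostic is raised.
    """
    x0 = np.asarray(x0, dtype=float)
    times = np.asarray(times, dtype=float)
    if np.any(x0 <= 0):
        raise ValueError("initial state must be positive")
    if times.ndim != 1 or len(times) < 1 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")

    def rhs(_t, x):
        xc = np.clip(x, 1e-12, None)
        logx = np.log(xc)
        return model.alpha * np.exp(model.g @ logx) - model.beta * np.exp(model.h @ logx)

    sol = solve_ivp(
        rhs,
        (times[0], times[-1]),
        x0,
        t_eval=times,
        method="RK45",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SimulationError(f"ODE solver failed: {sol.message}")
    traj = sol.y.T
    if not np.all(np.isfinite(traj)) or np.any(traj <= 0):
        raise SimulationError("trajectory left the positive orthant or blew up")
    return traj


def sample_model_from_topology(
    topology: DirectedNetwork, rng: np.random.Generator | None = None
) -> SSystemModel:
    """Random kinetics on a fixed topology.

    For every regulation m -> n, g[n, m] gets a uniform magnitude in
    [0.5, 1] with a uniform random sign; h is the identity and
    alpha = beta = 1.
    """
    rng = np.random.default_rng(rng)
    genes = topology.genes
    n = len(genes)
    idx = {g: i for i, g in enumerate(genes)}
    g = np.zeros((n, n))
    for m, t in sorted(topology.regulations):
        magnitude = rng.uniform(0.5, 1.0)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        g[idx[t], idx[m]] = sign * magnitude
    return SSystemModel(np.ones(n), np.ones(n), g, np.eye(n), genes)


@dataclass(frozen=True)
class TimeSeriesSet:
    """S experiment sets x T timepoints x N genes, clean and noisy."""

    times: np.ndarray
    clean: np.ndarray
    noisy: np.ndarray
    genes: tuple[str, ...]

    def __post_init__(self):
        s, t, n = self.clean.shape
        if self.noisy.shape != (s, t, n):
            raise ValueError("clean and noisy tensors must have the same shape")
        if self.times.shape != (t,):
            raise ValueError("times length must match the timepoint axis")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if len(self.genes) != n:
            raise ValueError("gene list length must match the gene axis")
        if not np.all(np.isfinite(self.clean)) or np.any(self.clean < 0):
            raise ValueError("clean values must be finite and nonnegative")

    @property
    def n_sets(self) -> int:
        return self.clean.shape[0]

    @property
    def n_obs(self) -> int:
        return self.clean.shape[1]

    @property
    def n_genes(self) -> int:
        return self.clean.shape[2]

    @property
    def k_measurements(self) -> int:
        """Measurements per gene: K = S * T."""
        return self.n_sets * self.n_obs


def generate_dataset(
    model: SSystemModel,
    n_sets: int = 100,
    n_obs: int = 11,
    dt: float = 0.4,
    noise_fraction: float = 0.1,
    rng: np.random.Generator | None = None,
    absolute_noise: bool = False,
) -> TimeSeriesSet:
    """Simulate the observation protocol on a model.

    Each set starts from X0 ~ Uniform[0, 2]^N and is observed at ``n_obs``
    points ``dt`` apart starting at t = 0.  An initial state is redrawn when
    any coordinate falls below ``MIN_INITIAL_VALUE`` (the power law is
    singular at zero) or when the trajectory it launches diverges within the
    observation window — unstable parameterizations admit no finite
    observations from that corner of state space.  If ``max_redraws``
    consecutive draws fail to integrate, the model itself is deemed unstable
    and the underlying :class:`SimulationError` propagates.

    Noise is multiplicative by default (observed = clean * (1 + eps),
    eps ~ N(0, noise_fraction^2)); with ``absolute_noise=True`` it is
    additive with sd ``noise_fraction``.  Noisy values are floored at
    ``NOISE_FLOOR``.
    """
    rng = np.random.default_rng(rng)
    n = model.n_genes
    times = np.arange(n_obs) * dt
    clean = np.empty((n_sets, n_obs, n))
    max_redraws = 20
    for s in range(n_sets):
        for attempt in range(max_redraws):
            x0 = rng.uniform(0.0, 2.0, size=n)
            if np.any(x0 < MIN_INITIAL_VALUE):
                continue
            try:
                clean[s] = simulate(model, x0, times)
                break
            except SimulationError:
                if attempt == max_redraws - 1:
                    raise
        else:
            raise SimulationError(
                f"no admissible initial state found in {max_redraws} draws"
            )
    eps = rng.normal(0.0, noise_fraction, size=clean.shape) if noise_fraction > 0 else 0.0
    noisy = clean + eps if absolute_noise else clean * (1.0 + eps)
    noisy = np.maximum(noisy, NOISE_FLOOR)
    return TimeSeriesSet(times=times, clean=clean, noisy=noisy, genes=model.genes)


# ---------------------------------------------------------------------------
# Dataset persistence: one TSV per set plus a YAML manifest.
# ---------------------------------------------------------------------------


def save_dataset(
    data: TimeSeriesSet,
    directory: str | Path,
    model: SSystemModel | None = None,
    seed: int | None = None,
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    header = "time\t" + "\t".join(data.genes)
    width = len(str(data.n_sets - 1))
    for s in range(data.n_sets):
        for kind, tensor in (("noisy", data.noisy), ("clean", data.clean)):
            lines = [header]
            for t in range(data.n_obs):
                row = "\t".join(format(v, ".8g") for v in tensor[s, t])
                lines.append(f"{data.times[t]:.8g}\t{row}")
            (directory / f"set_{s:0{width}d}.{kind}.tsv").write_text("\n".join(lines) + "\n")
    manifest: dict = {
        "genes": list(data.genes),
        "n_sets": data.n_sets,
        "n_obs": data.n_obs,
        "times": [float(t) for t in data.times],
        "seed": seed,
    }
    if model is not None:
        manifest["model"] = {
            "alpha": model.alpha.tolist(),
            "beta": model.beta.tolist(),
            "g": model.g.tolist(),
            "h": model.h.tolist(),
        }
    (directory / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))


def load_dataset(directory: str | Path) -> TimeSeriesSet:
    directory = Path(directory)
    manifest = yaml.safe_load((directory / "manifest.yaml").read_text())
    genes = tuple(manifest["genes"])
    times = np.asarray(manifest["times"], dtype=float)
    n_sets, n_obs = manifest["n_sets"], manifest["n_obs"]
    shape = (n_sets, n_obs, len(genes))
    clean = np.empty(shape)
    noisy = np.empty(shape)
    width = len(str(n_sets - 1))
    for s in range(n_sets):
        for kind, tensor in (("noisy", noisy), ("clean", clean)):
            path = directory / f"set_{s:0{width}d}.{kind}.tsv"
            table = np.loadtxt(path, delimiter="\t", skiprows=1)
            tensor[s] = table[:, 1:]
    return TimeSeriesSet(times=times, clean=clean, noisy=noisy, genes=genes)


def load_model(directory: str | Path) -> SSystemModel:
    manifest = yaml.safe_load((Path(directory) / "manifest.yaml").read_text())
    if "model" not in manifest:
        raise ValueError(f"{directory}: manifest carries no model parameters")
    m = manifest["model"]
    return SSystemModel(m["alpha"], m["beta"], m["g"], m["h"], tuple(manifest["genes"]))
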