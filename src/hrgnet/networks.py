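"""Directed/undirected gene networks, bootstrap ensembles, and their file formats.

Conventions
-----------
* A regulation is an ordered pair ``(regulator, target)``: "regulation of the
  target gene from the regulator gene".
* Probability/adjacency matrices are indexed ``[target, regulator]``: row *n*,
  column *m* holds the quantity attached to the regulation of gene *n* from
  gene *m*.  This matches the usual ``p[n, m]`` notation for "n regulated by m"
  and is deliberately the transpose of a row-regulator adjacency matrix.
* Gene identity is the string label; integer indices (positions in the shared
  gene list) are an internal detail.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DirectedNetwork",
    "UndirectedNetwork",
    "NetworkEnsemble",
    "undirect",
    "build_ensemble",
    "bootstrap_probabilities",
    "random_modular_topology",
    "read_edge_list",
    "write_edge_list",
    "read_adjacency",
    "write_adjacency",
    "read_gold_standard",
    "write_gold_standard",
    "read_ensemble",
    "write_ensemble",
]


def _check_genes(genes: Sequence[str]) -> tuple[str, ...]:
    genes = tuple(str(g) for g in genes)
    if len(set(genes)) != len(genes):
        raise ValueError("gene labels must be unique")
    if not genes:
        raise ValueError("gene list is empty")
    return genes


@dataclass(frozen=True)
class DirectedNetwork:
    """A directed regulation graph over a fixed, ordered gene list.

    ``regulations`` is a set of ordered pairs ``(regulator, target)``.
    Self-regulations are allowed here; they are stripped when the network is
    converted to its undirected form for hierarchy detection.
    """

    genes: tuple[str, ...]
    regulations: frozenset[tuple[str, str]]

    def __init__(self, genes: Sequence[str], regulations: Iterable[tuple[str, str]] = ()):
        genes = _check_genes(genes)
        gene_set = set(genes)
        regs = frozenset((str(m), str(n)) for m, n in regulations)
        for m, n in regs:
            if m not in gene_set or n not in gene_set:
                raise ValueError(f"regulation ({m!r} -> {n!r}) references unknown gene")
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "regulations", regs)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def has_regulation(self, regulator: str, target: str) -> bool:
        return (regulator, target) in self.regulations

    def adjacency(self) -> np.ndarray:
        """0/1 matrix ``A[target, regulator]``."""
        idx = {g: i for i, g in enumerate(self.genes)}
        a = np.zeros((self.n_genes, self.n_genes), dtype=np.int8)
        for m, n in self.regulations:
            a[idx[n], idx[m]] = 1
        return a


@dataclass(frozen=True)
class UndirectedNetwork:
    """An undirected interaction graph; no self-edges."""

    genes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]

    def __init__(self, genes: Sequence[str], edges: Iterable[tuple[str, str]] = ()):
        genes = _check_genes(genes)
        order = {g: i for i, g in enumerate(genes)}
        canon = set()
        for u, v in edges:
            u, v = str(u), str(v)
            if u not in order or v not in order:
                raise ValueError(f"edge ({u!r}, {v!r}) references unknown gene")
            if u == v:
                raise ValueError(f"self-edge on gene {u!r} is not allowed")
            canon.add((u, v) if order[u] < order[v] else (v, u))
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "edges", frozenset(canon))

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def has_edge(self, u: str, v: str) -> bool:
        order = {g: i for i, g in enumerate(self.genes)}
        key = (u, v) if order[u] < order[v] else (v, u)
        return key in self.edges


def undirect(net: DirectedNetwork) -> UndirectedNetwork:
    """Symmetrize a directed network and drop self-regulations.

    An edge {n, m} is present iff the directed network contains m->n, n->m,
    or both (n != m).
    """
    edges = {(m, n) for m, n in net.regulations if m != n}
    return UndirectedNetwork(net.genes, edges)


@dataclass(frozen=True)
class NetworkEnsemble:
    """N_g undirected networks over one shared gene list, with edge counts.

    ``weights[(u, v)]`` is the number of member networks containing the edge
    {u, v}; pairs are keyed in gene-list order.
    """

    genes: tuple[str, ...]
    networks: tuple[UndirectedNetwork, ...]
    weights: Mapping[tuple[str, str], int] = field(compare=False)

    def __init__(self, networks: Sequence[UndirectedNetwork]):
        if not networks:
            raise ValueError("ensemble needs at least one network")
        genes = networks[0].genes
        for i, net in enumerate(networks):
            if net.genes != genes:
                raise ValueError(f"network {i} has a different gene list than network 0")
        weights: dict[tuple[str, str], int] = {}
        for net in networks:
            for e in net.edges:
                weights[e] = weights.get(e, 0) + 1
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "networks", tuple(networks))
        object.__setattr__(self, "weights", weights)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_networks(self) -> int:
        return len(self.networks)

    def weight(self, u: str, v: str) -> int:
        order = {g: i for i, g in enumerate(self.genes)}
        key = (u, v) if order[u] < order[v] else (v, u)
        return self.weights.get(key, 0)

    def index_weights(self) -> dict[tuple[int, int], int]:
        """Weights keyed by (i, j) gene indices with i < j."""
        idx = {g: i for i, g in enumerate(self.genes)}
        return {(idx[u], idx[v]): w for (u, v), w in self.weights.items()}


def build_ensemble(nets: Sequence[DirectedNetwork]) -> NetworkEnsemble:
    """Symmetrize each directed network and aggregate into an ensemble."""
    if not nets:
        raise ValueError("cannot build an ensemble from zero networks")
    genes = nets[0].genes
    for i, net in enumerate(nets):
        if net.genes != genes:
            raise ValueError(f"network {i} has a different gene list than network 0")
    return NetworkEnsemble([undirect(net) for net in nets])


def bootstrap_probabilities(nets: Sequence[DirectedNetwork]) -> pd.DataFrame:
    """Per-regulation bootstrap confidence p^B.

    ``pB.loc[n, m]`` is the fraction of networks containing the regulation of
    gene *n* from gene *m*; all values lie on the grid {0, 1/N_g, ..., 1}.
    Diagonal entries (self-regulations) are computed here but are excluded
    from hierarchy detection, ranking, and evaluation downstream.
    """
    if not nets:
        raise ValueError("need at least one network to compute bootstrap probabilities")
    genes = nets[0].genes
    for i, net in enumerate(nets):
        if net.genes != genes:
            raise ValueError(f"network {i} has a different gene list than network 0")
    idx = {g: i for i, g in enumerate(genes)}
    counts = np.zeros((len(genes), len(genes)), dtype=float)
    for net in nets:
        for m, n in net.regulations:
            counts[idx[n], idx[m]] += 1.0
    counts /= len(nets)
    return pd.DataFrame(counts, index=list(genes), columns=list(genes))


def random_modular_topology(
    genes: Sequence[str] | int,
    n_modules: int = 2,
    p_within: float = 0.3,
    p_between: float = 0.05,
    rng: np.random.Generator | None = None,
) -> DirectedNetwork:
    """Random directed topology with module structure, DREAM-like in spirit.

    Genes are split into ``n_modules`` contiguous blocks; each ordered
    off-diagonal pair becomes a regulation with probability ``p_within``
    inside a block and ``p_between`` across blocks.  Self-regulations are
    never generated (degradation is modeled separately by the kinetics).
    """
    rng = np.random.default_rng(rng)
    if isinstance(genes, int):
        genes = [f"G{i + 1}" for i in range(genes)]
    genes = _check_genes(genes)
    n = len(genes)
    module = np.array([min(i * n_modules // n, n_modules - 1) for i in range(n)])
    regs = []
    for m in range(n):
        for t in range(n):
            if m == t:
                continue
            p = p_within if module[m] == module[t] else p_between
            if rng.random() < p:
                regs.append((genes[m], genes[t]))
    return DirectedNetwork(genes, regs)


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

_GENES_COMMENT = re.compile(r"^#\s*genes\s*:\s*(.*)$")


def _parse_lines(path: Path) -> tuple[list[str] | None, list[list[str]]]:
    """Split a whitespace/tab edge-list file into (declared genes, rows)."""
    declared = None
    rows = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        m = _GENES_COMMENT.match(line)
        if m:
            declared = m.group(1).split()
            continue
        if line.startswith("#"):
            continue
        rows.append(line.split())
    return declared, rows


def _looks_like_header(row: list[str]) -> bool:
    return {row[0].lower(), row[1].lower()} & {"regulator", "target", "source", "from", "to"} != set()


def read_edge_list(path: str | Path, genes: Sequence[str] | None = None) -> DirectedNetwork:
    """Read a directed TSV edge list: ``regulator<TAB>target[<TAB>weight]``.

    The gene universe is taken from, in order of precedence: the ``genes``
    argument, a ``# genes: ...`` comment line, or the labels seen on edges.
    A header row is detected and skipped.
    """
    declared, rows = _parse_lines(Path(path))
    if rows and len(rows[0]) >= 2 and _looks_like_header(rows[0]):
        rows = rows[1:]
    regs = []
    for row in rows:
        if len(row) < 2:
            raise ValueError(f"{path}: malformed edge-list row {row!r}")
        regs.append((row[0], row[1]))
    if genes is None:
        genes = declared
    if genes is None:
        seen: list[str] = []
        for m, n in regs:
            for g in (m, n):
                if g not in seen:
                    seen.append(g)
        genes = seen
    return DirectedNetwork(genes, regs)


def write_edge_list(net: DirectedNetwork, path: str | Path) -> None:
    lines = ["# genes: " + " ".join(net.genes)]
    for m, n in sorted(net.regulations):
        lines.append(f"{m}\t{n}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_adjacency(path: str | Path) -> DirectedNetwork:
    """Read a labeled adjacency matrix (row = target, column = regulator)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    genes = [str(g) for g in df.index]
    if [str(c) for c in df.columns] != genes:
        raise ValueError(f"{path}: adjacency row and column labels differ")
    regs = []
    arr = df.to_numpy()
    for ti, t in enumerate(genes):
        for mi, m in enumerate(genes):
            if arr[ti, mi]:
                regs.append((m, t))
    return DirectedNetwork(genes, regs)


def write_adjacency(net: DirectedNetwork, path: str | Path) -> None:
    df = pd.DataFrame(net.adjacency(), index=list(net.genes), columns=list(net.genes))
    df.to_csv(path, sep="\t")


def read_gold_standard(path: str | Path, genes: Sequence[str] | None = None) -> DirectedNetwork:
    """Read DREAM-style gold-standard triples ``regulator target {0,1}``.

    Rows flagged 0 declare known absences and contribute only gene labels.
    """
    declared, rows = _parse_lines(Path(path))
    regs = []
    seen: list[str] = []
    for row in rows:
        if len(row) < 2:
            raise ValueError(f"{path}: malformed gold-standard row {row!r}")
        m, n = row[0], row[1]
        present = True
        if len(row) >= 3:
            if row[2] not in {"0", "1"}:
                raise ValueError(f"{path}: gold-standard flag must be 0 or 1, got {row[2]!r}")
            present = row[2] == "1"
        for g in (m, n):
            if g not in seen:
                seen.append(g)
        if present:
            regs.append((m, n))
    if genes is None:
        genes = declared if declared is not None else seen
    return DirectedNetwork(genes, regs)


def write_gold_standard(net: DirectedNetwork, path: str | Path) -> None:
    lines = ["# genes: " + " ".join(net.genes)]
    for m, n in sorted(net.regulations):
        lines.append(f"{m}\t{n}\t1")
    Path(path).write_text("\n".join(lines) + "\n")


def write_ensemble(nets: Sequence[DirectedNetwork], path: str | Path) -> None:
    """Write an ensemble as one concatenated TSV with a network-index column."""
    if not nets:
        raise ValueError("cannot write an empty ensemble")
    lines = ["# genes: " + " ".join(nets[0].genes), "network\tregulator\ttarget"]
    for j, net in enumerate(nets):
        if net.genes != nets[0].genes:
            raise ValueError(f"network {j} has a different gene list than network 0")
        for m, n in sorted(net.regulations):
            lines.append(f"{j}\t{m}\t{n}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_ensemble(path: str | Path, genes: Sequence[str] | None = None) -> list[DirectedNetwork]:
    """Read an ensemble from a directory of edge lists or a concatenated TSV.

    A directory is read as sorted ``*.tsv`` member files.  A single file must
    carry a ``network`` index column as written by :func:`write_ensemble`;
    every index from 0 to the maximum is materialized, so trailing empty
    networks are preserved as long as the index appears.
    """
    p = Path(path)
    if p.is_dir():
        files = sorted(p.glob("*.tsv"))
        if not files:
            raise ValueError(f"{path}: no .tsv member files found")
        nets = [read_edge_list(f, genes=genes) for f in files]
        if genes is None:
            all_genes = nets[0].genes
            nets = [DirectedNetwork(all_genes, n.regulations) for n in nets]
        return nets
    declared, rows = _parse_lines(p)
    if rows and _looks_like_header(rows[0][1:3] if len(rows[0]) >= 3 else rows[0]):
        rows = rows[1:]
    by_net: dict[int, list[tuple[str, str]]] = {}
    for row in rows:
        if len(row) < 3:
            raise ValueError(f"{path}: ensemble rows need network, regulator, target; got {row!r}")
        by_net.setdefault(int(row[0]), []).append((row[1], row[2]))
    if genes is None:
        genes = declared
    if genes is None:
        seen: list[str] = []
        for regs in by_net.values():
            for m, n in regs:
                for g in (m, n):
                    if g not in seen:
                        seen.append(g)
        genes = seen
    n_nets = (max(by_net) + 1) if by_net else 0
    if n_nets == 0:
        raise ValueError(f"{path}: no networks found")
    return [DirectedNetwork(genes, by_net.get(j, [])) for j in range(n_nets)]
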