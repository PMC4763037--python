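"""The hierarchical random graph (HRG) model H(D, theta).

The model places the N genes at the leaves of a rooted binary dendrogram D
and attaches a probability ``theta_i`` to each of the N - 1 internal nodes.
An undirected network is generated by connecting each gene pair {u, v}
independently with probability ``theta`` at the pair's lowest common ancestor.

Given an ensemble of N_g networks over the same genes, the log-likelihood of
H(D, theta) is, per internal node i and network j,

    log L = sum_j sum_i [ E_ij log theta_i + (L_i R_i - E_ij) log(1 - theta_i) ]

with E_ij the number of edges of network j whose endpoints have node i as
their LCA and L_i, R_i the leaf counts of the node's two subtrees.  For a
fixed tree the maximizing theta has the closed form

    theta_i = sum_j E_ij / (N_g L_i R_i)

so the tree is the only free object during optimization; see
:mod:`hrgnet.anneal` for the search.  Likelihoods here are evaluated from the
aggregated counts E_i = sum_j E_ij, which is algebraically identical to the
double sum but costs O(N^2) instead of O(N^2 N_g).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .dendrogram import Dendrogram, _NO_NODE
from .networks import NetworkEnsemble, UndirectedNetwork

__all__ = [
    "subtree_leaf_counts",
    "edge_counts",
    "fit_theta",
    "log_likelihood",
    "HRGModel",
    "edge_probability",
    "sample_network",
    "to_newick",
    "from_newick",
]


def _check_gene_match(tree: Dendrogram, ens: NetworkEnsemble) -> None:
    if set(tree.genes) != set(ens.genes):
        raise ValueError("ensemble gene list does not match the dendrogram leaf set")


def subtree_leaf_counts(tree: Dendrogram) -> tuple[np.ndarray, np.ndarray]:
    """(L_i, R_i) leaf counts per internal node, indexed by node id.

    Entries for leaf ids are zero.  Always satisfies
    ``sum_i L_i * R_i = N (N - 1) / 2``: the internal nodes partition the
    unordered leaf pairs by their LCA.
    """
    below = tree.n_leaves_below()
    L = np.zeros(tree.n_nodes, dtype=np.int64)
    R = np.zeros(tree.n_nodes, dtype=np.int64)
    for node in tree.internal_nodes():
        L[node] = below[tree.left[node]]
        R[node] = below[tree.right[node]]
    return L, R


def edge_counts(
    tree: Dendrogram, ens: NetworkEnsemble, per_network: bool = False
) -> np.ndarray:
    """Aggregated ensemble edge counts E_i per internal node.

    E_i sums, over ensemble members, the edges whose endpoint pair has node i
    as its LCA.  With ``per_network=True`` returns instead an
    ``(N_g, 2N-1)`` array of the per-member counts E_ij.
    """
    _check_gene_match(tree, ens)
    gene_to_leaf = {g: i for i, g in enumerate(tree.genes)}
    depths = tree.depths()
    if per_network:
        out = np.zeros((ens.n_networks, tree.n_nodes), dtype=np.int64)
        for j, net in enumerate(ens.networks):
            for u, v in net.edges:
                node = tree.lca_index(gene_to_leaf[u], gene_to_leaf[v], depths)
                out[j, node] += 1
        return out
    out = np.zeros(tree.n_nodes, dtype=np.int64)
    for (u, v), w in ens.weights.items():
        node = tree.lca_index(gene_to_leaf[u], gene_to_leaf[v], depths)
        out[node] += w
    return out


def fit_theta(tree: Dendrogram, ens: NetworkEnsemble) -> np.ndarray:
    """Maximum-likelihood theta_i = E_i / (N_g L_i R_i), indexed by node id."""
    L, R = subtree_leaf_counts(tree)
    E = edge_counts(tree, ens)
    theta = np.zeros(tree.n_nodes, dtype=float)
    internal = np.arange(tree.n_leaves, tree.n_nodes)
    theta[internal] = E[internal] / (ens.n_networks * L[internal] * R[internal])
    return theta


def _xlogy(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """x * log(y) with the MLE convention 0 * log 0 := 0."""
    out = np.zeros_like(y, dtype=float)
    nz = x != 0
    out[nz] = x[nz] * np.log(y[nz])
    return out


def log_likelihood(tree: Dendrogram, ens: NetworkEnsemble) -> float:
    """Ensemble log-likelihood at the per-tree MLE theta.  Always <= 0."""
    L, R = subtree_leaf_counts(tree)
    E = edge_counts(tree, ens)
    internal = np.arange(tree.n_leaves, tree.n_nodes)
    total = ens.n_networks * L[internal] * R[internal]
    e = E[internal].astype(float)
    theta = e / total
    return float(np.sum(_xlogy(e, theta) + _xlogy(total - e, 1.0 - theta)))


def node_log_likelihood(e: float, total: float) -> float:
    """Contribution of one internal node with count e out of N_g*L*R = total."""
    theta = e / total
    out = 0.0
    if e > 0:
        out += e * np.log(theta)
    if total - e > 0:
        out += (total - e) * np.log(1.0 - theta)
    return out


@dataclass(frozen=True)
class HRGModel:
    """A fitted hierarchical random graph: dendrogram plus per-node theta.

    ``theta`` is indexed by internal node id (leaf entries are zero and
    meaningless).  ``leaf_counts`` caches (L_i, R_i).
    """

    tree: Dendrogram
    theta: np.ndarray
    leaf_counts: tuple[np.ndarray, np.ndarray] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        theta = np.asarray(self.theta, dtype=float)
        if theta.shape != (self.tree.n_nodes,):
            raise ValueError("theta must have one entry per tree node (2N-1)")
        internal = list(self.tree.internal_nodes())
        if np.any(theta[internal] < 0) or np.any(theta[internal] > 1):
            raise ValueError("theta entries must lie in [0, 1]")
        object.__setattr__(self, "theta", theta)
        if self.leaf_counts is None:
            object.__setattr__(self, "leaf_counts", subtree_leaf_counts(self.tree))
        L, R = self.leaf_counts
        n = self.tree.n_leaves
        if int(np.sum(L[internal] * R[internal])) != n * (n - 1) // 2:
            raise ValueError("leaf-count products do not partition the gene pairs")

    @classmethod
    def fit(cls, tree: Dendrogram, ens: NetworkEnsemble) -> "HRGModel":
        return cls(tree, fit_theta(tree, ens))

    @property
    def genes(self) -> tuple[str, ...]:
        return self.tree.genes

    def edge_probability(self, u: str, v: str) -> float:
        return edge_probability(self, u, v)

    def edge_probability_matrix(self) -> np.ndarray:
        """Symmetric N x N matrix of p^H; the diagonal is NaN (undefined)."""
        n = self.tree.n_leaves
        out = np.full((n, n), np.nan)
        for (i, j), node in self.tree.lca_map().items():
            out[i, j] = out[j, i] = self.theta[node]
        return out

    def sample(self, rng: np.random.Generator | None = None) -> UndirectedNetwork:
        return sample_network(self, rng)

    def expected_edge_count(self) -> float:
        L, R = self.leaf_counts
        internal = list(self.tree.internal_nodes())
        return float(np.sum(L[internal] * R[internal] * self.theta[internal]))


def edge_probability(model: HRGModel, u: str, v: str) -> float:
    """p^H(u, v): theta at the LCA of u and v.  Symmetric; u == v is an error."""
    if u == v:
        raise ValueError(f"hierarchy probability is undefined for self-regulation of {u!r}")
    tree = model.tree
    node = tree.lca_index(tree.gene_index(u), tree.gene_index(v))
    return float(model.theta[node])


def sample_network(model: HRGModel, rng: np.random.Generator | None = None) -> UndirectedNetwork:
    """Draw one network: each pair {u, v} is an edge w.p. theta at its LCA."""
    rng = np.random.default_rng(rng)
    tree = model.tree
    edges = []
    for (i, j), node in tree.lca_map().items():
        if rng.random() < model.theta[node]:
            edges.append((tree.genes[i], tree.genes[j]))
    return UndirectedNetwork(tree.genes, edges)


# ---------------------------------------------------------------------------
# Annotated Newick IO
# ---------------------------------------------------------------------------
# Internal nodes carry their theta as an NHX comment: (a,(b,c)[&&NHX:theta=x]).


def to_newick(model: HRGModel) -> str:
    """Serialize to Newick with per-internal-node ``theta`` NHX annotations."""
    tree = model.tree
    taxa = dendropy.TaxonNamespace()
    dnodes = {}
    for leaf in range(tree.n_leaves):
        nd = dendropy.Node(taxon=taxa.new_taxon(tree.genes[leaf]))
        dnodes[leaf] = nd
    for node in tree.postorder_internal():
        nd = dendropy.Node()
        nd.add_child(dnodes[int(tree.left[node])])
        nd.add_child(dnodes[int(tree.right[node])])
        nd.annotations.add_new("theta", format(float(model.theta[node]), ".12g"))
        dnodes[node] = nd
    dtree = dendropy.Tree(taxon_namespace=taxa, seed_node=dnodes[tree.root])
    return dtree.as_string(
        schema="newick",
        suppress_rooting=True,
        suppress_annotations=False,
        annotations_as_nhx=True,
        preserve_spaces=True,
    ).strip()


def from_newick(text: str) -> HRGModel:
    """Parse an annotated Newick string back into an :class:`HRGModel`.

    Raises ValueError (with the parser's line/column diagnostics) on
    malformed text, non-binary nodes, or missing theta annotations.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            extract_comment_metadata=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises schema-specific error types
        raise ValueError(f"malformed Newick: {exc}") from exc

    leaves = [nd for nd in dtree.leaf_node_iter()]
    genes = [nd.taxon.label for nd in leaves]
    n = len(genes)
    if n < 2:
        raise ValueError("Newick tree must have at least 2 leaves")
    total = 2 * n - 1
    parent = np.full(total, _NO_NODE, dtype=np.int64)
    left = np.full(total, _NO_NODE, dtype=np.int64)
    right = np.full(total, _NO_NODE, dtype=np.int64)
    theta = np.zeros(total, dtype=float)

    ids: dict[int, int] = {id(nd): i for i, nd in enumerate(leaves)}
    next_internal = n
    root = -1
    for nd in dtree.postorder_node_iter():
        if nd.is_leaf():
            continue
        children = nd.child_nodes()
        if len(children) != 2:
            raise ValueError(
                f"dendrograms are strictly binary; found a node with {len(children)} children"
            )
        me = next_internal
        next_internal += 1
        ids[id(nd)] = me
        l, r = ids[id(children[0])], ids[id(children[1])]
        left[me], right[me] = l, r
        parent[l] = parent[r] = me
        value = nd.annotations.get_value("theta")
        if value is None:
            raise ValueError("internal node is missing its theta annotation")
        theta[me] = float(value)
        if nd.parent_node is None:
            root = me
    if root < 0:
        raise ValueError("no root found in Newick tree")
    tree = Dendrogram(genes, parent, left, right, root)
    return HRGModel(tree, theta)


def write_newick(model: HRGModel, path: str | Path) -> None:
    Path(path).write_text(to_newick(model) + "\n")


def read_newick(path: str | Path) -> HRGModel:
    return from_newick(Path(path).read_text())
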