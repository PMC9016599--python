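"""Tree construction and nucleotide sequence simulation.

Trees are rooted binary dendropy trees, either fully balanced (complete
binary, taxon count a power of two) or fully imbalanced (caterpillar).
Branch lengths are equal within the internal and external classes and set so
that a target *stemminess* — the proportion of total tree length contributed
by internal branches — and a target mean branch length are met exactly.

Sequences evolve site-independently under Jukes–Cantor or GTR+Gamma: the
rate matrix is scaled to one expected substitution per site per unit branch
length at stationarity, per-branch transition probabilities come from the
spectral decomposition of the reversible rate matrix, continuous
Gamma(alpha, alpha) rate multipliers (mean 1) act on variable sites, and a
Bernoulli(p_invariant) mask fixes sites as constant before simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np

from .align import Alignment

__all__ = [
    "SubstModel",
    "SimConfig",
    "build_tree",
    "assign_branch_lengths",
    "sample_gtr_model",
    "evolve_sequences",
    "simulate_dataset",
    "taxon_labels",
]

#: Exchangeability parameter order for GTR: (AC, AG, AT, CG, CT, GT).
EXCH_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


@dataclass(frozen=True)
class SubstModel:
    """A nucleotide substitution model.

    ``kind`` is ``"JC"`` or ``"GTRG"``. For GTR+Gamma the six
    exchangeabilities follow the order AC, AG, AT, CG, CT, GT and the rate
    matrix is rescaled to unit mean rate at stationarity; ``gamma_shape`` is
    the shape (= inverse variance) of the mean-one rate multipliers.
    """

    kind: str
    base_freqs: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    exchangeabilities: np.ndarray | None = None
    gamma_shape: float | None = None
    p_invariant: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "base_freqs", np.asarray(self.base_freqs, dtype=float)
        )
        if self.base_freqs.shape != (4,) or abs(self.base_freqs.sum() - 1) > 1e-9:
            raise ValueError("base_freqs must be a 4-simplex")
        if (self.base_freqs <= 0).any():
            raise ValueError("base_freqs must be strictly positive")
        if self.exchangeabilities is not None:
            ex = np.asarray(self.exchangeabilities, dtype=float)
            if ex.shape != (6,) or (ex <= 0).any():
                raise ValueError("exchangeabilities must be 6 positive values")
            object.__setattr__(self, "exchangeabilities", ex)
        if not 0.0 <= self.p_invariant < 1.0 and self.p_invariant != 1.0:
            raise ValueError("p_invariant must lie in [0, 1]")

    @classmethod
    def jc(cls, p_invariant: float = 0.0) -> "SubstModel":
        return cls(kind="JC", p_invariant=p_invariant)

    def rate_matrix(self) -> np.ndarray:
        """Reversible rate matrix Q, scaled to unit mean rate."""
        pi = self.base_freqs
        if self.exchangeabilities is None:
            ex = np.ones(6)
        else:
            ex = self.exchangeabilities
        Q = np.zeros((4, 4))
        for rate, (i, j) in zip(ex, EXCH_PAIRS):
            Q[i, j] = rate * pi[j]
            Q[j, i] = rate * pi[i]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mean_rate = -np.dot(pi, np.diag(Q))
        return Q / mean_rate


@dataclass(frozen=True)
class SimConfig:
    """One simulation scenario: tree shape, branch lengths, model, seed."""

    n_taxa: int
    seq_len: int
    mean_branch_length: float
    stemminess_target: float
    balanced: bool
    model: SubstModel
    seed: int

    def __post_init__(self) -> None:
        if self.n_taxa < 4:
            raise ValueError("n_taxa must be >= 4")
        if self.seq_len < 1:
            raise ValueError("seq_len must be >= 1")
        if not 0.0 < self.stemminess_target < 1.0:
            raise ValueError("stemminess_target must lie in (0, 1)")


def taxon_labels(n_taxa: int) -> list[str]:
    return [f"t{i + 1}" for i in range(n_taxa)]


def _balanced_newick(labels: list[str]) -> str:
    if len(labels) == 1:
        return labels[0]
    half = len(labels) // 2
    return f"({_balanced_newick(labels[:half])},{_balanced_newick(labels[half:])})"


def _caterpillar_newick(labels: list[str]) -> str:
    nwk = f"({labels[0]},{labels[1]})"
    for lab in labels[2:]:
        nwk = f"({nwk},{lab})"
    return nwk


def build_tree(n_taxa: int, balanced: bool) -> dendropy.Tree:
    """Rooted binary tree topology: complete binary or caterpillar shape."""
    if n_taxa < 4:
        raise ValueError("n_taxa must be >= 4")
    labels = taxon_labels(n_taxa)
    if balanced:
        if n_taxa & (n_taxa - 1):
            raise ValueError("balanced trees require a power-of-two taxon count")
        nwk = _balanced_newick(labels)
    else:
        nwk = _caterpillar_newick(labels)
    tns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree.get(
        data=nwk + ";", schema="newick", taxon_namespace=tns
    )
    tree.is_rooted = True
    return tree


def _classified_edges(tree: dendropy.Tree):
    """(internal_edges, external_edges), excluding the root's own edge."""
    internal, external = [], []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        (external if node.is_leaf() else internal).append(node.edge)
    return internal, external


def assign_branch_lengths(
    tree: dendropy.Tree, mean_branch_length: float, stemminess_target: float
) -> dendropy.Tree:
    """Set equal within-class branch lengths hitting both targets exactly.

    With B branches in total, the tree length is ``mean_branch_length * B``;
    a fraction ``stemminess_target`` of it is split evenly among internal
    branches and the rest among external branches. The tree is modified in
    place and returned.
    """
    if not 0.0 < stemminess_target < 1.0:
        raise ValueError("stemminess_target must lie in (0, 1)")
    internal, external = _classified_edges(tree)
    if not internal:
        raise ValueError("tree has no internal branches")
    B = len(internal) + len(external)
    total = mean_branch_length * B
    for e in internal:
        e.length = stemminess_target * total / len(internal)
    for e in external:
        e.length = (1.0 - stemminess_target) * total / len(external)
    return tree


def sample_gtr_model(
    seed=None, base_freqs=None, gamma_shape: float = 1.0, p_invariant: float = 0.0
) -> SubstModel:
    """Draw a GTR+Gamma model: exchangeabilities ~ Dirichlet(5, ..., 5).

    ``seed`` may be an integer or a ``numpy.random.Generator``. Base
    frequencies default to uniform; the gamma shape defaults to 1.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ex = rng.dirichlet(np.full(6, 5.0))
    if base_freqs is None:
        base_freqs = np.full(4, 0.25)
    return SubstModel(
        kind="GTRG",
        base_freqs=base_freqs,
        exchangeabilities=ex,
        gamma_shape=gamma_shape,
        p_invariant=p_invariant,
    )


def _spectral(Q: np.ndarray, pi: np.ndarray):
    """Symmetrised eigendecomposition of a reversible Q; returns (w, A, Ainv)
    with Q = A diag(w) Ainv."""
    sq = np.sqrt(pi)
    S = (Q * sq[None, :]) / sq[:, None]
    S = 0.5 * (S + S.T)  # exact symmetry against round-off
    w, V = np.linalg.eigh(S)
    A = (1.0 / sq)[:, None] * V
    Ainv = V.T * sq[None, :]
    return w, A, Ainv


def evolve_sequences(
    tree: dendropy.Tree,
    seq_len: int,
    model: SubstModel,
    seed=None,
    rng: np.random.Generator | None = None,
) -> Alignment:
    """Simulate a nucleotide alignment along ``tree`` under ``model``.

    Root states are iid draws from the model base frequencies; along each
    branch of length t the per-site transition matrix is ``expm(Q t r)``
    with r the site's rate multiplier. Sites selected by the invariant-site
    mask never change. Fully reproducible given ``seed`` (or an explicit
    generator).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    pi = model.base_freqs
    Q = model.rate_matrix()
    w, A, Ainv = _spectral(Q, pi)

    invariant = rng.random(seq_len) < model.p_invariant
    var_idx = np.nonzero(~invariant)[0]
    n_var = var_idx.size
    rates = np.ones(n_var)
    if model.gamma_shape is not None and n_var:
        a = float(model.gamma_shape)
        rates = rng.gamma(shape=a, scale=1.0 / a, size=n_var)

    root_states = rng.choice(4, size=seq_len, p=pi)
    states = {id(tree.seed_node): root_states}
    arange = np.arange(n_var)
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        t = node.edge.length or 0.0
        if t < 0:
            raise ValueError("negative branch length")
        parent = states[id(node.parent_node)]
        child = parent.copy()
        if t > 0 and n_var:
            expw = np.exp(np.outer(rates * t, w))  # (n_var, 4)
            # per-site transition matrices: M[s] = A diag(expw[s]) Ainv
            M = np.einsum("ik,sk,kj->sij", A, expw, Ainv)
            rows = M[arange, parent[var_idx], :]
            rows = np.clip(rows, 0.0, None)
            rows /= rows.sum(axis=1, keepdims=True)
            u = rng.random(n_var)
            child[var_idx] = (np.cumsum(rows, axis=1) < u[:, None]).sum(axis=1)
        states[id(node)] = child
        if not node.is_leaf():
            continue

    labels = [t.label for t in tree.taxon_namespace]
    matrix = np.zeros((len(labels), seq_len), dtype=np.uint8)
    by_label = {
        leaf.taxon.label: states[id(leaf)] for leaf in tree.leaf_node_iter()
    }
    for i, lab in enumerate(labels):
        matrix[i] = by_label[lab]
    return Alignment(tuple(labels), matrix)


def simulate_dataset(config: SimConfig) -> tuple[dendropy.Tree, Alignment]:
    """Build the true tree and simulate one alignment; deterministic by seed."""
    tree = build_tree(config.n_taxa, config.balanced)
    assign_branch_lengths(
        tree, config.mean_branch_length, config.stemminess_target
    )
    aln = evolve_sequences(tree, config.seq_len, config.model, seed=config.seed)
    return tree, aln
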