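"""Sequence simulation along phylogenies.

Root states are drawn from the model's equilibrium frequencies, and each
branch evolves states by the transition matrix of the normalized
generator at its effective length (branch length times the site's rate
category).  Site categories — invariable or one of the discrete-Gamma
classes — are assigned per site up front and recorded, so simulated data
match the likelihood engine's "+I+G" mixture exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .alignment import ProteinAlignment
from .alphabet import AMINO_ACIDS, N_STATES
from .likelihood import NO_HETEROGENEITY, ModelEigen, RateHeterogeneity
from .models import SubstitutionModel, build_rate_matrix
from .trees import random_tree


@dataclass
class SimulationSpec:
    """What to simulate: model, tree (given or generated), sites, rates."""

    model: SubstitutionModel
    n_sites: int
    tree: dendropy.Tree | None = None
    n_taxa: int | None = None
    tree_process: str = "yule"
    brlen_mean: float = 0.1
    het: RateHeterogeneity = field(default_factory=RateHeterogeneity)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be at least 1")
        if self.tree is None and self.n_taxa is None:
            raise ValueError("give either a tree or n_taxa")


@dataclass
class SimulationResult:
    alignment: ProteinAlignment
    tree: dendropy.Tree
    site_rates: np.ndarray  # realized rate multiplier per site (0 = invariable)


def _sample_transitions(
    parent_states: np.ndarray, P: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    cum = P.cumsum(axis=1)
    cum[:, -1] = 1.0
    u = rng.random(parent_states.size)
    return (u[:, None] > cum[parent_states]).sum(axis=1)


def simulate_alignment(spec: SimulationSpec) -> SimulationResult:
    """Evolve an alignment down a tree under a substitution model."""
    rng = np.random.default_rng(spec.seed)
    tree = spec.tree
    if tree is None:
        tree = random_tree(
            spec.n_taxa, process=spec.tree_process, rng=rng,
            brlen_mean=spec.brlen_mean,
        )
    eigen = ModelEigen(build_rate_matrix(spec.model))

    rates, weights = spec.het.variable_categories()
    all_rates = np.concatenate([[0.0], rates]) if spec.het.p_inv > 0 else rates
    all_weights = (
        np.concatenate([[spec.het.p_inv], weights]) if spec.het.p_inv > 0 else weights
    )
    cat = rng.choice(len(all_rates), size=spec.n_sites, p=all_weights / all_weights.sum())
    site_rates = all_rates[cat]

    states: dict[dendropy.Node, np.ndarray] = {}
    root = tree.seed_node
    states[root] = rng.choice(N_STATES, size=spec.n_sites, p=eigen.pi)
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        parent = states[node.parent_node]
        child = parent.copy()
        t = node.edge.length or 0.0
        for r in np.unique(site_rates):
            if r == 0.0:
                continue
            mask = site_rates == r
            if t > 0:
                P = eigen.transition_matrix(t * r)
                child[mask] = _sample_transitions(parent[mask], P, rng)
        states[node] = child

    taxa, rows = [], []
    for leaf in tree.leaf_node_iter():
        taxa.append(leaf.taxon.label)
        rows.append([AMINO_ACIDS[s] for s in states[leaf]])
    aln = ProteinAlignment(taxa, np.array(rows, dtype="U1"))
    return SimulationResult(aln, tree, site_rates)


def simulate_tree(
    n_taxa: int,
    process: str = "yule",
    brlen_mean: float = 0.1,
    seed: int | None = None,
) -> dendropy.Tree:
    """Random binary tree; see :func:`aamodel.trees.random_tree`."""
    return random_tree(n_taxa, process=process, seed=seed, brlen_mean=brlen_mean)
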