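"""Iterative maximum-likelihood estimation of an empirical substitution
model from protein alignments.

The procedure mirrors the estimation pipelines used to build empirical
mitochondrial models: the taxa of a large training alignment are split
into sub-datasets of bounded size (either at random or by extracting
clades from a guide tree), each sub-dataset gets a phylogeny optimized
under the current model, and a new exchangeability matrix is then fitted
by expectation-maximization with the trees held fixed.  The loop repeats
until the per-site AIC gain of an iteration falls below a threshold.

Equilibrium frequencies are estimated by counting observed residues (the
usual "+F" convention); the EM update for the exchangeabilities uses
expected substitution counts ``N_xy`` and dwell times ``T_x`` computed
per branch from spectral integrals of the current generator:

    r'_xy  proportional to  (N_xy + N_yx) / (pi_y T_x + pi_x T_y)

which is the exact M-step for the reversible parameterization
``q_xy = r_xy pi_y`` with fixed frequencies, so the total log-likelihood
is non-decreasing over inner EM iterations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np

from .alignment import ProteinAlignment
from .alphabet import AMINO_ACIDS, N_STATES
from .models import (
    N_FREE_PARAMS,
    SubstitutionModel,
    build_rate_matrix,
)
from .likelihood import (
    NO_HETEROGENEITY,
    RateHeterogeneity,
    TreeLikelihood,
    ml_distances,
    nni_search,
    optimize_rate_heterogeneity,
)
from .registry import get_model
from .trees import leaf_labels, neighbor_joining

logger = logging.getLogger(__name__)

#: AIC penalty for the 208 free parameters of a full empirical model
FULL_MODEL_PENALTY = 2 * N_FREE_PARAMS


class AICGain(tuple):
    """(total AIC gain, per-site AIC gain)."""

    def __new__(cls, gain: float, per_site: float):
        return super().__new__(cls, (gain, per_site))

    @property
    def gain(self) -> float:
        return self[0]

    @property
    def per_site(self) -> float:
        return self[1]


def aic_gain(delta_ll: float, extra_params: int = N_FREE_PARAMS, n_sites: int = 1) -> AICGain:
    """AIC gain of a richer model: twice the LL gain minus 2 x extra params.

    The penalty is divided equally over the alignment sites for the
    per-site figure.
    """
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    gain = 2.0 * delta_ll - 2.0 * extra_params
    return AICGain(gain, gain / n_sites)


# ---------------------------------------------------------------------------
# Dataset splitting


def random_split(
    taxa: Sequence[str], k: int, seed: int | None = None
) -> list[list[str]]:
    """Shuffle taxa and cut into chunks of at most k.

    A trailing chunk smaller than 4 is merged backward into its
    predecessor (which may then exceed k; at least 4 taxa per subset is
    the binding constraint).
    """
    if k < 4:
        raise ValueError("k must be at least 4")
    taxa = list(taxa)
    if len(taxa) < 4:
        raise ValueError("need at least 4 taxa to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(taxa))
    shuffled = [taxa[i] for i in order]
    chunks = [shuffled[i:i + k] for i in range(0, len(shuffled), k)]
    if len(chunks) > 1 and len(chunks[-1]) < 4:
        chunks[-2].extend(chunks.pop())
    return chunks


def tree_based_split(tree: dendropy.Tree, k: int) -> list[list[str]]:
    """Partition leaves by greedy extraction of the largest clade of size
    in [4, k]; leftover leaves form a final subset (merged backward if
    smaller than 4).

    Every subset except possibly the leftover one is monophyletic in the
    input tree.
    """
    if k < 4:
        raise ValueError("k must be at least 4")
    labels = leaf_labels(tree)
    if len(labels) < 4:
        raise ValueError("need at least 4 leaves")
    below: dict[dendropy.Node, frozenset[str]] = {}
    clades: list[frozenset[str]] = []
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset({node.taxon.label})
        else:
            below[node] = frozenset().union(*(below[c] for c in node.child_nodes()))
        clades.append(below[node])
    assigned: set[str] = set()
    subsets: list[list[str]] = []
    while True:
        eligible = [
            c for c in clades
            if 4 <= len(c) <= k and not (c & assigned)
        ]
        if not eligible:
            break
        best = max(eligible, key=lambda c: (len(c), [-ord(ch) for ch in min(c)]))
        subsets.append(sorted(best))
        assigned |= best
    # the leftover is generally not monophyletic; chunk it to size
    leftover = sorted(set(labels) - assigned)
    while len(leftover) > k:
        subsets.append(leftover[:k])
        leftover = leftover[k:]
    if leftover:
        if len(leftover) < 4 and subsets:
            subsets[-1].extend(leftover)
        else:
            subsets.append(leftover)
    return subsets


# ---------------------------------------------------------------------------
# Training collection


@dataclass
class SubDataset:
    """One sub-alignment with its working tree and heterogeneity."""

    alignment: ProteinAlignment
    tree: dendropy.Tree | None = None
    het: RateHeterogeneity = NO_HETEROGENEITY


@dataclass
class EstimationConfig:
    """Settings of the iterative estimation loop."""

    initial_model: str | SubstitutionModel = "LG"
    k_max: int = 16
    max_iterations: int = 5
    aic_per_site_threshold: float = 0.01
    seed: int = 0
    split_strategy: str = "tree"  # "tree" or "random"
    optimize_p_inv: bool = True
    gamma_categories: int = 4
    use_gamma: bool = True
    use_nni: bool = False
    em_tol: float = 1e-2
    em_max_iterations: int = 30

    def __post_init__(self) -> None:
        if self.k_max < 4:
            raise ValueError("k_max must be at least 4")
        if self.aic_per_site_threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be >= 0")

    def resolve_initial_model(self) -> SubstitutionModel:
        if isinstance(self.initial_model, SubstitutionModel):
            return self.initial_model
        return get_model(self.initial_model)


@dataclass
class IterationRecord:
    iteration: int
    ll_before_update: float  # current model, trees freshly optimized
    ll_after_update: float   # updated model, same trees
    delta_ll_vs_previous: float
    per_site_aic_gain: float
    max_abs_matrix_change: float


@dataclass
class EstimationTrace:
    """Per-iteration accounting of the estimation loop."""

    initial_ll: float | None = None
    n_sites: int = 0
    n_subsets: int = 0
    records: list[IterationRecord] = field(default_factory=list)

    @property
    def final_ll(self) -> float | None:
        return self.records[-1].ll_after_update if self.records else self.initial_ll

    def total_aic_gain(self) -> AICGain | None:
        if self.initial_ll is None or not self.records:
            return None
        return aic_gain(
            self.final_ll - self.initial_ll, N_FREE_PARAMS, self.n_sites
        )

    def log_likelihoods(self) -> list[float]:
        return [r.ll_after_update for r in self.records]

    def as_table(self) -> str:
        lines = ["iteration\tll_before\tll_after\tdelta_ll\tper_site_aic_gain"]
        for r in self.records:
            lines.append(
                f"{r.iteration}\t{r.ll_before_update:.6f}\t{r.ll_after_update:.6f}"
                f"\t{r.delta_ll_vs_previous:.6f}\t{r.per_site_aic_gain:.6g}"
            )
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# EM update of the exchangeabilities


def observed_frequencies(
    alignments: Sequence[ProteinAlignment], pseudocount: float = 0.5
) -> np.ndarray:
    """Residue frequencies counted over all alignments (definite states only)."""
    counts = np.full(N_STATES, pseudocount)
    for aln in alignments:
        for i, a in enumerate(AMINO_ACIDS):
            counts[i] += (aln.sites == a).sum()
    return counts / counts.sum()


def _total_ll(likelihoods: Sequence[TreeLikelihood]) -> float:
    return sum(tl.log_likelihood() for tl in likelihoods)


def update_exchangeabilities(
    collection: Sequence[SubDataset],
    current: SubstitutionModel,
    em_tol: float = 1e-2,
    em_max_iterations: int = 30,
    floor: float = 1e-7,
    name: str = "estimated",
) -> tuple[SubstitutionModel, float]:
    """EM re-estimation of R with trees and heterogeneity held fixed.

    Frequencies are set to the observed residue frequencies of the
    collection.  Returns (new model, total log-likelihood under it).
    """
    if not collection:
        raise ValueError("empty training collection")
    pi = observed_frequencies([sd.alignment for sd in collection])
    model = SubstitutionModel(name, current.exchangeabilities, pi, source="estimated")
    likelihoods = [
        TreeLikelihood(sd.alignment, sd.tree, model, sd.het) for sd in collection
    ]
    ll = _total_ll(likelihoods)
    for it in range(em_max_iterations):
        N = np.zeros((N_STATES, N_STATES))
        T = np.zeros(N_STATES)
        for tl in likelihoods:
            n, t = tl.expected_substitution_stats()
            N += n
            T += t
        denom = pi[None, :] * T[:, None] + pi[:, None] * T[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            R = np.where(denom > 0, (N + N.T) / np.maximum(denom, 1e-300), floor)
        np.fill_diagonal(R, 0.0)
        off = ~np.eye(N_STATES, dtype=bool)
        R[off] = np.maximum(R[off], floor)
        # normalize to unit mean rate under the model's own frequencies
        mu = float(pi @ (R * pi[None, :]).sum(axis=1) - (R.diagonal() * pi).sum())
        R = R / mu
        model = SubstitutionModel(name, R, pi, source="estimated")
        for tl in likelihoods:
            tl.set_model(model)
        new_ll = _total_ll(likelihoods)
        gain = new_ll - ll
        logger.debug("EM iteration %d: LL %.4f (gain %.4f)", it + 1, new_ll, gain)
        ll = new_ll
        if gain < em_tol:
            break
    return model, ll


# ---------------------------------------------------------------------------
# The full estimation loop


def _build_subdatasets(
    alignment: ProteinAlignment, config: EstimationConfig, model: SubstitutionModel
) -> list[SubDataset]:
    taxa = alignment.taxa
    if len(taxa) <= config.k_max:
        groups = [list(taxa)]
    elif config.split_strategy == "random":
        groups = random_split(taxa, config.k_max, seed=config.seed)
    else:
        distances = ml_distances(alignment, model)
        guide = neighbor_joining(distances, list(taxa))
        groups = tree_based_split(guide, config.k_max)
    return [SubDataset(alignment.subset(g)) for g in groups]


def _optimize_subdataset(
    sd: SubDataset, model: SubstitutionModel, config: EstimationConfig
) -> float:
    """(Re)fit the working tree of one sub-dataset under `model`."""
    if sd.tree is None:
        distances = ml_distances(sd.alignment, model)
        sd.tree = neighbor_joining(distances, list(sd.alignment.taxa))
    tl = TreeLikelihood(sd.alignment, sd.tree, model, sd.het)
    tl.optimize_branch_lengths(tol=1e-5, max_passes=4)
    if config.use_gamma:
        sd.het, _ = optimize_rate_heterogeneity(
            sd.alignment, sd.tree, model,
            n_categories=config.gamma_categories,
            optimize_p_inv=config.optimize_p_inv,
            tl=tl,
        )
    if config.use_nni:
        _, ll = nni_search(sd.alignment, sd.tree, model, sd.het)
        return ll
    tl.set_heterogeneity(sd.het)
    return tl.optimize_branch_lengths(tol=1e-5, max_passes=2)


def estimate_model(
    alignments: ProteinAlignment | Sequence[ProteinAlignment],
    config: EstimationConfig,
    name: str = "estimated",
) -> tuple[SubstitutionModel, EstimationTrace]:
    """Iteratively estimate an empirical substitution model.

    `alignments` is either one training alignment (its taxa are split
    into sub-datasets of at most `config.k_max`) or a pre-split list.
    Each iteration re-optimizes branch lengths and rate heterogeneity of
    every sub-dataset under the current model, then re-estimates the
    exchangeability matrix by EM with the trees fixed; topologies are
    built once (neighbor joining on ML distances, optionally improved by
    NNI) and kept thereafter, so the trace log-likelihood is monotone.
    The loop stops when the per-site AIC gain of an iteration drops
    below `config.aic_per_site_threshold`.
    """
    if isinstance(alignments, ProteinAlignment):
        alignment_list = [alignments]
    else:
        alignment_list = list(alignments)
    if not alignment_list:
        raise ValueError("no training alignments")
    total_taxa = sum(a.n_taxa for a in alignment_list)
    if total_taxa < 4:
        raise ValueError("need at least 4 taxa in total")
    for aln in alignment_list:
        distinct = {"".join(row) for row in aln.sites}
        if aln.n_taxa > 1 and len(distinct) == 1:
            raise ValueError(
                "all sequences identical: no substitutions to learn from; "
                "provide more divergent data"
            )

    model = config.resolve_initial_model()
    trace = EstimationTrace(n_sites=sum(a.n_sites for a in alignment_list))
    if config.max_iterations == 0:
        return model, trace

    collection: list[SubDataset] = []
    for aln in alignment_list:
        if len(alignment_list) == 1:
            collection.extend(_build_subdatasets(aln, config, model))
        else:
            collection.append(SubDataset(aln))
    trace.n_subsets = len(collection)

    previous_ll: float | None = None
    for iteration in range(1, config.max_iterations + 1):
        ll_before = sum(
            _optimize_subdataset(sd, model, config) for sd in collection
        )
        if trace.initial_ll is None:
            trace.initial_ll = ll_before
        old_R = build_rate_matrix(model).values
        model, ll_after = update_exchangeabilities(
            collection, model,
            em_tol=config.em_tol,
            em_max_iterations=config.em_max_iterations,
            name=name,
        )
        new_R = build_rate_matrix(model).values
        reference = previous_ll if previous_ll is not None else ll_before
        delta = ll_after - reference
        per_site = 2.0 * delta / trace.n_sites
        trace.records.append(
            IterationRecord(
                iteration=iteration,
                ll_before_update=ll_before,
                ll_after_update=ll_after,
                delta_ll_vs_previous=delta,
                per_site_aic_gain=per_site,
                max_abs_matrix_change=float(np.abs(new_R - old_R).max()),
            )
        )
        logger.info(
            "iteration %d: LL %.3f -> %.3f (per-site AIC gain %.4g)",
            iteration, ll_before, ll_after, per_site,
        )
        previous_ll = ll_after
        if iteration > 1 and per_site < config.aic_per_site_threshold:
            break
    return model, trace
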