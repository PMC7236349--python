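"""Likelihood of protein alignments on trees under empirical models.

The engine implements Felsenstein pruning over compressed site patterns,
with a mixture over discrete-Gamma rate categories and an optional class
of invariable sites ("+I+G4").  Transition probabilities come from the
symmetric eigendecomposition of ``Pi^{1/2} Q Pi^{-1/2}``, computed once
per model and reused for every branch and rate category.

Rate heterogeneity follows the common mean-preserving median
discretization: category rates are the medians of K equiprobable slices
of Gamma(alpha, alpha), rescaled to mean one; when a proportion
``p_inv`` of sites is invariable, the variable-category rates are
divided by ``1 - p_inv`` so that the total expected rate stays one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import dendropy
import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import logsumexp
from scipy.stats import gamma as gamma_dist

from .alignment import ProteinAlignment
from .alphabet import AMBIGUITY, AMINO_ACIDS, N_STATES, UNKNOWN_STATES
from .models import (
    DEFAULT_RATE_FLOOR,
    RateMatrix,
    SubstitutionModel,
    build_rate_matrix,
)
from .trees import leaf_labels

BRANCH_LENGTH_BOUNDS = (1e-8, 10.0)
ALPHA_BOUNDS = (0.02, 100.0)
PINV_BOUNDS = (0.0, 0.99)


# ---------------------------------------------------------------------------
# Rate heterogeneity


def discrete_gamma_rates(alpha: float, n_categories: int) -> np.ndarray:
    """Mean-one category rates: medians of equiprobable Gamma(a, a) slices."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if n_categories == 1:
        return np.ones(1)
    q = (2 * np.arange(n_categories) + 1) / (2 * n_categories)
    medians = gamma_dist.ppf(q, a=alpha, scale=1.0 / alpha)
    return medians * n_categories / medians.sum()


@dataclass(frozen=True)
class RateHeterogeneity:
    """Proportion of invariable sites plus a discrete-Gamma shape.

    ``alpha=None`` disables Gamma variation (a single rate-1 category).
    The mixture always has total mean rate one.
    """

    p_inv: float = 0.0
    alpha: float | None = None
    n_categories: int = 4

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_inv < 1.0:
            raise ValueError(f"p_inv must be in [0, 1): {self.p_inv}")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError(f"alpha must be positive: {self.alpha}")
        if self.n_categories < 1:
            raise ValueError("need at least one rate category")

    def variable_categories(self) -> tuple[np.ndarray, np.ndarray]:
        """(rates, weights) of the variable-site categories."""
        if self.alpha is None:
            rates = np.ones(1)
        else:
            rates = discrete_gamma_rates(self.alpha, self.n_categories)
        k = len(rates)
        weights = np.full(k, (1.0 - self.p_inv) / k)
        if self.p_inv > 0:
            rates = rates / (1.0 - self.p_inv)
        return rates, weights


NO_HETEROGENEITY = RateHeterogeneity()


# ---------------------------------------------------------------------------
# Transition probabilities


class ModelEigen:
    """Spectral form of a normalized reversible generator."""

    def __init__(self, rate_matrix: RateMatrix):
        self.Q = rate_matrix.values
        self.pi = rate_matrix.frequencies
        s = np.sqrt(self.pi)
        B = (self.Q * s[:, None]) / s[None, :]
        B = 0.5 * (B + B.T)  # symmetric up to round-off by reversibility
        lam, S = np.linalg.eigh(B)
        self.lam = lam
        self.S = S
        self._s = s

    def transition_matrix(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError(f"negative branch length: {t}")
        E = self.S * np.exp(self.lam * t)[None, :]
        P = (E @ self.S.T) * (self._s[None, :] / self._s[:, None])
        np.clip(P, 0.0, None, out=P)
        return P

    def count_integrals(self, t: float) -> np.ndarray:
        """M with M_xy = int_0^t [P(s) e_x e_y^T P(t-s)]-type overlap factors.

        Returns the 20x20 matrix J in the eigenbasis, J_ij =
        (e^{l_i t} - e^{l_j t}) / (l_i - l_j), with t e^{l_i t} on
        coincident eigenvalues; used for expected counts and dwell times.
        """
        lam = self.lam
        elt = np.exp(lam * t)
        diff = lam[:, None] - lam[None, :]
        near = np.abs(diff) < 1e-10
        safe = np.where(near, 1.0, diff)
        J = (elt[:, None] - elt[None, :]) / safe
        avg = 0.5 * (lam[:, None] + lam[None, :])
        J = np.where(near, t * np.exp(avg * t), J)
        return J


def transition_probabilities(rate_matrix: RateMatrix, t: float) -> np.ndarray:
    """P(t) = exp(Q t): rows sum to one, entries non-negative."""
    return ModelEigen(rate_matrix).transition_matrix(t)


# ---------------------------------------------------------------------------
# Alignment encoding

_STATE_VECTORS: dict[str, np.ndarray] = {}
for _i, _a in enumerate(AMINO_ACIDS):
    _v = np.zeros(N_STATES)
    _v[_i] = 1.0
    _STATE_VECTORS[_a] = _v
for _code, _set in AMBIGUITY.items():
    _v = np.zeros(N_STATES)
    for _a in _set:
        _v[AMINO_ACIDS.index(_a)] = 1.0
    _STATE_VECTORS[_code] = _v
for _code in UNKNOWN_STATES:
    _STATE_VECTORS[_code] = np.ones(N_STATES)


def compress_patterns(aln: ProteinAlignment) -> tuple[np.ndarray, np.ndarray]:
    """Unique site columns and their multiplicities."""
    cols, counts = np.unique(aln.sites.T, axis=0, return_counts=True)
    return cols.T, counts.astype(float)


def leaf_partial_matrix(column_chars: np.ndarray) -> np.ndarray:
    """(n_patterns, 20) partial-likelihood rows for one taxon's characters."""
    return np.stack([_STATE_VECTORS[c] for c in column_chars])


# ---------------------------------------------------------------------------
# Tree likelihood


class TaxonMismatchError(ValueError):
    pass


class TreeLikelihood:
    """Pruning likelihood on one (alignment, tree, model) triple.

    The tree is referenced, not copied: branch-length optimization
    mutates the ``dendropy`` edge lengths in place.
    """

    def __init__(
        self,
        aln: ProteinAlignment,
        tree: dendropy.Tree,
        model: SubstitutionModel,
        het: RateHeterogeneity = NO_HETEROGENEITY,
        floor: float | None = DEFAULT_RATE_FLOOR,
        compress: bool = True,
    ):
        tree_taxa = set(leaf_labels(tree))
        aln_taxa = set(aln.taxa)
        if tree_taxa != aln_taxa:
            missing = sorted(aln_taxa - tree_taxa)[:5]
            extra = sorted(tree_taxa - aln_taxa)[:5]
            raise TaxonMismatchError(
                f"tree/alignment taxa differ (alignment only: {missing}; "
                f"tree only: {extra})"
            )
        for node in tree.preorder_node_iter():
            if node.parent_node and node.edge.length is None:
                node.edge.length = 0.0
        self.aln = aln
        self.tree = tree
        self.model = model
        self.het = het
        self.floor = floor
        if compress:
            patterns, weights = compress_patterns(aln)
        else:
            patterns, weights = aln.sites.T.copy().T, np.ones(aln.n_sites)
        self.patterns = patterns  # (n_taxa, n_patterns)
        self.weights = weights
        self.n_patterns = patterns.shape[1]
        row = {t: i for i, t in enumerate(aln.taxa)}
        self._leaf_partials = {}
        for leaf in tree.leaf_node_iter():
            self._leaf_partials[leaf] = leaf_partial_matrix(
                patterns[row[leaf.taxon.label]]
            )
        self._rebuild_eigen()
        # product over all leaves: nonzero only where a constant assignment fits
        prod = np.ones((self.n_patterns, N_STATES))
        for lp in self._leaf_partials.values():
            prod *= lp
        self._invariable_site_lik = prod @ self.eigen.pi

    # -- model / heterogeneity updates ------------------------------------

    def _rebuild_eigen(self) -> None:
        self.eigen = ModelEigen(
            build_rate_matrix(self.model, normalize=True, floor=self.floor)
        )

    def set_model(self, model: SubstitutionModel) -> None:
        self.model = model
        self._rebuild_eigen()
        prod = np.ones((self.n_patterns, N_STATES))
        for lp in self._leaf_partials.values():
            prod *= lp
        self._invariable_site_lik = prod @ self.eigen.pi

    def set_heterogeneity(self, het: RateHeterogeneity) -> None:
        self.het = het

    # -- core recursions ----------------------------------------------------

    def _edges(self) -> list[dendropy.Node]:
        """Non-root nodes, each standing for the edge above it."""
        return [n for n in self.tree.preorder_node_iter() if n.parent_node]

    def _upward(self, rate: float):
        """Post-order partials.  Returns (up, scale) keyed by node."""
        P = {}
        for node in self._edges():
            P[node] = self.eigen.transition_matrix(node.edge.length * rate)
        up: dict[dendropy.Node, np.ndarray] = {}
        scale: dict[dendropy.Node, np.ndarray] = {}
        zero = np.zeros(self.n_patterns)
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                up[node] = self._leaf_partials[node]
                scale[node] = zero
                continue
            partial = np.ones((self.n_patterns, N_STATES))
            sc = np.zeros(self.n_patterns)
            for child in node.child_nodes():
                partial = partial * (up[child] @ P[child].T)
                sc = sc + scale[child]
            m = partial.max(axis=1)
            m[m == 0] = 1.0
            up[node] = partial / m[:, None]
            scale[node] = sc + np.log(m)
        return up, scale, P

    def _site_log_likelihoods(self) -> np.ndarray:
        rates, weights = self.het.variable_categories()
        per_cat = np.empty((len(rates), self.n_patterns))
        for c, (r, w) in enumerate(zip(rates, weights)):
            up, scale, _ = self._upward(r)
            root = self.tree.seed_node
            lik = up[root] @ self.eigen.pi
            with np.errstate(divide="ignore"):
                per_cat[c] = np.log(lik) + scale[root] + math.log(w)
        if self.het.p_inv > 0:
            with np.errstate(divide="ignore"):
                inv = np.log(self.het.p_inv * self._invariable_site_lik)
            per_cat = np.vstack([per_cat, inv[None, :]])
        return logsumexp(per_cat, axis=0)

    def log_likelihood(self) -> float:
        return float(np.dot(self.weights, self._site_log_likelihoods()))

    # -- branch-length optimization -----------------------------------------

    def optimize_branch_lengths(
        self,
        tol: float = 1e-6,
        max_passes: int = 8,
        bounds: tuple[float, float] = BRANCH_LENGTH_BOUNDS,
        brent_xtol: float = 1e-6,
    ) -> float:
        """Round-robin bounded Brent on each branch until LL stabilizes.

        Within a pass, branches are visited in pre-order and the outside
        ("down") vectors are refreshed along the way, so every 1-D
        optimization sees likelihood context consistent with all updates
        made so far; the log-likelihood is non-decreasing.
        """
        ll = self.log_likelihood()
        for _ in range(max_passes):
            self._branch_pass(bounds, brent_xtol)
            new_ll = self.log_likelihood()
            if new_ll - ll < tol * max(1.0, abs(ll)):
                ll = new_ll
                break
            ll = new_ll
        return ll

    def _branch_pass(self, bounds, brent_xtol) -> None:
        rates, weights = self.het.variable_categories()
        ncat = len(rates)
        ups, scales, Ps = [], [], []
        for r in rates:
            up, scale, P = self._upward(r)
            ups.append(up)
            scales.append(scale)
            Ps.append(P)
        root = self.tree.seed_node
        pinv_part = self.het.p_inv * self._invariable_site_lik

        # down[c][node]: outside likelihood over the node's own state
        down = [{root: np.tile(self.eigen.pi, (self.n_patterns, 1))} for _ in range(ncat)]
        dscale = [{root: np.zeros(self.n_patterns)} for _ in range(ncat)]

        for parent in self.tree.preorder_node_iter():
            children = parent.child_nodes()
            if not children:
                continue
            contrib = [
                [ups[c][ch] @ Ps[c][ch].T for ch in children] for c in range(ncat)
            ]
            for idx, child in enumerate(children):
                G = []
                Gscale = []
                for c in range(ncat):
                    g = down[c][parent].copy()
                    sc = dscale[c][parent].copy()
                    for k, other in enumerate(children):
                        if k != idx:
                            g *= contrib[c][k]
                            sc += scales[c][other]
                    G.append(g)
                    Gscale.append(sc + scales[c][child])
                upc = [ups[c][child] for c in range(ncat)]

                def neg_ll(t: float) -> float:
                    per_cat = np.empty((ncat, self.n_patterns))
                    for c in range(ncat):
                        P = self.eigen.transition_matrix(t * rates[c])
                        lik = ((G[c] @ P) * upc[c]).sum(axis=1)
                        with np.errstate(divide="ignore"):
                            per_cat[c] = (
                                np.log(np.maximum(lik, 1e-300))
                                + Gscale[c]
                                + math.log(weights[c])
                            )
                    site = logsumexp(per_cat, axis=0)
                    if self.het.p_inv > 0:
                        site = np.logaddexp(
                            site,
                            np.log(np.maximum(pinv_part, 1e-300)),
                        )
                    return -float(np.dot(self.weights, site))

                res = minimize_scalar(
                    neg_ll, bounds=bounds, method="bounded",
                    options={"xatol": brent_xtol},
                )
                if res.fun <= neg_ll(child.edge.length):
                    child.edge.length = float(res.x)
                for c in range(ncat):
                    Ps[c][child] = self.eigen.transition_matrix(
                        child.edge.length * rates[c]
                    )
                    contrib[c][idx] = ups[c][child] @ Ps[c][child].T
            # push down-vectors to children under the updated lengths
            for idx, child in enumerate(children):
                if child.is_leaf():
                    continue
                for c in range(ncat):
                    g = down[c][parent].copy()
                    sc = dscale[c][parent].copy()
                    for k, other in enumerate(children):
                        if k != idx:
                            g *= contrib[c][k]
                            sc += scales[c][other]
                    d = g @ Ps[c][child]
                    m = d.max(axis=1)
                    m[m == 0] = 1.0
                    down[c][child] = d / m[:, None]
                    dscale[c][child] = sc + np.log(m)

    # -- sufficient statistics for EM ----------------------------------------

    def expected_substitution_stats(self) -> tuple[np.ndarray, np.ndarray]:
        """Expected substitution counts N_xy and dwell times T_x.

        Both are posterior expectations over all branches and rate
        categories given the data, computed from spectral integrals of
        the current generator; dwell is in units of effective branch
        length (branch length times category rate).
        """
        rates, weights = self.het.variable_categories()
        site_ll = self._site_log_likelihoods()
        root = self.tree.seed_node
        s = self.eigen._s
        S, Q = self.eigen.S, self.eigen.Q
        N = np.zeros((N_STATES, N_STATES))
        T = np.zeros(N_STATES)
        for r, w in zip(rates, weights):
            up, scale, P = self._upward(r)
            down = {root: np.tile(self.eigen.pi, (self.n_patterns, 1))}
            dscale = {root: np.zeros(self.n_patterns)}
            for parent in self.tree.preorder_node_iter():
                children = parent.child_nodes()
                if not children:
                    continue
                contrib = [up[ch] @ P[ch].T for ch in children]
                for idx, child in enumerate(children):
                    g = down[parent].copy()
                    sc = dscale[parent].copy()
                    for k, other in enumerate(children):
                        if k != idx:
                            g *= contrib[k]
                            sc += scale[other]
                    # joint endpoint weights for this branch
                    logw = sc + scale[child] - site_ll + math.log(w)
                    wvec = self.weights * np.exp(logw)
                    C = (g * wvec[:, None]).T @ up[child]
                    tau = child.edge.length * r
                    J = self.eigen.count_integrals(tau)
                    D = S.T @ ((C * (s[None, :] / s[:, None]))) @ S
                    M = (S @ (D * J) @ S.T) * (s[:, None] / s[None, :])
                    T += np.diag(M)
                    N += Q * M
                    if not child.is_leaf():
                        d = g @ P[child]
                        m = d.max(axis=1)
                        m[m == 0] = 1.0
                        down[child] = d / m[:, None]
                        dscale[child] = sc + np.log(m)
        np.fill_diagonal(N, 0.0)
        return N, T


# ---------------------------------------------------------------------------
# Convenience wrappers


def log_likelihood(
    aln: ProteinAlignment,
    tree: dendropy.Tree,
    model: SubstitutionModel,
    het: RateHeterogeneity = NO_HETEROGENEITY,
    floor: float | None = DEFAULT_RATE_FLOOR,
) -> float:
    """Pruning log-likelihood of the alignment on the tree under the model."""
    if len(aln.taxa) == 1:
        # no tree edges: sites are independent draws from Pi
        pi = build_rate_matrix(model, floor=floor).frequencies
        lp = leaf_partial_matrix(aln.sites[0])
        informative = lp.sum(axis=1) < N_STATES
        with np.errstate(divide="ignore"):
            vals = np.where(informative, np.log(lp @ pi), 0.0)
        return float(vals.sum())
    return TreeLikelihood(aln, tree, model, het, floor).log_likelihood()


def optimize_branch_lengths(
    aln: ProteinAlignment,
    tree: dendropy.Tree,
    model: SubstitutionModel,
    het: RateHeterogeneity = NO_HETEROGENEITY,
    tol: float = 1e-6,
) -> tuple[dendropy.Tree, float]:
    """Optimize branch lengths in place; returns (tree, final LL)."""
    tl = TreeLikelihood(aln, tree, model, het)
    ll = tl.optimize_branch_lengths(tol=tol)
    return tree, ll


def optimize_rate_heterogeneity(
    aln: ProteinAlignment,
    tree: dendropy.Tree,
    model: SubstitutionModel,
    n_categories: int = 4,
    optimize_p_inv: bool = True,
    tl: TreeLikelihood | None = None,
) -> tuple[RateHeterogeneity, float]:
    """Jointly optimize (p_inv, alpha) by bounded 2-D search."""
    if tl is None:
        tl = TreeLikelihood(aln, tree, model)

    def ll_at(p_inv: float, alpha: float) -> float:
        tl.set_heterogeneity(
            RateHeterogeneity(p_inv=p_inv, alpha=alpha, n_categories=n_categories)
        )
        return tl.log_likelihood()

    # coarse grid start, then simplex refinement in transformed coordinates
    p_grid = [0.0, 0.2, 0.4] if optimize_p_inv else [0.0]
    a_grid = [0.3, 1.0, 5.0, 50.0]
    best = max(
        ((p, a) for p in p_grid for a in a_grid), key=lambda pa: ll_at(*pa)
    )

    def unpack(z) -> tuple[float, float]:
        p = PINV_BOUNDS[0] + (PINV_BOUNDS[1] - PINV_BOUNDS[0]) / (1 + math.exp(-z[0]))
        a = math.exp(
            np.clip(z[1], math.log(ALPHA_BOUNDS[0]), math.log(ALPHA_BOUNDS[1]))
        )
        return (p if optimize_p_inv else 0.0), a

    def neg(z) -> float:
        return -ll_at(*unpack(z))

    z0 = [
        math.log((best[0] + 1e-3) / max(PINV_BOUNDS[1] - best[0], 1e-3)),
        math.log(best[1]),
    ]
    res = minimize(
        neg, z0, method="Nelder-Mead",
        options={"xatol": 1e-3, "fatol": 1e-4, "maxfev": 60},
    )
    p_inv, alpha = unpack(res.x)
    het = RateHeterogeneity(p_inv=p_inv, alpha=alpha, n_categories=n_categories)
    tl.set_heterogeneity(het)
    return het, tl.log_likelihood()


# ---------------------------------------------------------------------------
# Information criteria and model selection


@dataclass(frozen=True)
class ModelFitResult:
    """Per-model fit summary on one dataset."""

    model_name: str
    log_likelihood: float
    n_free_params: int
    n_sites: int
    AIC: float
    AICc: float | None
    BIC: float
    p_inv: float = 0.0
    alpha: float | None = None

    @property
    def per_site_AIC(self) -> float:
        return self.AIC / self.n_sites


def information_criteria(
    log_likelihood: float, n_free_params: int, n_sites: int
) -> dict[str, float | None]:
    """AIC, AICc, BIC and per-site AIC from standard formulas.

    AICc is None (flagged undefined) when n_sites <= n_free_params + 1.
    """
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    aic = -2.0 * log_likelihood + 2.0 * n_free_params
    bic = -2.0 * log_likelihood + n_free_params * math.log(n_sites)
    if n_sites > n_free_params + 1:
        aicc = aic + (
            2.0 * n_free_params * (n_free_params + 1) / (n_sites - n_free_params - 1)
        )
    else:
        aicc = None
    return {
        "AIC": aic,
        "AICc": aicc,
        "BIC": bic,
        "per_site_AIC": aic / n_sites,
    }


def select_best_model(
    aln: ProteinAlignment,
    tree: dendropy.Tree,
    candidates: Sequence[SubstitutionModel],
    criterion: str = "BIC",
    n_categories: int = 4,
    optimize_p_inv: bool = True,
    branch_tol: float = 1e-4,
) -> list[ModelFitResult]:
    """Score candidate models on a fixed topology and rank them.

    Each candidate gets its own optimized branch lengths and (p_inv,
    alpha).  Free parameters count the branch lengths plus the two
    heterogeneity parameters (the empirical matrices are constants), so
    ranking differences come from the data fit.  Ties break by name.
    """
    if criterion not in {"AIC", "AICc", "BIC"}:
        raise ValueError(f"unknown criterion {criterion!r}")
    if len(candidates) < 1:
        raise ValueError("need at least one candidate")
    results = []
    for model in candidates:
        work = tree.clone(depth=1)
        tl = TreeLikelihood(aln, work, model)
        tl.optimize_branch_lengths(tol=branch_tol, max_passes=3)
        het, _ = optimize_rate_heterogeneity(
            aln, work, model, n_categories=n_categories,
            optimize_p_inv=optimize_p_inv, tl=tl,
        )
        ll = tl.optimize_branch_lengths(tol=branch_tol, max_passes=2)
        n_branches = sum(1 for n in work.preorder_node_iter() if n.parent_node)
        k = n_branches + (2 if optimize_p_inv else 1)
        ic = information_criteria(ll, k, aln.n_sites)
        results.append(
            ModelFitResult(
                model_name=model.name,
                log_likelihood=ll,
                n_free_params=k,
                n_sites=aln.n_sites,
                AIC=ic["AIC"],
                AICc=ic["AICc"],
                BIC=ic["BIC"],
                p_inv=het.p_inv,
                alpha=het.alpha,
            )
        )
    key = {"AIC": lambda r: r.AIC, "AICc": lambda r: (r.AICc if r.AICc is not None else r.AIC), "BIC": lambda r: r.BIC}[criterion]
    return sorted(results, key=lambda r: (key(r), r.model_name))


# ---------------------------------------------------------------------------
# Pairwise ML distances and NNI search


def ml_distances(
    aln: ProteinAlignment,
    model: SubstitutionModel,
    het: RateHeterogeneity = NO_HETEROGENEITY,
) -> np.ndarray:
    """Pairwise two-sequence maximum-likelihood distances.

    Each entry maximizes the two-sequence likelihood over the separating
    branch length; sites with a gap or ambiguity in either sequence are
    ignored for that pair.
    """
    if aln.n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    eigen = ModelEigen(build_rate_matrix(model))
    rates, weights = het.variable_categories()
    idx = np.full(aln.sites.shape, -1, dtype=int)
    for i, a in enumerate(AMINO_ACIDS):
        idx[aln.sites == a] = i
    n = aln.n_taxa
    D = np.zeros((n, n))
    log_pi = np.log(eigen.pi)
    for i in range(n):
        for j in range(i + 1, n):
            ok = (idx[i] >= 0) & (idx[j] >= 0)
            C = np.zeros((N_STATES, N_STATES))
            np.add.at(C, (idx[i][ok], idx[j][ok]), 1.0)

            def neg_ll(t: float) -> float:
                mix = np.zeros((N_STATES, N_STATES))
                for r, w in zip(rates, weights):
                    mix += w * eigen.transition_matrix(t * r)
                if het.p_inv > 0:
                    mix += het.p_inv * np.eye(N_STATES)
                with np.errstate(divide="ignore"):
                    return -float(
                        (C * (log_pi[:, None] + np.log(np.maximum(mix, 1e-300)))).sum()
                    )

            if C.sum() == 0 or np.trace(C) == C.sum():
                D[i, j] = D[j, i] = BRANCH_LENGTH_BOUNDS[0]
                continue
            res = minimize_scalar(
                neg_ll, bounds=BRANCH_LENGTH_BOUNDS, method="bounded",
                options={"xatol": 1e-6},
            )
            D[i, j] = D[j, i] = float(res.x)
    return D


def _nni_moves(tree: dendropy.Tree):
    """(edge child node v, donor subtree under u, recipient child of v) pairs."""
    root = tree.seed_node
    for v in tree.preorder_node_iter():
        u = v.parent_node
        if u is None or v.is_leaf():
            continue
        others = [c for c in u.child_nodes() if c is not v]
        if u is root:
            if len(others) < 1:
                continue
            donor = others[0]
        else:
            donor = others[0] if others else None
        if donor is None:
            continue
        for recipient in list(v.child_nodes()):
            yield v, donor, recipient


def _apply_swap(v, donor, recipient) -> None:
    u = v.parent_node
    u.remove_child(donor)
    v.remove_child(recipient)
    u.add_child(recipient)
    v.add_child(donor)


def nni_search(
    aln: ProteinAlignment,
    tree: dendropy.Tree,
    model: SubstitutionModel,
    het: RateHeterogeneity = NO_HETEROGENEITY,
    max_rounds: int = 10,
    min_improvement: float = 1e-4,
) -> tuple[dendropy.Tree, float]:
    """Greedy NNI hill-climbing; LL is non-decreasing, in-place on `tree`."""
    tl = TreeLikelihood(aln, tree, model, het)
    ll = tl.optimize_branch_lengths(tol=1e-5, max_passes=4)
    for _ in range(max_rounds):
        improved = False
        for v, donor, recipient in list(_nni_moves(tree)):
            # skip moves invalidated by an earlier accepted swap
            if v.parent_node is None or donor.parent_node is not v.parent_node:
                continue
            if recipient.parent_node is not v:
                continue
            _apply_swap(v, donor, recipient)
            cand = TreeLikelihood(aln, tree, model, het).log_likelihood()
            if cand > ll + min_improvement:
                ll = cand
                improved = True
            else:
                _apply_swap(v, recipient, donor)  # revert
        if not improved:
            break
        tl = TreeLikelihood(aln, tree, model, het)
        ll = tl.optimize_branch_lengths(tol=1e-5, max_passes=3)
    return tree, ll
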