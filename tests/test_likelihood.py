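"""Likelihood engine: transition matrices, pruning, optimization, criteria."""

import itertools
import math

import numpy as np
import pytest

from aamodel.alignment import ProteinAlignment
from aamodel.alphabet import AMINO_ACIDS
from aamodel.likelihood import (
    ModelEigen,
    RateHeterogeneity,
    TaxonMismatchError,
    TreeLikelihood,
    discrete_gamma_rates,
    information_criteria,
    log_likelihood,
    ml_distances,
    nni_search,
    optimize_rate_heterogeneity,
    select_best_model,
    transition_probabilities,
)
from aamodel.models import build_rate_matrix
from aamodel.registry import get_model
from aamodel.simulate import SimulationSpec, simulate_alignment
from aamodel.trees import leaf_labels, parse_newick, random_tree, robinson_foulds

from conftest import make_random_model


def brute_force_ll(aln, tree, model, het=RateHeterogeneity()):
    """Exhaustive enumeration over all internal-node state assignments."""
    eig = ModelEigen(build_rate_matrix(model))
    pi = eig.pi
    nodes = list(tree.postorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    row = {t: i for i, t in enumerate(aln.taxa)}
    vec = {}
    for leaf in tree.leaf_node_iter():
        from aamodel.likelihood import _STATE_VECTORS
        vec[leaf] = [
            _STATE_VECTORS[aln.sites[row[leaf.taxon.label], s]]
            for s in range(aln.n_sites)
        ]
    rates, weights = het.variable_categories()
    total = 0.0
    for s in range(aln.n_sites):
        lik = 0.0
        for r, w in zip(rates, weights):
            P = {
                n: eig.transition_matrix((n.edge.length or 0.0) * r)
                for n in nodes
                if n.parent_node
            }
            for states in itertools.product(range(20), repeat=len(internal)):
                assign = dict(zip(internal, states))
                p = pi[assign[tree.seed_node]]
                for n in nodes:
                    if n.parent_node is None:
                        continue
                    a = assign[n.parent_node]
                    if n.is_leaf():
                        p *= float(P[n][a] @ vec[n][s])
                    else:
                        p *= P[n][a, assign[n]]
                lik += w * p
        if het.p_inv > 0:
            prod = np.ones(20)
            for leaf in tree.leaf_node_iter():
                prod = prod * vec[leaf][s]
            lik += het.p_inv * float(prod @ pi)
        total += math.log(lik)
    return total


# ---------------------------------------------------------------------------
# Rate heterogeneity


def test_discrete_gamma_rates_have_mean_one():
    for alpha in (0.3, 1.0, 4.0):
        rates = discrete_gamma_rates(alpha, 4)
        assert rates.shape == (4,)
        assert rates.mean() == pytest.approx(1.0)
        assert np.all(np.diff(rates) > 0)


def test_mixture_total_mean_rate_is_one_with_pinv():
    het = RateHeterogeneity(p_inv=0.3, alpha=0.7)
    rates, weights = het.variable_categories()
    assert (rates * weights).sum() == pytest.approx(1.0)  # invariable class adds 0


def test_heterogeneity_validation():
    with pytest.raises(ValueError):
        RateHeterogeneity(p_inv=1.0)
    with pytest.raises(ValueError):
        RateHeterogeneity(alpha=-1.0)


# ---------------------------------------------------------------------------
# Transition probabilities


def test_transition_matrix_limits(mtort):
    Q = build_rate_matrix(mtort)
    assert np.allclose(transition_probabilities(Q, 0.0), np.eye(20), atol=1e-12)
    P = transition_probabilities(Q, 500.0)
    assert np.abs(P - Q.frequencies[None, :]).max() < 1e-6
    P = transition_probabilities(Q, 0.7)
    assert np.abs(P.sum(axis=1) - 1.0).max() < 1e-10
    assert P.min() >= 0
    with pytest.raises(ValueError):
        transition_probabilities(Q, -0.1)


def test_uniform_model_matches_closed_form(uniform_model):
    """20-state equal-rates chain: p_same = 1/20 + (19/20) e^{-20t/19}."""
    Q = build_rate_matrix(uniform_model)
    for t in (0.05, 0.3, 1.7):
        P = transition_probabilities(Q, t)
        p_same = 1 / 20 + (19 / 20) * math.exp(-20 * t / 19)
        p_diff = (1 - p_same) / 19
        assert np.allclose(np.diag(P), p_same, atol=1e-12)
        assert np.allclose(P[~np.eye(20, dtype=bool)], p_diff, atol=1e-12)


# ---------------------------------------------------------------------------
# Pruning likelihood


def test_single_taxon_ll_is_log_frequencies(mtort):
    aln = ProteinAlignment.from_sequences([("a", "MKV-X")])
    pi = build_rate_matrix(mtort).frequencies
    idx = [AMINO_ACIDS.index(c) for c in "MKV"]
    expected = sum(math.log(pi[i]) for i in idx)  # gaps and X contribute 0
    assert log_likelihood(aln, None, mtort) == pytest.approx(expected)


def test_identical_sequences_on_zero_branches_equal_single_sequence(mtort):
    seq = "MKVLWAAR"
    single = log_likelihood(ProteinAlignment.from_sequences([("a", seq)]), None, mtort)
    aln = ProteinAlignment.from_sequences([("a", seq), ("b", seq)])
    tree = parse_newick("(a:0.0,b:0.0);")
    assert log_likelihood(aln, tree, mtort) == pytest.approx(single, abs=1e-9)


def test_pruning_equals_enumeration_on_small_trees(rng):
    """Felsenstein pruning against exhaustive state enumeration."""
    for trial in range(6):
        n = int(rng.integers(3, 5))
        model = make_random_model(rng)
        tree = random_tree(n, rng=rng, brlen_mean=0.2)
        het = (
            RateHeterogeneity()
            if trial % 2
            else RateHeterogeneity(p_inv=0.15, alpha=0.9)
        )
        sim = simulate_alignment(
            SimulationSpec(model=model, n_sites=8, tree=tree, seed=int(rng.integers(1 << 30)), het=het)
        )
        got = log_likelihood(sim.alignment, tree, model, het)
        expected = brute_force_ll(sim.alignment, tree, model, het)
        assert got == pytest.approx(expected, abs=1e-8)


def test_ll_invariant_to_rerooting(mtort):
    sim = simulate_alignment(SimulationSpec(model=mtort, n_sites=60, n_taxa=6, seed=9))
    tree = sim.tree
    het = RateHeterogeneity(p_inv=0.1, alpha=1.2)
    ref = log_likelihood(sim.alignment, tree, mtort, het)
    internals = [
        n for n in tree.preorder_node_iter()
        if not n.is_leaf() and n is not tree.seed_node
    ]
    for node in internals[:3]:
        tree.reroot_at_node(node, update_bipartitions=False)
        got = log_likelihood(sim.alignment, tree, mtort, het)
        assert got == pytest.approx(ref, abs=1e-8)


def test_all_gap_taxon_on_zero_pendant_leaves_ll_unchanged(mtort):
    sim = simulate_alignment(SimulationSpec(model=mtort, n_sites=40, n_taxa=5, seed=4))
    base = log_likelihood(sim.alignment, sim.tree, mtort)
    taxa = sim.alignment.taxa + ["ghost"]
    sites = np.vstack([sim.alignment.sites, np.full((1, 40), "-")])
    aln2 = ProteinAlignment(taxa, sites)
    import dendropy
    tree2 = sim.tree.clone(depth=1)
    host = next(tree2.leaf_node_iter())
    ghost = dendropy.Node(taxon=dendropy.Taxon("ghost"))
    tree2.taxon_namespace.add_taxon(ghost.taxon)
    host.add_child(ghost)
    ghost.edge.length = 0.0
    host.new_child(taxon=host.taxon)
    host.child_nodes()[-1].edge.length = 0.0
    host.taxon = None
    assert log_likelihood(aln2, tree2, mtort) == pytest.approx(base, abs=1e-9)


def test_pattern_compression_does_not_change_ll(mtort):
    sim = simulate_alignment(SimulationSpec(model=mtort, n_sites=200, n_taxa=5, seed=2))
    het = RateHeterogeneity(p_inv=0.1, alpha=0.8)
    a = TreeLikelihood(sim.alignment, sim.tree, mtort, het, compress=True).log_likelihood()
    b = TreeLikelihood(sim.alignment, sim.tree, mtort, het, compress=False).log_likelihood()
    assert a == pytest.approx(b, abs=1e-8)


def test_taxon_mismatch_reports_offenders(mtort):
    aln = ProteinAlignment.from_sequences([("a", "MK"), ("b", "MR"), ("c", "ML")])
    tree = parse_newick("(a,b,zzz);")
    with pytest.raises(TaxonMismatchError, match="zzz"):
        TreeLikelihood(aln, tree, mtort)


# ---------------------------------------------------------------------------
# Optimization


def test_branch_length_recovered_for_two_sequences(mtort):
    sim = simulate_alignment(
        SimulationSpec(model=mtort, n_sites=5000, tree=parse_newick("(a:0.15,b:0.15);"), seed=21)
    )
    tl = TreeLikelihood(sim.alignment, parse_newick("(a:0.05,b:0.05);"), mtort)
    ll = tl.optimize_branch_lengths()
    total = sum(e.length for e in tl.tree.preorder_edge_iter() if e.length)
    assert 0.2 <= total <= 0.4  # true separation 0.3
    # grid-scan oracle: no single-branch assignment beats the optimum
    for t in np.linspace(0.05, 0.6, 12):
        tree = parse_newick(f"(a:{t / 2},b:{t / 2});")
        assert log_likelihood(sim.alignment, tree, mtort) <= ll + 1e-6


def test_branch_length_optimization_is_idempotent(mtort):
    sim = simulate_alignment(SimulationSpec(model=mtort, n_sites=300, n_taxa=6, seed=3))
    tl = TreeLikelihood(sim.alignment, sim.tree, mtort)
    ll1 = tl.optimize_branch_lengths()
    ll2 = tl.optimize_branch_lengths()
    assert ll2 >= ll1 - 1e-9
    assert ll2 - ll1 < 1e-4


def test_identical_sequences_drive_lengths_to_lower_bound(mtort):
    aln = ProteinAlignment.from_sequences(
        [("a", "MKVLW" * 20), ("b", "MKVLW" * 20), ("c", "MKVLW" * 20)]
    )
    tree = parse_newick("(a:0.1,b:0.1,c:0.1);")
    tl = TreeLikelihood(aln, tree, mtort)
    tl.optimize_branch_lengths()
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            assert e.length <= 1e-4


def test_gamma_limit_reproduces_homogeneous_ll(mtort):
    sim = simulate_alignment(SimulationSpec(model=mtort, n_sites=100, n_taxa=5, seed=6))
    plain = log_likelihood(sim.alignment, sim.tree, mtort)
    limit = log_likelihood(
        sim.alignment, sim.tree, mtort, RateHeterogeneity(alpha=1e7, n_categories=4)
    )
    assert limit == pytest.approx(plain, abs=1e-4)


def test_homogeneous_data_pushes_alpha_to_bound(mtort):
    sim = simulate_alignment(SimulationSpec(model=mtort, n_sites=8000, n_taxa=8, seed=13))
    tl = TreeLikelihood(sim.alignment, sim.tree, mtort)
    plain = tl.optimize_branch_lengths()
    het, ll = optimize_rate_heterogeneity(
        sim.alignment, sim.tree, mtort, optimize_p_inv=False, tl=tl
    )
    assert het.alpha >= 99 or (ll - plain) < 0.5


def test_heterogeneity_recovery_improves_ll(mtort):
    het_true = RateHeterogeneity(p_inv=0.25, alpha=0.5)
    sim = simulate_alignment(
        SimulationSpec(model=mtort, n_sites=1000, n_taxa=8, seed=17, het=het_true)
    )
    plain = log_likelihood(sim.alignment, sim.tree, mtort)
    het, ll = optimize_rate_heterogeneity(sim.alignment, sim.tree, mtort)
    assert ll > plain + 5
    assert het.alpha < 5


# ---------------------------------------------------------------------------
# Information criteria and model selection


def test_information_criteria_match_hand_formulas(rng):
    for _ in range(10):
        ll = float(-rng.uniform(100, 1e5))
        k = int(rng.integers(1, 300))
        n = int(rng.integers(k + 2, k + 5000))
        ic = information_criteria(ll, k, n)
        assert ic["AIC"] == pytest.approx(-2 * ll + 2 * k)
        assert ic["BIC"] == pytest.approx(-2 * ll + k * math.log(n))
        assert ic["AICc"] == pytest.approx(ic["AIC"] + 2 * k * (k + 1) / (n - k - 1))
        assert ic["per_site_AIC"] == pytest.approx(ic["AIC"] / n)


def test_aicc_flagged_undefined_for_tiny_samples():
    assert information_criteria(-10.0, 5, 6)["AICc"] is None
    with pytest.raises(ValueError):
        information_criteria(-10.0, 5, 0)


def test_single_candidate_is_selected(mtort):
    sim = simulate_alignment(SimulationSpec(model=mtort, n_sites=120, n_taxa=5, seed=8))
    ranked = select_best_model(sim.alignment, sim.tree, [mtort], criterion="BIC")
    assert len(ranked) == 1 and ranked[0].model_name == "mtOrt"


def test_identical_models_tie_and_sort_by_name(mtort):
    sim = simulate_alignment(SimulationSpec(model=mtort, n_sites=120, n_taxa=5, seed=8))
    twin_b = mtort.renamed("zzz_twin")
    twin_a = mtort.renamed("aaa_twin")
    ranked = select_best_model(sim.alignment, sim.tree, [twin_b, twin_a], criterion="AIC")
    assert [r.model_name for r in ranked] == ["aaa_twin", "zzz_twin"]
    assert ranked[0].AIC == pytest.approx(ranked[1].AIC, abs=1e-6)


# ---------------------------------------------------------------------------
# Pairwise distances and NNI


def test_ml_distance_identical_and_symmetry(mtort):
    aln = ProteinAlignment.from_sequences([("a", "MKVLW" * 10), ("b", "MKVLW" * 10)])
    D = ml_distances(aln, mtort)
    assert D[0, 1] == pytest.approx(1e-8, abs=1e-6)
    aln2 = ProteinAlignment.from_sequences(
        [("b", "MKVLWRRK" * 10), ("a", "MKVLWAAR" * 10)]
    )
    D2 = ml_distances(aln2, mtort)
    assert D2[0, 1] == D2[1, 0]


def test_ml_distance_recovers_simulated_divergence(mtort):
    sim = simulate_alignment(
        SimulationSpec(model=mtort, n_sites=5000, tree=parse_newick("(a:0.15,b:0.15);"), seed=30)
    )
    D = ml_distances(sim.alignment, mtort)
    assert 0.25 <= D[0, 1] <= 0.35


def test_nni_keeps_true_topology(mtort):
    sim = simulate_alignment(SimulationSpec(model=mtort, n_sites=2000, n_taxa=8, seed=22))
    start = sim.tree.clone(depth=1)
    result, _ = nni_search(sim.alignment, start, mtort)
    assert robinson_foulds(result, sim.tree) == 0


def test_nni_finds_best_four_taxon_topology(mtort):
    sim = simulate_alignment(
        SimulationSpec(
            model=mtort, n_sites=1500,
            tree=parse_newick("((a:0.2,b:0.2):0.12,(c:0.2,d:0.2):0.12);"), seed=14,
        )
    )
    topologies = [
        "((a:0.1,b:0.1):0.1,(c:0.1,d:0.1):0.1);",
        "((a:0.1,c:0.1):0.1,(b:0.1,d:0.1):0.1);",
        "((a:0.1,d:0.1):0.1,(b:0.1,c:0.1):0.1);",
    ]
    scored = []
    for t in topologies:
        tree = parse_newick(t)
        tl = TreeLikelihood(sim.alignment, tree, mtort)
        scored.append((tl.optimize_branch_lengths(), tree))
    best_ll, best_tree = max(scored, key=lambda x: x[0])
    start = parse_newick(topologies[1])
    result, ll = nni_search(sim.alignment, start, mtort)
    assert robinson_foulds(result, best_tree) == 0
    assert ll == pytest.approx(best_ll, abs=0.1)


def test_nni_never_decreases_ll(mtort):
    sim = simulate_alignment(SimulationSpec(model=mtort, n_sites=500, n_taxa=7, seed=19))
    start = random_tree(7, seed=99, labels=leaf_labels(sim.tree))
    start_ll = log_likelihood(sim.alignment, start, mtort)
    _, final_ll = nni_search(sim.alignment, start, mtort)
    assert final_ll >= start_ll
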