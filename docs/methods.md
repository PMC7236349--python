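# Methods

## The model class

An empirical amino-acid substitution model is a pair (R, Π): a symmetric
20×20 matrix of exchangeabilities r_xy ≥ 0 (the relative propensity of
substitution between residues x and y, independent of how common the
target residue is) and an equilibrium frequency vector Π = {π_x}.  The
continuous-time Markov generator is

    q_xy = r_xy π_y   (x ≠ y),     q_xx = −Σ_{y≠x} q_xy,

which is time-reversible by construction (π_x q_xy = π_y q_yx).  Q is
normalized so that the expected number of substitutions per site per
unit time, −Σ_x π_x q_xx, equals one; branch lengths are then expected
substitutions per site.  A full model of this class has 208 free
parameters: 189 independent exchangeabilities (190 pairs minus one fixed
by the overall scale) plus 19 free frequencies.  Transition matrices
P(t) = exp(Qt) are computed by symmetric eigendecomposition of
Π^{1/2} Q Π^{−1/2}, once per model, and reused for every branch and rate
category.

Residues are indexed in the canonical PAML order
(Ala, Arg, Asn, Asp, Cys, Gln, Glu, Gly, His, Ile, Leu, Lys, Met, Phe,
Pro, Ser, Thr, Trp, Tyr, Val); files in other orders must be re-indexed
on load.

## Bundled matrices and their provenance

The registry bundles Dayhoff, JTT, LG, WAG, mtREV, mtArt and mtZoa
verbatim at their published scales (the standard PAML-format values),
plus mtOrt, an empirical model for Orthoptera mitochondrial proteins.
mtOrt is bundled at the precision of its published table (two decimals).
Five pair rates print as 0.00 there; they are reconstructed as follows
and the reconstruction is part of this package, not of the original
publication: Arg–Phe carries its separately published value 0.00005 (the
model's stated minimum), and Lys–Ala, Lys–Cys, Pro–Cys and Val–His are
set to 0.001, a value inside the printed rounding band (0.00005, 0.005).
The published frequency row sums to 1.02 and is renormalized on load.
Model comparison statistics (Pearson correlations over the 190 pair
values or the 20 frequencies, extreme entries, ratio-exceedance counts)
are computed on raw values without rescaling — correlations are
scale-invariant, and the bundled published matrices reproduce the
printed pairwise correlation table to three decimals.

A caveat discovered while validating: the published pairwise-correlation
table is internally inconsistent for some rows.  Computed from the
printed matrices, mtOrt correlates strongly (≈ 0.8) with the general
models (LG, JTT), as mtArt and mtZoa do, whereas the table prints
near-zero values for exactly the rows whose model files circulate in a
different residue order.  The package trusts the matrices; tests assert
only the table cells that are consistent with them.

When a generator is built for likelihood work, exchangeabilities below
1e-7 are floored at 1e-7 so the chain stays irreducible; the stored
model keeps the published zeros for comparison statistics.

## Likelihood

Alignment likelihoods use Felsenstein pruning over site patterns
(identical columns are collapsed and weighted), with per-node rescaling
of partial likelihoods to prevent underflow.  Gaps, `X`, `?` and `*`
contribute a partial likelihood of one for every state; `B`, `Z`, `J`
restrict to {Asn, Asp}, {Gln, Glu}, {Ile, Leu}.  Because the process is
reversible, the likelihood is invariant to the position of the root;
this is verified by re-rooting tests.

Rate heterogeneity follows the "+I+G4" convention: a proportion p_inv of
invariable sites plus four discrete-Gamma categories.  Category rates
are the medians of four equiprobable slices of Gamma(α, α), rescaled to
mean one (the mean-preserving median discretization used by IQ-TREE and
PhyML; a dial — `n_categories` is configurable).  With p_inv > 0 the
variable-category rates are divided by 1 − p_inv so the total expected
rate stays one.

Branch lengths are optimized by bounded Brent searches on one branch at
a time, bounds [1e-8, 10].  Within a pass, branches are visited in
pre-order while the outside ("down") partial vectors are refreshed along
the way, so each 1-D optimization is exact coordinate ascent and the
log-likelihood never decreases; passes repeat until the relative change
falls below 1e-6 (default).  (p_inv, α) are optimized jointly by a
coarse grid start followed by Nelder–Mead in transformed coordinates,
with α ∈ [0.02, 100] and p_inv ∈ [0, 0.99].

Information criteria use the standard formulas AIC = −2LL + 2k,
BIC = −2LL + k ln n, AICc = AIC + 2k(k+1)/(n−k−1) with n the site count;
AICc is flagged undefined when n ≤ k + 1.  When ranking fixed empirical
models, k counts the branch lengths plus the heterogeneity parameters —
the matrices themselves are constants shared by all candidates, so the
ranking reflects data fit.  Ties break by model name.

## Model estimation

The estimation loop mirrors the FastMG-style procedure used to build
empirical mitochondrial models:

1. **Split.**  The taxa of the training alignment are partitioned into
   sub-datasets of at most k_max sequences (default 16), either at
   random (shuffled chunks; a trailing chunk smaller than 4 merges
   backward) or by tree-based splitting: a guide tree is built by
   neighbor joining on pairwise ML distances under the initial model,
   and clades of size 4..k_max are greedily extracted, largest first,
   always selecting clades of the *original* guide tree so every
   extracted subset is monophyletic; leftover leaves form trailing
   subsets that need not be.  The partition is computed once and held
   fixed across iterations, so per-iteration likelihood totals are
   comparable and the trace is monotone.
2. **Trees.**  Each sub-dataset gets a neighbor-joining topology from
   pairwise ML distances, then per-iteration branch-length and (p_inv, α)
   re-optimization under the current model (optional NNI hill-climbing).
3. **Update.**  With trees fixed, the exchangeabilities are re-estimated
   by expectation–maximization.  The E-step computes, per branch and
   rate category, the posterior expected substitution counts N_xy and
   dwell times T_x from spectral integrals of the generator
   (J_ij(t) = (e^{λ_i t} − e^{λ_j t})/(λ_i − λ_j) in the eigenbasis,
   combined with the inside/outside partial vectors).  The M-step is the
   exact maximizer of the complete-data likelihood for the reversible
   parameterization with fixed frequencies:

       r'_xy ∝ (N_xy + N_yx) / (π_y T_x + π_x T_y),

   so each inner EM step cannot decrease the likelihood.  Frequencies
   are set to observed residue counts over the collection (the "+F"
   convention; a pseudocount of 0.5 per residue avoids zeros).  The
   inner loop stops when the total log-likelihood gains less than 0.01.
4. **Convergence.**  The outer loop records, per iteration, the total
   log-likelihood before and after the matrix update and stops when an
   iteration's per-site AIC gain (2·ΔLL/n_sites) drops below the
   threshold (default 0.01/site) or max_iterations is reached.  The
   416-unit penalty for the 208 extra parameters is applied once, in the
   cumulative gain versus the initial model, not per iteration.

The estimated matrix is reported with frequencies summing to one and
exchangeabilities scaled so the generator has unit mean rate under the
model's own frequencies, which puts the values on the same magnitude
scale as the published matrices.

A statistical point that shapes the tests: re-fitting 208 parameters at
the generating model still gains roughly k/2 ≈ 104 log-likelihood units
of sampling-noise overfit on finite data, independent of alignment
length; "near fixed point" is therefore asserted on that scale, not at
zero.

## Tree distances

Robinson–Foulds is the size of the symmetric difference of the two
trees' non-trivial splits.  The Matching Split distance solves a
minimum-weight perfect matching (Hungarian algorithm via
`scipy.optimize.linear_sum_assignment`) between the two split sets,
where matching split A|B with C|D costs min(|A△C|, |A△D|); when the
trees have different numbers of splits (polytomies), the smaller set is
padded with virtual empty splits whose cost against A|B is min(|A|,|B|)
— TreeCmp's convention.  Both metrics unroot their inputs first.
Normalized MS divides by the Monte-Carlo mean MS between independent
random tree pairs on the same leaf count, under a Yule null (new leaves
attach to random pendant edges) or a uniform null (attachment to any
edge); the baseline is cached per (leaf count, null, sample count, seed).

## Synthetic data

The simulator draws root states from Π and evolves each branch by
P(t·r) where r is the site's rate category, drawn up front (0 for the
invariable class) and recorded in the output.  Branch lengths on
generated trees default to exponential with mean 0.1 substitutions/site
— a realistic scale for mitochondrial protein divergence within an
insect order — and all randomness flows from one seeded generator, so
runs are exactly reproducible.  The generator matches the likelihood
engine's model class by construction: no indels (gaps appear only via
taxon/gene mismatches in concatenation), no codon-level effects, no
site-specific profiles, and no compositional drift across the tree.
Passing recovery tests therefore demonstrate the correctness and
statistical efficiency of the estimator under its own assumptions, not
robustness to the ways real mitochondrial proteins violate them
(alignment error, heterotachy, saturated sites).

Problem sizes in the shipped tests and the acceptance script were
chosen to make each scientific claim measurable at desk scale: recovery
uses 60 taxa × 3000 sites split into four sub-datasets; model selection
uses 50 taxa × 2000 sites with five replicates; oracle comparisons use
≤4-leaf trees (exhaustive 20²-state enumeration) and 6–8-leaf trees
(factorial matching).

## Numerical choices and degenerate inputs

- Transition-matrix entries are clipped at zero after the
  eigendecomposition (round-off can produce −1e-16).
- Extreme-value queries break ties toward the smallest canonical index.
- Neighbor joining breaks Q-criterion ties toward the smallest index
  pair, making the tree deterministic on degenerate inputs.
- Identical sequences drive ML distances and branch lengths to the lower
  bound 1e-8; a training set of entirely identical sequences is rejected
  with a message asking for more divergent data.
- Frequency vectors whose printed values do not sum to one are
  renormalized on load; deviations beyond 0.05 raise a validation error.
- Model files are written at 17 significant digits, so write→read
  round-trips are bit-exact.

## Known limitations

- The registry carries only the seven classic published matrices plus
  mtOrt; the newer mitochondrial models (mtInv, mtMet, mtPan2013, mtDeu,
  mtPro) and the robustness variants mtOrt_O/C/E are not redistributed
  here, so comparisons against them require user-supplied model files.
- No FreeRate (+R) heterogeneity and no site-heterogeneous mixtures;
  "+I+G4" is the richest rate model.
- Tree search is NJ plus optional NNI hill-climbing — adequate for the
  bounded sub-dataset sizes the estimation loop creates, not a
  replacement for a dedicated tree-search program on large phylogenies.
- The mtOrt file reflects printed two-decimal precision (plus the two
  text-level extremes); statistics that depend on sub-0.005 structure of
  the unpublished full-precision matrix cannot be reproduced from it.
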