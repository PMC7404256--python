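# Methods

This note documents the models, algorithms and design choices behind
`sdtp`, in the spirit of the methods documentation of packages such as
statsmodels or scanpy: what is computed, under which assumptions, which
knobs matter, and what the synthetic benchmarks do and do not show.

## The multilayer model

A drug treating m diseases is associated with m weighted tissue-specific
gene interaction networks.  After restriction to the genes common to
all layers, the stack is a symmetric third-order tensor
`a[i, j, k] ∈ [0, 1]` with zero diagonal.  Edge weights are confidence
scores, not physical quantities; before stacking, each layer is rescaled
affinely so its minimum weight maps to 0.1 and its maximum to 1.0, which
makes layers with different score scales commensurable while preserving
within-layer ordering.  The 0.1 lower anchor (rather than 0) keeps every
retained edge strictly informative in sums.  Layer thinning keeps the
`ceil(f·|E|)` highest-weight edges per layer; the per-layer fraction f
is a user choice (real tissue networks need different fractions to reach
comparable densities, and no principled automatic rule exists), with
ties at the cutoff broken lexicographically on the gene pair so results
are reproducible.

## Recurrent heavy subgraph mining

A module is a gene set G and layer set L; its **heaviness** is the
summed weight of all edges internal to G across the layers of L,
`H = ½ Σ a[i,j,k] x_i x_j y_k` with indicator vectors.  Its **density**
`H / (C(|G|,2)·|L|)` is the mean weight over all internal edge slots —
a size-free quality measure in [0, 1].  The mining threshold is applied
to density (default 0.41): raw heaviness grows unboundedly with module
size and cannot serve as a fixed threshold in (0, 1], so the operating
parameter is interpreted as mean internal edge weight.  The default is
the operating point where, in threshold scans of the kind implemented
by `heaviness_scan`, the enriched-module ratio stabilizes while module
counts remain useful.

The solver alternates three deterministic phases:

1. **Continuous relaxation.**  From uniform positive x, y (restarts add
   bounded seeded noise), iterate the multiplicative updates
   `x_i ← g_i^{1/(p−1)} / ‖·‖` with `g_i = Σ_{jk} a_ijk x_j y_k` and
   `y_k ← h_k / ‖h‖` with `h_k = Σ_{ij} a_ijk x_i x_j`, until the
   relative change of the continuous heaviness drops below
   `convergence_tol` (1e−6) or `max_iterations` (200).  For the default
   sparsity exponent p = 2 this is a tensor power iteration; it
   concentrates x on the heaviest coherent subgraph and y on the layers
   where that subgraph recurs.  All-zero gradients terminate early, so
   an empty tensor yields no modules rather than an error.
2. **Discretization.**  For each layer prefix along the y ranking, two
   candidate families are evaluated: prefixes of the x ranking, and the
   greedy peeling family (repeatedly remove the gene with the smallest
   internal weighted degree).  Peeling is the classic dense-subgraph
   heuristic and covers optima that are not prefixes of the relaxation
   ranking.  Among all candidates meeting the size minimum (3) and the
   density threshold, the winner maximises the density-weighted
   heaviness `H^γ · density` with γ = `selection_exponent` (default 3).
   The exponent resolves a real tension: heaviness alone is monotone in
   module size, so maximising it pads modules with weak background
   genes, while density alone collapses to the tightest triangle.  At
   γ = 3 the rule recovers planted dense modules exactly (padding a
   dense module with background genes always lowers the score) while
   staying within a few percent of the maximum attainable heaviness on
   unstructured instances; both behaviours are enforced by the
   acceptance suite against an exhaustive-search oracle.  Ties anywhere
   are broken by gene/layer identifier, so output is bit-reproducible.
3. **Masking.**  The accepted module's internal entries are zeroed in
   its accepted layers only, and mining repeats.  Because genes are not
   removed, modules sharing a few genes remain discoverable (published
   module pairs do overlap, e.g. two genes shared between the two final
   modules of the packaged fixture).  Mining stops when a full round of
   restarts produces no qualifying candidate or `max_modules` is
   reached.

The miner is a heuristic: no global-optimality guarantee is made at
scale.  On instances small enough for exhaustive search (≤ 8 genes,
≤ 3 layers) the first module's heaviness is required, by test, to reach
at least 90 % of the global constrained optimum.

## Differential expression and concordance

Moderated statistics are deliberately out of scope; `log_fold_change`
is the plain difference of group means on the log2 scale.  A gene is
*concordant* when |logFC| exceeds a threshold (default 0, strict
inequality) in both the disease and the drug table.  Direction is not
compared by default — the underlying selection rule is
direction-agnostic — but `require_opposite_sign` implements the
pharmacologically common reversal hypothesis.  Genes absent from either
table are excluded, never imputed.

## Enrichment

Term enrichment is the hypergeometric upper tail P(X ≥ k) for a query
of size n against a term of size K in a background of size N, with
Benjamini–Hochberg adjustment across the tested terms (k ≥ 1) of one
namespace, significance at adjusted p ≤ 0.05.  This is a deliberate,
transparent replacement for web-service enrichment tools whose scores
depend on database versions; term identifiers are opaque (no ontology
graph traversal), and namespaces (BP / MF / CC / PATHWAY) are just
labels in the annotation table.

In the term-overlap filter, a module's overlap proportion with a
reference term set is computed per namespace as
|common significant terms| / |module's significant terms| (the
significant-terms reading of the denominator), and a module must reach
`min_proportion` (default 0.2) in all of BP, MF and CC.  A namespace
with no significant terms leaves the proportion undefined and drops the
module, with a logged reason.  The disease-term filter is a strict
conjunction: at least one shared significant term per namespace per
disease.

## Neighbour scoring and final ranking

A module's first-order neighbours are scored by total edge weight into
the module.  The retention threshold follows a sampling construction:
draw 1,000,000 neighbours uniformly *with replacement* (the sample size
far exceeds the neighbour count, so replacement is the only consistent
scheme), sort the scores descending and take the 50th value; neighbours
strictly above it are retained.  Retained neighbours are enriched
against the PATHWAY namespace, and modules are ranked by the total
count of pathways shared with the drug-target pathway set across
tissues; the pipeline keeps the top k (default 2).

## Permutation significance

The null model fixes the network topology and shuffles only the
edge-weight multiset over all edges (a global shuffle, not a
degree-preserving rewiring).  The p-value is the fraction of shuffles
whose internal weight sum reaches the observed one.  Two estimators are
provided: the plain count/n (which can report exactly 0, matching the
convention of reporting zero when no permutation reaches the observed
sum) and the pseudocount form (count+1)/(n+1), which is the exact
finite-sample-uniform estimator under exchangeability and is the one
used in calibration tests.  With i.i.d. continuous weights and a module
chosen independently of the weights, the pseudocount p-value is exactly
uniform on its discrete support — the property the calibration test
checks with a Kolmogorov–Smirnov test over 200 independent replicates
at n_perm = 500.  Default n_perm is 10,000 (standard-error ≈ 0.004 at
p = 0.25), configurable upward.

Co-expression networks connect module gene pairs with |Pearson r| above
a threshold (default 0.8; negative correlations count, since the sign
of co-regulation is not informative for rewiring) computed within one
condition's samples; at least 3 samples are required and zero-variance
genes are excluded with a warning.  The case/control comparison is a
plain partition of the edge union into case-only, control-only and
shared edges.

## Synthetic data: what it emulates, and what it does not

The generators produce inputs with the statistical structure the method
assumes:

* `simulate_multilayer` — background edges appear independently (default
  probability 0.1) with uniform weights in (0.05, 0.2); planted modules
  are complete subgraphs with uniform weights in (0.8, 1.0) on their
  designated layers.  The reference recovery configuration is 200 genes,
  3 layers, one 8-gene module — small enough to mine in under a second,
  large enough that the background dwarfs the module.  Contrast between
  planted and background ranges is enforced unless explicitly waived.
* `simulate_expression` — a single-factor model gives module genes a
  target pairwise correlation in case samples only; control samples and
  non-module genes are independent noise.  This mirrors the qualitative
  case/control rewiring the co-expression comparison is meant to expose.
* `simulate_logfc_tables` — concordant genes get nonzero logFC of random
  sign in both tables, all other genes are zero in at least one, so the
  planted set is recoverable exactly at threshold 0.
* `simulate_annotation` — planted terms annotate all of a module's genes
  plus ~1 % of a 500-gene background, a configuration whose
  hypergeometric tail is orders of magnitude below significance.

Uniform weight distributions were chosen for transparency over realism.
The generators do **not** reproduce the heavy-tailed degree
distributions of real tissue networks, correlated measurement noise,
batch structure, or annotation bias; passing the recovery benchmarks
therefore demonstrates algorithmic correctness under the stated model,
not performance on real networks, where weight miscalibration and
incomplete annotation dominate.

## Numerical and interface choices

* Density comparisons use an absolute 1e−12 slack so thresholds behave
  as closed bounds under floating-point arithmetic; the 2/3 overlap
  cutoff is compared exactly in integers (3·|A∩B| ≥ 2·min).
* Duplicate edges in input files keep the maximum weight; self-loops are
  dropped with a warning; edge-list and tensor serializations use
  shortest round-trip float representation, so write→read is bit-exact.
* The pipeline expands one global seed into per-stage seeds by a fixed
  offset scheme, so any stage can be rerun independently and a full
  rerun is byte-identical.
* Problem sizes in the test and acceptance suites (200-gene recovery
  instances, 50 oracle tensors, 200 calibration replicates, 10,000
  permutations) are chosen so each suite completes in seconds while
  leaving the statistical assertions well-powered.

## Known limitations

* The miner's quality guarantee is empirical-plus-tested on small
  instances only; adversarial tensors can defeat the two candidate
  families.
* Permutation p-values at n_perm shuffles cannot resolve below 1/n_perm;
  the plain estimator reports 0 there by design.
* Gene identifiers are compared as exact strings; no alias resolution
  or identifier mapping is performed.
* Enrichment treats terms as flat labels; ontology structure (term
  ancestry, redundancy) is ignored.
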