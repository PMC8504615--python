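# Methods

## Model

`rarebic` casts rare-subpopulation detection as a constrained
combinatorial optimization over a signed expression matrix
`M ∈ R^{|G|×|C|}` (genes × cells). A bicluster is a pair `(I, J)` of a
gene subset and a cell subset; its score is

```
f(I, J) = Σ_{i∈I} [ Σ_{j∈J} m_ij − κ · Σ_{k∈C\J} max(0, m_ik) ]
```

subject to the sparsity constraint
`#{(i,j) ∈ I×J : m_ij < 0} ≤ μ·|I|·|J|`.

Assumptions built into this formulation:

* **Sign encodes expression.** After `log10(x + pseudo)` with
  `pseudo = 0.1`, a positive entry means the raw value exceeded 0.9.
  Everything downstream (the penalty's `max(0,·)`, the prevalence
  filter, the μ constraint's strict `m_ij < 0`) keys off this zero
  point. Entries exactly zero are neutral: not expressed, not negative.
* **Sums, not profiles.** The objective is additive, so within-bicluster
  variation (transcriptional bursting, depth differences) is tolerated
  as long as the aggregate is high; no pairwise similarity is computed.
* **Dropout is expected.** The μ constraint allows a bounded fraction of
  negative entries inside the bicluster, so a true member cell that lost
  a few marker reads is not excluded.
* **Specificity is enforced, not assumed.** A gene expressed broadly
  outside the candidate cells pays the κ penalty and drops out of `I`.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `kappa` | `100/|C|` | weight of out-of-cluster positive expression; higher → fewer, more specific genes (∼20 selected genes is a practical target) |
| `mu` | 0.10 | allowed fraction of negative in-bicluster entries |
| `max_prevalence` | 0.25 | genes expressed in more than this fraction of cells are removed before the search |
| `pseudo` | 0.1 | pseudo-count of the log transform; implies raw threshold `1 − pseudo` |
| `beam_width` | 100 | frontier size of the breadth-first search |
| `patience` | 2 | levels without frontier improvement before stopping |
| `min_cells` / `max_cells` | 2 / `|C|` | bicluster size bounds on the cell axis |

All are dimensionless; counts are raw (unnormalized) transcript counts.

## Gene selection for a fixed cell set

The objective is additive over genes, so with the constraint relaxed
(μ = 1) the optimum over genes is exactly the genes with strictly
positive gain `g_i = in_sum_i − κ·out_pos_i` — computed in linear time.
Zero-gain genes are excluded (they add nothing and consume μ budget);
negative-gain genes are never included even though they could in
principle buy μ budget for others — this keeps selection gene-separable
and linear, at a cost that the exact branch-and-bound mode
(`exact_genes`, intended for ≤ ~20 candidate genes) quantifies on small
instances in the test suite.

Under μ < 1 the default heuristic sorts positive-gain candidates by
ascending negative count (ties: descending gain, then input order) and
returns the longest feasible prefix. Prefix means of a sorted sequence
are non-decreasing, so prefix feasibility is monotone and the longest
feasible prefix is well defined; the selection never violates the
constraint. Tie-breaking is deterministic everywhere so runs are
reproducible.

## Search over cell subsets

Because genes are optimized per cell set, only cell subsets are
enumerated (`O(|G|·2^|C|)` implicit search space). The solver is a
breadth-first beam search: level 2 scores every pair of cells; each
later level extends only the `beam_width` best frontier sets by one cell
(supersets only), de-duplicating canonical sorted index tuples.
Candidates whose gene selection is empty stay in the frontier with
objective 0 — a superset may still be valid — but are never reported as
solutions; with an unlimited width the search therefore degenerates to
an exact enumeration, which is how it is validated against the
exhaustive oracle. Per-gene statistics of a child set are the parent's
plus one column (`out_pos = total_pos − in_pos`), so candidate
evaluation is incremental; tests confirm identity with from-scratch
recomputation. The search stops when the frontier's best objective has
not improved for `patience` consecutive levels, the level exceeds
`max_cells`, or the frontier is empty. The stopping rule and the fixed
top-`beam_width` cut are design choices of this package: the objective
distribution at a level is heavy-tailed in practice and only its head is
worth expanding.

The exhaustive solver enumerates all admissible cell subsets (guarded to
|C| ≤ 20), breaking ties toward smaller, lexicographically earlier cell
sets; the beam search uses the same tie-breaks so that agreement can be
checked exactly. Both solvers use the same gene-selection mode, so
oracle comparisons isolate the cell-subset search.

The top-k strategy removes a found bicluster's cells, re-applies the
gene prevalence filter to the remaining cells (the follow-up search
should see the same preconditions as the first), and repeats. Blocks
are returned in discovery order, which is descending objective order
whenever the blocks differ in score. Returned cell sets are pairwise
disjoint by construction; gene sets may overlap.

## Simulation design

`PlantedDesign` emulates a controlled spike-in experiment: `n_cells`
cells of which `n_rare ≥ 5` form a planted subpopulation, `n_genes`
genes of which `n_markers` are dedicated markers. Counts are negative
binomial with mean `marker_mean` (default 20) and dispersion
`nb_dispersion` (default 2), a standard minimal model of scRNA-seq
counts. Markers are expressed in every planted cell, zeroed
independently with probability `dropout`, and fire spuriously in
background cells with probability `background_rate`. Background genes
are expressed in a random `background_sparsity` (default 5%) of cells,
so after log-normalization the matrix is predominantly negative, as
real filtered scRNA-seq data is.

Each planted subpopulation additionally carries `n_accessory` (default
30) genes expressed in only 2–3 of its cells and nowhere else. This
mirrors a property of real cell types that matters for the search:
beyond uniform markers, member cells share bursty, partially penetrant
programs. These genes are what make *small subsets* of the
subpopulation stand out at early search levels — for a pair of planted
cells the uniform markers are penalized by the remaining planted cells,
which at that point sit out-of-cluster — and without them a level-wise
search faces an unrealistically adversarial instance. The accessory
genes do not change the optimum: with support 2 their in-block gain is
negative and they are not selected at the full block, which remains
exactly the planted cells (verified against the exhaustive oracle on
small instances).

Default problem sizes used throughout the tests and the acceptance
script — 1 000 genes and 50–200 cells, 10 runs per condition — are
scaled-down versions of a typical experiment (tens of thousands of
genes); the search cost per candidate is linear in genes, so the scaling
affects runtime, not behaviour. Per-run seeds derive from the master
seed as `seed + run_index`.

What passing these simulations does **not** show: robustness to
per-cell depth variation (the generator draws i.i.d. counts; the method
assumes count-comparable cells), to correlated background structure
(e.g. cell-cycle programs in the background population), or to real
dropout processes, which are gene- and expression-dependent rather than
i.i.d. Bernoulli.

## Evaluation metrics

Recovery of a planted subpopulation is scored by precision
(fraction of reported cells that are planted), recall (fraction of
planted cells reported) and their harmonic mean F1; an empty prediction
scores (0, 0, 0). When several candidate biclusters are reported
(top-k), the candidate with the highest precision — ties broken by
recall — is taken as the run's solution, matching the convention that
the cluster with the highest proportion of true cells is the answer.
Aggregates count runs with 100% precision (solution ⊆ truth) and with
exact recovery (solution = truth).

## Numerical choices and degenerate inputs

* Feasibility comparisons use a `1e-9` absolute slack on the μ budget to
  absorb float accumulation; objective comparisons in tests use exact
  or `1e-9` tolerances since all arithmetic is plain sums.
* An all-negative (or all-filtered) instance yields an explicit
  no-solution result, not an exception; the CLI exits 0 and reports an
  empty result list.
* Matrices with NaN/Inf, duplicate names, or negative "raw" counts are
  rejected at the boundary with specific errors.
* Re-normalizing an already signed matrix is refused unless forced,
  since a double log transform silently corrupts the sign structure.
* The prevalence boundary is inclusive (a gene at exactly 25% is kept),
  and "expressed" means strictly positive.

## Known limitations

* The constrained gene selection is heuristic (longest feasible
  prefix); the exact mode exists only for small candidate counts. The
  heuristic can under-select when a high-gain gene carries many
  negatives.
* The beam search is a heuristic over cell subsets: with the default
  width it matched the exhaustive oracle on ≥ 95% of small random
  instances, but no optimality guarantee exists at scale.
* Complexity is `O(beam_width·|C|²)` candidate evaluations, each
  `O(|G| log |G|)`; practical up to ~1 000 cells, beyond which the
  level-wise frontier becomes the bottleneck.
* One matrix, one sample: batch structure across samples is not
  modelled.
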