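# Methods

## Model

`guidedcoc` operates on three non-negative cells × features matrices that
share one gene vocabulary: the target scRNA-seq matrix `R_t`, a target
gene-activity matrix `A_t` derived from scATAC-seq and row-paired with
`R_t` (same cells, same order), and an unpaired source scRNA-seq matrix
`R_s` with a known, fixed cell clustering `C_X`. Each matrix is normalized
by its grand total into an empirical joint distribution over (cell,
feature) indices; because all downstream quantities are functionals of
these probabilities, the method is insensitive to sequencing depth and no
per-cell scaling is applied.

For one matrix, a pair of hard clusterings `(C_Y, C_Z)` induces the
coarse-grained joint `P̃(Ỹ, Z̃)` (block sums of `P`) and the reference

    P*(y, z) = P̃(Ỹ, Z̃) · [P(y)/P̃(Ỹ)] · [P(z)/P̃(Z̃)].

`P*` carries only the cluster-level dependence while preserving the exact
row and column marginals of `P`; the co-clustering loss `D_KL(P ‖ P*)`
equals the mutual-information deficit `I(Y;Z) − I(Ỹ;Z̃)`. Both facts are
enforced as test invariants (to 1e-10) rather than assumed.

The Stage-1 objective weights three such losses:

    L(C_Y, C_Z) = L_Rt + α·L_At + β·L_Rs(C_Z | C_X),

with `C_Y` shared by the two target matrices and `C_Z` shared by all
three. Conventions: natural logarithms everywhere in Stage 1 (losses are
only compared, never thresholded), `0·log(0/x) = 0`, and no pseudocounts —
the normalization operates on raw values.

## Optimization

One iteration is: a synchronous sweep assigning every target cell to the
cluster minimizing its weighted conditional KL cost (references taken from
the pre-sweep state), a refresh of the coarse statistics, the analogous
synchronous sweep over features (cost summed over `R_t`, `A_t`, and `R_s`,
the latter with rows clustered by `C_X`), and another refresh. Per-item
costs drop additive terms that do not depend on the candidate cluster, so
a sweep reduces to one dense matrix product between the cluster-aggregated
joint and the log conditional cluster profiles — `O(nnz·(N+K))` per
iteration. Ties in the argmin go to the lowest cluster index, which makes
runs bit-reproducible.

Cluster counts are fixed, so a sweep that empties a cluster triggers a
repair: the item with the largest current conditional-KL contribution is
donated to the empty cluster. Moving an item into an empty cluster splits
its former cluster — a refinement — and refinements never increase the
loss, so the repair preserves descent.

The loop stops when the relative objective change falls below `tol`
(default 1e-6, ceiling 30 iterations). Batch sweeps converge to a fixed
point of their own dynamics, which is not necessarily a local minimum of
the objective under single reassignments (the sweep evaluates candidates
against pre-sweep references). A polish phase therefore follows: exact
single-move descent, alternating over cells and features, until no move
improves the objective. Moving one item only changes the coarse joint and
one pair of its cluster marginals, so each candidate delta costs `O(K)`
(or `O(N)` for features); moves that would empty a cluster are skipped
since merging partitions can never decrease the loss. The polish is
deterministic (items in index order, strict-improvement threshold 1e-12)
and typically relocates only a handful of boundary items, but it
guarantees the converged state is a genuine local minimum — a property
the test suite checks exhaustively on small instances.

Initialization defaults to seeded k-means: cells on the log2(1+x) target
RNA profiles, features on their source-cluster conditional profiles
`P_Rs(X̃ | z)`, which groups genes by how their signal distributes across
the known source populations. A `random` mode (seeded, every cluster
guaranteed non-empty) is kept for ablations, and `provided` accepts
validated user labels.

Defaults follow the method's empirical setting: `K = 12` feature clusters,
`α = 0.8`, `β = 1`. Sensitivity is mild — performance is flat over broad
ranges of `α` and `β`, and `β = 0` or `α = 0` degrade gracefully to the
corresponding ablated models, which the tests exercise as reductions.

## Cross-domain matching

After Stage 1, each source cluster `i` and target cluster `j` is
summarized by the normalized aggregate feature profile of its cells
(profiles are taken over the raw shared genes, not the K feature
clusters, to preserve resolution; target profiles use the RNA modality
only, so source and target are compared like with like). The pair score
is the averaged Jensen-Shannon divergence: base-2 JSD — bounded in
[0, 1] — between profiles recomputed from random subsamples of 80% of
each cluster's cells (without replacement, floor one cell), averaged over
`n_trials = 25` trials. Subsampling makes the distance stability-aware:
pairs whose similarity hinges on a few cells score worse.

Matching is exclusive and threshold-filtered: only pairs with
AJSD < `τ_JSD = 0.45` are eligible. The AJSD matrix is computed once;
`n_shuffles = 25` seeded permutations of the target-cluster order each
yield a greedy assignment (each target cluster claims the closest
unmatched source cluster), and the configuration with the smallest total
AJSD wins, ties broken toward more matches. Greedy passes always produce
maximal matchings, so the exhaustive minimum-total maximal matching is a
lower bound; the tests compare against that oracle and surface (as a
warning, with the instances listed) the occasional adversarial random
matrix where no greedy order attains it. An empty match set is a legal
outcome — domains need not share populations.

## Preprocessing

Highly variable genes are selected on the source matrix: dispersion
(variance/mean) is z-scored within 20 equal-count bins of mean expression
and the top 2500 genes are kept. All-zero cells are excluded from the
moment computation, making the ranking invariant to padding with empty
cells. Note the z-score of a lone outlier saturates near `sqrt(m)` for a
bin of `m` genes, so very small feature sets blunt the ranking; the tests
use several hundred features per run for this reason.

Gene-activity scores aggregate peak counts over each gene's body plus a
2-kb upstream promoter window (strand-aware, clipped at zero); any
nonzero overlap counts, with no distance weighting. Coordinates are
0-based half-open internally; GTF input is converted on read. Expression
and activity values are log2(x+1)-transformed before fitting; the
container records the transform so accidental double application raises.

Cross-species runs supply a two-column homolog table; only one-to-one
pairs are used, aligned target columns are renamed into the source
vocabulary, and genes with zero signal in any matrix are dropped and
reported.

## Synthetic data

The generator plants the structure the model assumes: cells belong to
populations, genes to modules, and the expected count depends only on the
(population, module) block. Shared populations reuse the same block-mean
row in both domains; private populations get fresh rows. Counts are
Poisson (negative binomial via a gamma-mixed rate when `noise > 0`),
zero-inflated at the `dropout` rate after the draw; the ATAC matrix is a
paired re-draw from block rates jittered per (population, module) by a
mean-one log-normal factor with scale `atac_distortion`. Default
conditions — 500/800 cells, 400 genes, five shared populations, twelve
modules at 3× contrast, 70% dropout, distortion 0.5 — describe a
mid-sized, realistically sparse experiment. `target_dropout` /
`target_noise` override the shared values to build clean-source /
noisy-target transfer scenarios.

What the generator does not emulate: batch effects beyond the ATAC
distortion, per-cell library-size variation, doublets, gene-gene
correlation within a module, or fragment-level ATAC structure. Passing
recovery tests on these data shows the optimizer finds planted block
structure under heavy sparsity; it does not certify performance on real
tissues, where cluster boundaries are fuzzier than any block model.

## Problem sizes and numerical choices

The test suite and the acceptance script run at deliberately moderate
scale, chosen so the full battery exercises every guarantee in minutes:
identity checks on random joints up to 20×20 (tolerance 1e-10); descent
and exhaustive local-optimality on 50 triples at n = q = 12; convergence
and recovery on 20 triples of up to 800 cells × 400 genes. The optimizer
itself is vectorized and handles tens of thousands of cells; nothing in
the implementation is specific to the test sizes.

Degenerate inputs: all-zero matrices are rejected at construction;
features with zero total signal are dropped during alignment; a cell with
zero mass in one modality contributes nothing to that modality's cost and
is placed by the other's (a cell empty in both falls to cluster 0 by the
tie-break). Cluster counts are validated against matrix dimensions at
initialization.

## Known limitations

- Stage 1 finds local minima; quality depends on initialization. Seeded
  k-means is markedly better than random starts (tested), but no
  multi-restart consensus is attempted.
- The shuffled-greedy matcher is a heuristic; a Hungarian-style exact
  assignment is kept only as a test oracle.
- `N_t` and `K` are user-supplied; there is no model-selection machinery.
- Sweeps are single-threaded; the synchronous semantics would admit a
  bit-identical parallel map, but none is implemented.
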