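# guidedcoc

Guided information-theoretic co-clustering for single-cell multi-omics.

Paired scRNA-seq/scATAC-seq ("multiome") experiments profile gene
expression and chromatin accessibility in the same single cells, but both
modalities are sparse and noisy, and high-quality paired datasets are
scarce. Large unpaired scRNA-seq references, by contrast, usually carry
robust, biologically meaningful cluster structure. `guidedcoc` transfers
that structure: it jointly co-clusters the cells and features of a paired
target dataset while a cluster-annotated, unpaired scRNA-seq source
dataset guides the shared feature clustering — and then matches cell
populations across the two domains without requiring any label
correspondence.

## The model

Each non-negative cells × features matrix is normalized to an empirical
joint distribution `P(Y, Z)` over (cell, feature) indices. A pair of hard
clusterings — `C_Y` over cells, `C_Z` over features — defines a
coarse-grained joint `P̃(Ỹ, Z̃)` and a reference distribution

    P*(y, z) = P̃(Ỹ, Z̃) · [P(y)/P̃(Ỹ)] · [P(z)/P̃(Z̃)],

and the co-clustering loss of one matrix is `D_KL(P ‖ P*)`, which equals
the mutual information lost by coarse-graining, `I(Y;Z) − I(Ỹ;Z̃)`.

**Stage 1** minimizes, over `(C_Y, C_Z)`,

    L = L_Rt(C_Y, C_Z) + α · L_At(C_Y, C_Z) + β · L_Rs(C_Z | C_X)

where `R_t` is the target RNA matrix, `A_t` the row-paired gene-activity
matrix derived from ATAC peaks (same cells, same gene vocabulary), and
`R_s` the source RNA matrix whose cell clustering `C_X` is known and held
fixed. The shared feature clustering `C_Z` is the conduit through which
the source's structure stabilizes the target's cell clustering.
Optimization is block-coordinate descent: a synchronous sweep reassigning
every cell to its minimum-conditional-KL cluster, then the analogous sweep
over features (whose cost sums across all three matrices), iterated to
convergence and finished with an exact single-move descent so the result
is a true local minimum. Defaults: `K = 12` feature clusters, `α = 0.8`,
`β = 1`.

**Stage 2** summarizes every source cluster and learned target cluster by
its normalized feature profile and scores each pair by the averaged
Jensen-Shannon divergence (AJSD): the mean base-2 JSD over 25 random 80%
subsamples of each cluster's cells. Pairs below `τ_JSD = 0.45` are
eligible; exclusive one-to-one matches are chosen greedily over 25 random
permutations of the target-cluster order, keeping the configuration with
the smallest total AJSD. Populations private to one domain simply remain
unmatched.

## Worked example

```python
import numpy as np
from guidedcoc import (SyntheticSpec, Stage1Config, MatchConfig,
                       default_block_means, generate, fit, match, ari)

spec = SyntheticSpec(n_source=300, n_target=400, q=200,
                     n_source_clusters=4, n_target_clusters=4, k_features=8,
                     dropout=0.6, atac_distortion=0.4, seed=0,
                     block_means=default_block_means(4, 8, contrast=3.0))
R_s, R_t, A_t, cx, planted_cy, planted_cz = generate(spec)

cfg = Stage1Config(n_target_clusters=4, k_features=8, alpha=0.8, beta=1.0, seed=0)
res = fit(R_t, A_t, R_s, cx, cfg)
print(f"converged in {res.n_iter} iterations; final objective {res.objective_trace[-1]:.4f}")
print(f"ARI vs planted labels: {ari(res.state.cy.labels, planted_cy.labels):.3f}")

m = match(R_s, R_t, cx, res.state.cy, MatchConfig(seed=0))
for i, j, a in m.matches:
    print(f"source cluster {i} <-> target cluster {j}  (AJSD = {a:.4f})")
```

Output:

```
converged in 7 iterations; final objective 3.6323
ARI vs planted labels: 1.000
source cluster 0 <-> target cluster 0  (AJSD = 0.0153)
source cluster 1 <-> target cluster 1  (AJSD = 0.0167)
source cluster 2 <-> target cluster 2  (AJSD = 0.0165)
source cluster 3 <-> target cluster 3  (AJSD = 0.0149)
```

The synthetic triple plants four cell populations shared between domains,
with 60% dropout and a distorted ATAC modality; the fit recovers the
planted cell clusters exactly (ARI 1.0) and Stage 2 re-identifies every
shared population with near-zero divergence, well below the 0.45
acceptance threshold.

The same pipeline runs from the shell:

```sh
guidedcoc simulate --out-dir sim --seed 0
guidedcoc run --source sim/R_s.mtx --target-rna sim/R_t.mtx \
    --target-activity sim/A_t.mtx --cx sim/cx.tsv \
    --ground-truth sim/planted_cy.tsv --n-clusters 5 --out-dir out
guidedcoc evaluate out/cell_clusters.tsv sim/planted_cy.tsv
```

`guidedcoc run` also accepts a peak-by-cell matrix plus BED/GTF gene
annotations in place of `--target-activity`; gene-activity scores are then
computed from the gene body plus a 2-kb upstream promoter window. Real
matrices are reduced to 2500 source-selected highly variable genes and
log2(x+1)-transformed before fitting (see `docs/methods.md`).

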