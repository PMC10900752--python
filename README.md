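# scmet

**scmet** converts bulk RNA-seq profiles into scRNA-seq-like expression
matrices. It is aimed at researchers who have large bulk cohorts (e.g. TCGA
tumor collections) plus a much smaller labelled single-cell reference, and
who want per-sample pseudo-single-cell matrices that downstream single-cell
toolchains (Scanpy, Seurat) can consume.

## Method

The pipeline has four stages:

1. **Reference QC.** The single-cell reference is filtered with the usual
   per-cell criteria (cells with fewer than 200 detected genes or a
   mitochondrial count fraction above 10% are removed; genes must be
   expressed in ≥ 3 cells) and de-doubleted with a simulation-based scorer
   (expected doublet rate 0.05, cells scoring > 0.3 removed). Expression is
   normalized to log1p CP10K: `x = ln(1 + 10^4 · c / depth)`.

2. **Conditional VAE.** A conditional variational auto-encoder is trained
   on the normalized reference: encoder `[x ; one-hot(type)] → 512 → 256 →
   (μ, log σ²)` with a 64-dimensional latent space, mirror decoder with a
   softplus output, loss `‖x̂ − x‖² + β·KL(q(z|x,y) ‖ N(0, I))` with
   β = 0.5, Adam, early stopping on a validation split. Sampling
   `z ~ N(0, σ_scale²·I)` and decoding with a cell-type condition generates
   new cells of that type; `σ_scale` tunes the dispersion of the generated
   population.

3. **Deconvolution.** Per-type marker genes (one-vs-rest log2 fold change,
   top *k* per type, default 25) define a signature matrix **S** of mean
   CP10K expression. For each bulk sample **b** (library-size scaled), the
   proportions **p** solve `min ‖S·p − b‖₂` subject to `p ≥ 0` (NNLS),
   renormalized onto the simplex.

4. **Selection fitting.** The target cell count is apportioned to types by
   largest remainder, a candidate pool of generated cells is drawn per type
   (`pool_factor ×` the allocation), and a seeded hill climb cyclically
   swaps per-type batches, accepting a swap only when it strictly improves
   `J = r(b, pseudobulk) − λ·d(b, pseudobulk)` — Pearson correlation minus
   λ times the Euclidean distance of the L2-normalized vectors (λ = 0.1).
   Selected cells across samples are concatenated into one cohort matrix
   with per-cell sample and type metadata.

A fully seeded synthetic-data module (negative-binomial multi-type
references with planted markers, injected cross-type doublets, multinomial
pseudo-bulk of known composition) closes the loop so every stage is
testable without external data.

## Worked example

```python
import numpy as np
import scmet

# 1. labelled reference: 3 cell types, 1,278 cells, 200 genes
cfg = scmet.SimConfig(n_types=3, n_genes=200, cells_per_type=426, seed=3)
ref, truth = scmet.simulate_reference(cfg)
norm = np.asarray(scmet.normalize_log1p(ref.counts).todense())

# 2. train the conditional VAE
model, trace = scmet.train_cvae(norm, ref.labels, gene_list=ref.genes,
                                max_epochs=60, random_state=0)

# 3. a bulk sample of known composition (60/30/10)
bulk, _ = scmet.simulate_bulk(truth, {"typeA": 0.6, "typeB": 0.3, "typeC": 0.1},
                              depth=1_000_000, seed=10, sample_id="s0")

# 4. convert it into 500 fitted single cells
cohort = scmet.fit_cohort([bulk], model, norm, ref.labels,
                          config=scmet.CohortConfig(cells_per_sample=500,
                                                    pool_factor=10, seed=7))
```

This prints (via the obvious `print` calls):

```
training loss: 776.2 -> 180.0 over 60 epochs
estimated proportions: {'typeA': 0.62, 'typeB': 0.285, 'typeC': 0.096}
fit: r = 0.9703, d = 0.1104, 500 cells, allocation {'typeA': 310, 'typeB': 142, 'typeC': 48}
```

The training loss falls by a factor of ~4; deconvolution recovers the true
(0.60, 0.30, 0.10) mixture to within 0.02; and the selected 500 cells form a
pseudo-bulk correlating at r = 0.97 with the input bulk profile. The fitted
cells live in `cohort.matrix` with `cohort.sample_ids` / `cohort.cell_types`
metadata, and `out_dir=` writes a Matrix Market bundle plus
`cell_metadata.tsv` and `fit_report.json`.

The same pipeline is available from the shell:

```bash
scmet simulate reference --out ref/ --seed 3
scmet qc --input ref/ --out qc/ --min-genes 50 --seed 1
scmet train --input qc/ --checkpoint model.npz --epochs 60 --seed 0
scmet deconv --bulk bulk.tsv --reference qc/ --out dec/
scmet fit --bulk bulk.tsv --checkpoint model.npz --reference qc/ \
          --cells-per-sample 500 --out fitted/
```

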