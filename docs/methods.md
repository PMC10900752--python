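# Methods

This note documents the models, the parameters that matter, the numerical
choices, and what the synthetic benchmarks do and do not demonstrate.

## Quality control

Cell filtering uses two per-cell statistics: the number of detected genes
and the fraction of counts on mitochondrial genes (identified by the
case-insensitive `MT-` prefix, overridable by an explicit gene list).
Boundary semantics are strict: a cell with exactly `min_genes` (default
200) detected genes is kept, a cell with mito fraction exactly `max_mito`
(default 0.10) is kept. Gene filtering keeps genes with nonzero counts in
at least `min_cells` (default 3) cells. Filters run in the order cells →
genes → doublets; both cell- and gene-filters are idempotent and preserve
input order.

The doublet scorer synthesizes artificial doublets by summing the raw
counts of random observed cell pairs (`sim_ratio` = 2 simulated per
observed cell), embeds observed + simulated cells by PCA (30 components on
log-normalized top-1000 HVGs, PCA fit on observed cells only), and scores
each observed cell by the fraction q of simulated doublets among its
k = ⌈0.5·√n⌉ nearest neighbors. q is smoothed as `(s+1)/(k+2)` and
calibrated into a posterior-like score using the expected doublet rate ρ
(default 0.05) and the simulated/observed ratio r:
`score = (q·ρ/r) / (1 − ρ − q·(1 − ρ − ρ/r))`, clipped to [0, 1]. Cells
scoring strictly above 0.3 are removed. The calibration maps the
chance-level neighbor fraction r/(1+r) to ≈ ρ and a pure-doublet
neighborhood to ≈ 1, so the 0.3 threshold is conservative on clean data.
The scorer is deliberately self-contained (no external doublet package) so
the whole pipeline is reproducible from the standard scientific stack.

Normalization is log1p CP10K throughout: signatures, generated cells and
bulk vectors all share this space unless stated otherwise. HVG selection
ranks genes by binned standardized dispersion (variance/mean of
log-normalized expression, z-scored within 20 mean-expression bins);
constant genes are excluded outright, ties resolve to the earlier gene.

## Conditional VAE

Architecture: encoder `[x ; one-hot(y)] → 512 → 256 → (μ, log σ²)`,
latent dimension 64; decoder mirrors (`[z ; one-hot(y)] → 256 → 512 →
genes`) with a softplus output so decoded expression is nonnegative.
log σ² is clipped to ±15 for numerical stability. Loss per batch is the
summed-over-genes squared reconstruction error plus β times the
summed-over-latents KL divergence from N(0, I), both averaged over the
batch; β = 0.5 by default. Squared error on log-normalized expression is a
deliberate choice: the generator's job here is to reproduce per-type mean
profiles and their dispersion in normalized space, not the raw count
likelihood, and it keeps the model free of a dispersion parameter the
selection stage would never use.

Optimization: Adam (lr 1e-3, batch 128), validation fraction 0.1, early
stopping with patience 10 on a deterministic validation loss (decoded
posterior mean, no sampling noise), up to `max_epochs` (default 200; the
benchmark fixtures use 60, which is past the loss plateau at their scale).
The kept weights are the validation optimum, so the selected checkpoint is
never worse than epoch 1 on validation. Everything — split, shuffling,
initialization, reparameterization noise — flows from one seed, making
training bit-reproducible on a given platform. The whole model is plain
numpy with hand-written gradients; at the scales the package targets
(10²–10⁴ cells, a few thousand genes) a CPU trains it in seconds to
minutes, and the absence of a framework dependency keeps installation
trivial.

Generation draws `z ~ N(0, σ_scale²·I)` and decodes with the requested
label. σ_scale is the dispersion control: 0 yields the deterministic
per-type archetype, larger values spread the generated population (the
mean pairwise distance grows monotonically in σ_scale on all fixtures).
The interpretation of the dispersion knob as the latent prior scale is a
design choice; an alternative would be additive output noise, but latent
scaling preserves the decoder's learned manifold and keeps generated cells
realistic at every scale. Candidate pools are built per label with
sub-seeds spawned from the master seed in vocabulary order, so a label's
cells do not depend on which other labels are requested.

`evaluate_generation` reports per-type Pearson correlation between mean
real and mean generated expression plus a marker-concordance score (the
fraction of each type's top-20 real markers found among the generated
type's top-100). The choice of σ_scale is left to the user, guided by
these metrics.

## Deconvolution

Markers are ranked per type by one-vs-rest log2 fold change of mean CP10K
expression with a pseudocount of 1, restricted to genes expressed in at
least 10% of the type's cells (a Wilcoxon rank-sum ranking is available
behind `method="wilcoxon"`). Default 25 markers per type; an oversized k is
capped with a warning. The signature matrix is the per-type mean expression
of the marker union.

The NNLS solve runs in **linear CP10K space** by default. This is the one
substantive departure from the otherwise log-normalized pipeline, and it is
deliberate: a bulk mixture is a (depth-weighted) linear combination of
cell-type mean profiles, so the linear model is the one under which the
least-squares estimator is unbiased. In log space, `log1p` of a mixture is
not the mixture of `log1p` signatures, and on the standard 3-type fixture
the induced bias is ~0.06 mean absolute error in recovered proportions —
an order of magnitude worse than the ~0.002 the linear solve achieves at
depth 10⁶. A log-space mode (`space="log"`) is retained for comparison.
Either way the bulk vector is library-size scaled before the solve, so
proportions are invariant to the bulk's sequencing depth or unit scale,
and estimates are renormalized onto the simplex (NNLS does not constrain
the sum). Since the simplex is a subset of the NNLS feasible set, the NNLS
residual is never worse than the best simplex point, which the tests
verify against a 0.02-step grid-search oracle.

## Selection fitting

Cell counts per type come from largest-remainder apportionment of the
estimated proportions (floors plus leftover seats by descending fractional
part, earlier type first on ties). The candidate pool holds
`pool_factor × allocation` generated cells per type (default 10×). The
hill climb starts from a seeded random selection honoring the allocation
and cycles over types, proposing to replace a random `⌈swap_batch ·
alloc⌉`-cell subset (default 10%) with unused same-type pool cells; a
proposal is accepted only if it strictly improves `J = r − λ·d` (λ = 0.1;
λ = 0 reduces to pure correlation). Stopping: `max_rounds` (20) full
cycles, or `patience` (3) consecutive cycles without improvement. The
pseudo-bulk is maintained incrementally as a running sum, so a proposal
costs one similarity evaluation. Selection is without replacement within a
sample; samples are independent, each with its own sub-seed.

Consequences that hold by construction and are asserted in tests: the
accepted-step objective trace is strictly increasing, the final selection
is never worse than the initial one, and the per-type composition always
equals the allocation exactly.

## Synthetic data

The simulator draws per-gene baseline means from lognormal(0, 1), gives
each type a disjoint block of `marker_frac · n_genes` planted markers
up-regulated by `2^marker_lfc` (default 8-fold), and scales a
`mito_gene_frac` block of `MT-`-named genes to a fixed 3% share of each
type's expected counts (comfortably under the 10% QC cut, so only
deliberately manipulated cells fail it). Per-cell depths are lognormal
(median 2,000 counts, log-sd 0.3); counts are gamma-Poisson with
`var = m + φ·m²`, φ = 0.3. Injected doublets are cross-type pair sums
(`⌈rate·n⌉` of them); same-type doublets are excluded from the default
oracle because they are near-indistinguishable by construction. Pseudo-bulk
samples are single multinomial draws at a chosen depth from a known mixture
of the per-type mean profiles.

Benchmark scales: the reference fixtures use 3 types × 426 cells = 1,278
cells and 200 genes — the small-sample regime the generator is expected to
handle — with 60 training epochs, 500 cells per fitted sample and a 10×
pool; these sizes exercise every code path while keeping the full suite in
the tens of seconds. What passing does **not** show: the simulator has no
batch effects, no ambient RNA, no gene-gene correlation structure beyond
the type means, and markers are cleanly disjoint; real references are
noisier in all four respects, so real-data proportions and fit
correlations will be below the synthetic ones. The closed loop
demonstrates internal consistency of the machinery, not field performance.

## Degenerate inputs and tie-breaking

Zero-depth cells are rejected at normalization with a pointer to filtering.
Zero-variance vectors make the Pearson correlation undefined and raise. All
ranking operations (HVGs, markers, apportionment) break ties by input
order via stable sorts, so results are platform-independent given a seed.
Checkpoints verify both a blob digest and a gene-list/label-vocabulary
hash on load, and refuse mismatched sidecars rather than generating from a
silently inconsistent model.
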