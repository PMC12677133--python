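# Methods

## Model and procedure

`trajrank` treats a maturing cell population as points along a single
latent axis and asks which genes' expression trajectories track a chosen
reference gene. The procedure is: quality control → depth normalization →
embedding → diffusion pseudotime → trajectory binning → four count forms
→ RMSE ranking → onset/enrichment scoring → evidence overlays. Branching
trajectories are deliberately out of scope: the target lineage
(GBC → INP → iOSN → mOSN) is linear, and no branch detection is
attempted.

### Quality control and normalization

Cells are scored by total counts and mitochondrial fraction
(`mito_frac = mito counts / total counts`, defined as 0 for empty cells,
which are flagged). Defaults `max_mito = 0.2` and `min_counts = 500` are
conventional starting points for droplet data rather than derived
quantities; both are explicit in the config and logged on every run.
Counts are scaled to 10,000 per cell and log1p-transformed ("logarithmized
counts" means log(1+x) of the depth-normalized counts, the standard
single-cell convention). Noise genes (prefixes `mt-`, `Malat`) are removed
globally. Odorant-receptor genes (prefixes `Olfr`, `Or<digit>` — the digit
prevents swallowing symbols like Orc2; a whitelist overrides both) are
masked out of the embedding only, because their mutually exclusive
one-per-cell expression would otherwise dominate the neighbor graph, but
they stay in the trajectory/ranking tables.

### Highly variable genes

Dispersion (variance/mean of normalized counts) is z-scored within 20
mean-expression quantile bins and the top `n_hvg` (default 1,000) genes
are kept. Zero-variance genes score −∞ and can never displace a varying
gene; residual ties break on gene symbol for determinism.

### Diffusion pseudotime

PCA (default 40 components, genes centered and unit-scaled, full SVD so
results are deterministic) feeds a kNN graph (k = 10, Euclidean,
symmetrized by union). Edge weights use an adaptive Gaussian kernel,
`w_ij = exp(−d_ij² / (σ_i σ_j))` with σ_i the distance to the ⌈k/2⌉-th
neighbor, giving weights in (0, 1]. The kernel is density-normalized on
both sides (anisotropy exponent 1), the transition operator is
row-normalized, and eigenpairs come from its symmetric conjugate via a
Lanczos solver started from the all-ones vector (no randomized
initialization anywhere). The largest *algebraic* eigenvalues are
requested: the operator carries substantial negative spectrum (oscillatory
modes) that a largest-magnitude query would return instead. The stationary
eigenpair is dropped, eigenvectors are mapped back to right eigenvectors
of the transition operator (ψ = D^(−1/2) v), unit-normalized, and
sign-fixed by making the largest-magnitude entry positive. Pseudotime is
Euclidean distance from the root in the space of components scaled by
λ/(1−λ), divided by its maximum, so pseudotime(root) = 0 and max = 1.
Components with λ = 1 after stationary removal are skipped with a
warning; a disconnected graph is an error that reports component sizes.

The root is the cell in the designated progenitor cluster (default GBC)
maximizing mean normalized expression of supplied marker genes, with ties
going to the lexicographically lowest barcode; without markers, the
cluster cell most extreme on the first diffusion component is used.

### Binning and count forms

Cells fall into `n_bins = 50` equal-width bins over [0, 1] (last bin
right-inclusive). Equal-width was chosen over equal-count so that bin
midpoints have a fixed pseudotime meaning across datasets; bins with fewer
than `min_cells_per_bin = 3` cells (and empty bins) are filled by linear
interpolation between the nearest populated bins (constant extension at
the ends) and flagged — interpolation rather than dropping keeps every
gene's trajectory the same length, which RMSE comparability requires. Bin
means for NORM and LOG are computed first; NORM_MAX and LOG_MAX divide
each gene's trajectory by its own maximum (so max-scaled trajectories
peak at exactly 1, and max-scaling is idempotent). Genes with all-zero
trajectories are flagged and excluded from the max-scaled forms, not
silently dropped.

### Ranking and integration

Per form, `RMSE_g = sqrt((1/B) Σ_b (x_gb − x_ref,b)²)`; the reference
scores exactly 0 and wins any tie at 0, so it is rank 1 on any input.
Ranks ascend with RMSE, ties breaking on symbol. Integration sorts by
(descending count of forms with rank ≤ k, ascending mean rank, symbol)
with k = 50; both sub-orderings are kept as columns so users can re-rank.
A gene missing from the max-scaled forms averages over the forms it has
and is flagged. Anti-regulated candidates can be scored as RMSE against
the vertically flipped max-scaled reference (1 − x̂_ref), reported in an
optional column. Pan-neuronal exclusion flags matching genes and
recomputes the final ordering over the survivors, leaving their RMSE
values in the table for audit.

### Onset, enrichment and over-representation

Onset AUC is the trapezoidal integral of the max-scaled trajectory
(LOG_MAX by default; configurable) with bin midpoints mapped linearly to
[0, 1], so a constantly-on gene scores 1 and higher AUC means earlier
onset. Note the corollary: genes that *decline* along the axis (e.g.
progenitor markers) also get small AUCs and land in the "late" tercile —
AUC is an onset clock only for switch-on genes. Onset classes are AUC
terciles (boundaries at the 1/3 and 2/3 quantiles, values on a boundary
going to the higher class); fewer than three genes degenerate to "mid"
with a warning.

Cluster enrichment uses `log2((mean_target + ε)/(mean_rest + ε))` with
ε = 1e−9 (avoids infinities while preserving order) and a two-sided
Wilcoxon rank-sum p-value (exact for small tie-free samples, normal
approximation otherwise), with Benjamini–Hochberg FDR across genes; the
"top enriched" list takes the `n_top` largest fold changes among genes
with FDR < 0.05. Over-representation of user-supplied GMT gene sets is
the upper-tail hypergeometric P(X ≥ k) after intersecting each set with
the universe, BH-corrected across sets. No gene-ontology semantics or
annotation retrieval is attempted — gene sets are caller-supplied.

### Evidence overlays

Regulatory-network input is an edge list (e.g. from a mutual-information
network inference run); self-loops are dropped and duplicate pairs
collapse to the maximum weight. Interaction counts against a TF list
(default: the nine-member ER-stress panel Atf5, Atf6, Ddit3, Ebf1, Ebf2,
Ebf3, Ebf4, Nfe2l2, Xbp1) treat edges as undirected by default because
mutual information is symmetric; a directed mode exists. DE overlays flag
candidates significant below an FDR cutoff with the requested sign.
Evidence is annotation only: no composite score combines network counts,
DE flags and RMSE ranks, because any such weighting would be arbitrary —
the columns are exposed and the choice left to the analyst.

## The simulator

`simulate_lineage` draws latent time t ~ U(0, 1) per cell, stage labels
at boundaries 0.25/0.5/0.75, and gene means from four template families:
sigmoid-on `baseline + A/(1+e^(−s(t−t0)))`, the mirrored sigmoid-off,
Gaussian pulse (width 0.08), and constant. Counts are negative binomial
(var = m + φm², φ = 0.3, shared across genes for simplicity) around
`L_c · μ_g(t_c)` with log-normal library factors (σ = 0.35). Planted
structure: one reference gene (sigmoid-on, t0 = 0.35, slope 12, amplitude
3) plus 25 coregulated genes jittering its parameters (t0 sd 0.01,
slope/amplitude 8% relative — tight coregulation); 30 constant
pan-neuronal genes; 100 OR-like genes of which each mature-stage cell
expresses exactly one at high amplitude (a deterministic floor of 5
counts guarantees the "exactly one above threshold" construction); 10
mitochondrial genes carrying ~3% of counts, inflated 20× in the 3% of
cells marked damaged; and a few early sigmoid-off GBC marker genes for
root selection. These defaults were fixed from a signal-to-noise sketch
(bin occupancy ≈ 60 cells makes the binned noise floor ≈ 0.02–0.04 in
LOG_MAX RMSE, well below the separation that background sigmoid-on genes
with independent t0 and amplitude produce) before any end-to-end run.
The `tiny` preset shrinks the gene panel for unit-test speed and raises
`mean_scale` so per-cell depth stays realistic relative to the default QC
thresholds.

The negative control `shuffle_planted=True` evaluates each planted gene's
template on an independently permuted latent-time vector: marginal count
distributions are unchanged but coordination with the reference is
destroyed, so planted genes present flat noisy trajectories that never
outrank genuinely similar background genes.

What the simulator does **not** emulate: empirical depth/dropout
distributions of any real platform, batch effects, doublets, ambient RNA,
per-gene dispersion heterogeneity, or branching. Passing recovery tests
therefore demonstrate that the pipeline's inference is correct under its
own statistical assumptions, not that those assumptions hold for any
particular real dataset.

## Problem sizes and numerical choices

Recovery and pseudotime checks run the default 3,000-cell × 2,000-gene
simulation over three seeds (plus shuffled controls); oracle tests use
≤ 150-cell fixtures where brute-force enumeration (dense
eigendecomposition, exhaustive permutations, exhaustive hypergeometric
draws) is exact. All eigensolvers are deterministic; every tie-break in
ranking, HVG selection and root choice is lexicographic; depth
normalization tolerates 1e−6 relative error on row sums. Degenerate
inputs (all cells filtered, disconnected graphs, empty root clusters,
< 2 populated bins, zero-total cells) raise errors naming the offending
entity rather than propagating NaNs.

## Known limitations

- RMSE on un-max-scaled forms conflates shape and amplitude; that is by
  design (the integration step is what removes single-form bias), but a
  reference gene with unusual amplitude will rank amplitude-matched genes
  above shape-matched ones in those two forms.
- The integration rule (top-k membership, then mean rank) is one
  defensible choice; the per-form columns allow any other aggregation.
- DPT here is single-root, single-branch; datasets with real branching
  need the branch assigned upstream and the subset passed in.
- Cluster labels are consumed from input metadata, never recomputed.
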