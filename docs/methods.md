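# Methods

## Scope and model

`deltacomm` scores sender→receiver ligand–receptor (L–R) pairs for
*disease-associated change* in the receiver's downstream transcriptional
program, in an annotated two-condition scRNA-seq matrix. The score factors
into an expression-specificity weight and a TF activity-change term:

```
S_k = ‖LR_k‖₂ × TF_k
```

The pipeline per receiver cell type: (1) log2 fold changes (FC) of every
gene, disease vs. control means within the receiver cells; (2) for each TF
downstream of any candidate pair, a coexpression-filtered regulon and a
permutation-GSEA enrichment of that regulon in the FC ranking; (3) a
directional significance gate mapping the result to a non-negative
activity; (4) inverse-distance aggregation over a pair's TFs and the final
product with the softmax/L2 expression weight.

## Assumptions

* Exactly two conditions, labeled `disease` and `control`, both present in
  every scored receiver cell type. Cell-type annotation is taken as given
  (no clustering or QC here; upstream tools own those).
* Receptor engagement manifests as transcriptional change of the TF's
  targets in the receiver. Sender expression enters only through the
  ligand-specificity weight; no spatial or contact information is used.
* Gene symbols are case-sensitive and shared across matrix and databases;
  database genes absent from the matrix contribute zero expression and are
  dropped from regulons.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `scale` | 1e4 | normalization `log2(1 + scale·count/total)`; 1e5 reproduces log2(CPM/10+1) |
| `epsilon` | 0.01 | pseudocount on normalized means in the FC ratio; keeps dropout-heavy genes finite while leaving moderate means essentially untouched |
| `rho_cut`, `p_cut` | 0.1, 0.05 | Spearman regulon retention cutoffs |
| `alpha`, `gate_on` | 0.05, `adj_p` | TF significance gate; `gate_on="p"` gates on the raw permutation p |
| `direction` | `both` | `up`/`down` restrict to positive/negative NES |
| `n_perm` | 1000 | permutations per (receiver, TF); p floor = 1/(1+#same-sign nulls) |
| `min_expressed_fraction` | 0.10 | detection fraction every subunit must reach in its cell type |
| `statistic` | `mean` | `quantile` (+`quantile_q`) is the dropout-robust alternative |
| `regulon_scope` | `receiver` | cells used for the coexpression filter (`all` uses every cell) |

## Numerical and procedural choices

* **GSEA flavor.** Classic weighted Kolmogorov–Smirnov running sum (hit
  increments ∝ |FC|¹, miss decrement 1/(N−N_h)), ES = signed value at the
  maximum absolute deviation. The null permutes *gene-set labels* (random
  equal-size sets), not phenotypes, because one FC ranking exists per
  receiver. NES divides ES by the mean |ES| of same-sign nulls; p counts
  same-sign nulls at least as extreme, with the +1 pseudo-count. If a
  gene set's |FC| weights are all zero, hits fall back to equal increments.
  An exhaustive mode enumerates all C(N,k) placements for small instances.
* **Ranking.** FCs of *all* matrix genes, descending, ties broken by gene
  symbol — a one-set ranking restricted to the regulon would be degenerate.
* **Gating.** BH adjustment is computed across the TFs scored within one
  receiver cell type. The default gate uses the adjusted p for all three
  directions for internal consistency; the raw-p gate is a switch.
* **TF aggregation.** Weighted mean with weights 1/M (M = shortest
  receptor→TF step count, ≥1): closer TFs are more credible reporters of
  the receptor.
* **Softmax scope.** For a ligand, softmax runs over its summaries across
  all (sender) cell types; for a receptor, across all (receiver) cell
  types, with max-shift stabilization. This makes ‖LR‖₂ a specificity
  weight in (0, √2) comparable across pairs.
* **Duplicate axes** merge with minimum distance and pathway union —
  the shortest path dominates the weight.
* **Enrichment.** PAS is the plain Jaccard index of altered vs. pathway
  pair sets; nPAS standardizes with the *population* σ across pathways in a
  scope (errors if all PAS are identical; NaN when only one pathway).
  The hypergeometric test is the upper tail P(X ≥ q) with universe m =
  distinct pairs in the pathway database (overridable), computed via the
  log-space survival function. Scope defaults to per sender→receiver block.
* **Determinism.** Every (receiver, TF) GSEA derives its own seed from the
  pipeline seed and a CRC of the labels, so results are independent of
  iteration order and byte-identical across reruns.

## Synthetic data

The generator plants the causal chain the scorer targets: ligand high in
sender cells (8× the negative-binomial baseline, both conditions), receptor
high in receivers, a TF and its targets coupled through a shared per-cell
log-normal latent activity factor (σ = 0.8, giving median regulon Spearman
ρ ≈ 0.2 — typical of scRNA-seq TF–target coexpression), and the targets'
means multiplied by `2^shift` in receiver disease cells only. Decoy axes
are expressed everywhere and coexpressed but unshifted. Background counts
are iid NB (mean 2, size 2) with log-normal cell size factors and 20%
independent dropout. Not emulated: batch effects, ambient RNA, UMI
saturation, doublets — a green recovery test establishes the mechanics of
the pipeline, not field performance.

## Known limitations

* **Null calibration under correlated regulons.** Gene-set permutation
  assumes genes are exchangeable. A regulon coexpressed through a shared
  latent factor has *coherent* FC noise (the latent factor's
  disease–control imbalance shifts all targets together), so its observed
  ES is systematically more extreme than the iid-set null. On the all-null
  fixture ~16–23% of decoy pairs are flagged at the 0.05 BH gate (seeds
  0–2, 7) instead of ≤10%; the coherent and independent FC-noise components
  both scale as 1/√n_cells, so more cells do not cure it. The GSEA p-value
  itself is verified uniform under an iid null (KS = 0.028 over 2000
  draws). The corresponding acceptance test states the nominal bound and
  fails; treat `altered` calls on strongly coexpressed regulons as
  anti-conservative, or gate on raw p with a stricter α.
* Only two conditions; no second significance layer on S_k beyond the TF
  gate; no phenotype-permutation GSEA or leading-edge reporting.
* The expression filter and softmax use all cells of a type (conditions
  pooled); condition-specific summaries are available through
  `group_summary` but not wired into the score.
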