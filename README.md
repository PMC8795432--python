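# dlnatlas

Single-cell analysis of innate immune responses to vaccination in draining
lymph nodes (dLNs): a tested, reusable pipeline for paired scRNA-seq /
scATAC-seq data comparing an adjuvanted protein vaccine (a TLR7/8-agonist
formulation, `3M`) with a live attenuated viral vaccine (`YF`) across a
day 0 / day 1 / day 28 time course, together with a synthetic-data
generator that plants every signal the analyses are meant to find.

It is written for computational immunologists who want the statistical
machinery of this kind of study — QC, graph clustering, differential
expression, TF motif deviation scoring, gene-set overrepresentation,
TF–gene network inference, and cross-species meta-analysis — as importable,
unit-tested functions rather than a one-off notebook, and who want every
step validated against planted ground truth.

## The methods at the core

- **Motif deviations (chromVAR-style).** For motif *m* and cell *c*, with
  peak count shares *fᵢ* and cell totals *T_c*, the expected motif count is
  *E_mc = (Σ_{i∈m} fᵢ)·T_c* and the raw deviation *(O_mc − E_mc)/E_mc*.
  GC bias is removed by resampling each member peak from its nearest
  neighbors in (GC, mean accessibility) space over `n_bg = 50` background
  sets: *corrected = raw − mean_bg*, *z = corrected / sd_bg*.
- **Differential expression.** Two-sided Wilcoxon rank-sum per feature
  (exact for combined n ≤ 20 without ties), natural-log fold change of
  pseudocounted de-logged means, Benjamini–Hochberg correction; acute
  regime FDR < 0.05 & |logFC| > 0.25, late regime FDR < 0.05 & |logFC| ≥ 0.1.
- **Overrepresentation.** Hypergeometric upper tail
  *p = P(X ≥ k)*, *X ~ Hypergeom(N, K, n)* against BTM-style gene-set
  collections, BH across sets.
- **TF–gene networks.** Pearson correlations of neighbor-smoothed gene
  accessibility scores and motif z-scores across single cells; edges at
  r > 0.9 (gene–gene) and r > 0.8 (gene–TF); greedy modularity communities,
  communities smaller than 4 nodes pruned; hub TFs at the 95th percentile
  of TF gene-degree; seeded Fruchterman–Reingold layout.
- **Meta-analysis.** Per study Hedges'
  *g = J·(x̄_post − x̄_pre)/s_pooled*, *J = 1 − 3/(4n − 9)*, with
  *var_g = n/(n₁n₂) + g²/2n*; DerSimonian–Laird random-effects summary
  (*τ² = max(0, (Q − (k−1))/(S₁ − S₂/S₁))*), then Pearson correlation of
  summary effects against homologous mouse log fold changes.

## Worked example

The numbered scripts under `analysis/` run the whole study on simulated
data (the generator's defaults are the study conditions: 10 innate cell
types × 3 timepoints × 2 stimuli × 50 cells, a 40-gene ISG program induced
at day 1 with cell-type-specific magnitude and 40% day-28 persistence in
monocytes under `3M` only):

```bash
python analysis/01_simulate.py
python analysis/02_qc_cluster.py
python analysis/03_differential_expression.py
python analysis/04_motif_deviations.py
python analysis/05_network.py
python analysis/06_meta_analysis.py
```

Output from a run (tables land under `results/`):

```
10 clusters over 2725 cells; cell-type ARI (singlets) = 1.000
monocyte day0+day28 sub-clustering: 3 subclusters, Ly6C subcluster ARI = 1.000
day-1 monocyte DEGs: 29 (3M), 32 (YF)
direction sharing 3M->YF: 100.0% (29/29); logFC Pearson r = 0.509 over 1056 genes
day-28 residual monocyte DEGs: 2 (3M) vs 0 (YF)
top enriched module: viral_sensing_module (k=28/39, FDR=3.65e-44)
Irf2 deviation z separates day1 vs day0: AUROC = 0.937
network: 25 nodes, 100 edges, 3 communities; hub TFs: ['Irf2']
summary ES vs mouse logFC over homologs: r = 0.584 (p = 1.09e-19, n = 200)
```

Reading this: clustering recovers every planted cell type and the three
Ly6C monocyte subclusters exactly; both stimuli induce the same ISG program
at day 1 (hence ~100% direction sharing); only the adjuvanted stimulus
leaves residual day-28 calls in monocytes; the planted Irf-like motif is
both the strongest day-1 deviation signal and the hub of the TF–gene
network; and the cross-species summary-effect correlation recovers the
planted value of 0.6 up to sampling attenuation.

The same stages are available as a CLI (`dlnatlas sim|qc|cluster|diff|
motifdev|enrich|network|tfcorr|meta`); every stage takes `--seed` and is
byte-reproducible given it.

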