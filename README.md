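# exorna

Analysis toolkit for paired **cell / exosome small-RNA sequencing** studies
in families. Exosomes — 30–100 nm extracellular vesicles — carry a
selectively exported RNA cargo that can differ radically from their parent
cells: entire genomic miRNA clusters can be shuttled out while remaining
nearly undetectable inside the cell. `exorna` implements the complete
analysis stack for quantifying that export and its genetics:

* **miRNA cluster analysis** — hairpins are grouped into genomic clusters
  (every member within 10 kb of at least one other member, single linkage);
  mature-miRNA counts are summed per cluster, excluding matures that could
  originate from more than one cluster.
* **Biotype composition** — per-sample proportions of the six small-RNA
  classes (lincRNA, miRNA, misc, piRNA, rRNA, snoRNA), compared between
  compartments with paired two-sided t-tests and Bonferroni correction.
* **Differential expression** — a simplified negative-binomial Wald engine
  (median-of-ratios size factors, per-transcript method-of-moments
  dispersion, log-link GLM with size-factor offsets, Benjamini–Hochberg FDR),
  at mature-miRNA, cluster, and piRNA level.
* **Interindividual variability** — Spearman correlation matrices,
  average-linkage hierarchical clustering of samples, and a Wilcoxon
  rank-sum contrast of within-cell vs within-exosome correlations.
* **Pedigree haplotypes** — from unphased three-generation genotypes:
  Mendelian filtering, grandparent-anchored phasing, per-child transmission
  inference with majority-vote smoothing, and segmentation into haplotype
  blocks between recombination points.
* **eQTL mapping** — the two-haplotype linear model per transcript *t* and
  child *i*,

  `log(Y_i + 1) ~ μ + β_p · p_i + β_m · m_i`

  where `Y_i` is size-factor-normalized expression and `p_i, m_i ∈ {0, 1}`
  code the inherited paternal/maternal haplotype at the transcript's locus;
  the model fit (R²) yields the p-value via the overall F-test. Includes
  cross-compartment effect-size correlation, intersection of hits at 20%
  FDR, and nongenetic-confounder QC (genome-wide haplotype ranking,
  unmapped-read 10-mer bias tests, sex confounding).
* **NTA profiling** — nontemplated 1–2 nt additions at the 5′/3′ ends of
  mature miRNAs, extracted from soft clips in hairpin-local alignments.
* **Synthetic-study generator** — a first-class module emulating the full
  design (4 grandparents + 2 parents + 11 children, 34 paired libraries,
  one massively exported cluster, compartment-specific NB dispersion,
  planted cis effects, planted NTA tails), with every planted quantity
  recorded in a `TruthSet`.

## Worked example

```python
from exorna import (
    SimulationConfig, simulate_study, build_clusters,
    aggregate_cluster_counts, nb_differential_test,
)

cfg = SimulationConfig(seed=1)
pedigree, genotypes, annotation, counts, truth = simulate_study(cfg)

mirna = [t for t in counts.transcripts if annotation.biotypes[t] == "miRNA"]
cmap = build_clusters(annotation)                       # 10-kb rule
agg = aggregate_cluster_counts(counts.subset_transcripts(mirna), cmap)
res = nb_differential_test(agg)                         # exosome vs cell

cluster_id = cmap.mature_cluster[truth.exported_cluster_matures[0]]
row = res.loc[cluster_id]
print(f"exported cluster: log2FC = {row.log2FoldChange:.2f}, padj = {row.padj:.3g}")
```

prints

```
exported cluster: log2FC = 10.71, padj = 0
```

i.e. the planted exported cluster is recovered with a log2 fold change near
its simulated value of 10 (≈1000-fold more abundant in exosomes, relative
to library size) and a BH-adjusted p-value that underflows double
precision — unambiguous significance at the 1% FDR.

The same run end-to-end, from the shell:

```sh
smallrna-exo run --seed 1 --out out/
```

writes per-stage TSVs (clusters, composition, differential expression,
Spearman matrices, haplotype blocks, eQTL fits, NTA frequencies) plus a
`summary.json` with the headline numbers.

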