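# degrank

Evaluation framework for differential-expression gene-ranking methods on
MAQC-style titration designs. The package bundles:

- **synthetic**: a generator for MAQC-like studies — reference profiles A
  and B, natural-scale mixtures C = 0.75·A + 0.25·B and D = 0.25·A + 0.75·B,
  replicates at several test sites on several array "platforms" with
  overlapping probe sets (gene dropout, multi-probe genes, duplicate probe
  IDs), intensity-dependent noise, a low-noise RT-PCR-like assay on a gene
  subset, and random gene-set collections — all with known ground truth.
- **preprocess**: duplicate-probe averaging (natural scale), floor
  substitution (default 0.169), log2 transform, probe-to-gene collapsing
  (log2 scale).
- **ranking**: eight two-class statistics — WAD, AD, FC, rank products
  (RP), moderated t (modT), SAM t (samT), shrinkage t (shrT) and
  intensity-based moderated t (ibmT) — with their ordering conventions
  (descending |statistic|; ascending net value for RP) and two tie modes
  (average ranks; stable probe-ID truncation order).
- **truth**: "true DEG" definitions from RT-PCR-style tables via pooled
  two-sample t + Benjamini–Hochberg FDR (< 0.05), |AD| (> 1), or top-X.
- **evalmetrics**: AUC (rank-sum, ties ½), percentage of overlapping genes
  (POG) over top-X sets, Spearman correlation of rank vectors, and
  average-linkage clustering of lists on 1 − ρ with newick output.
- **enrichment**: rank-average gene-set enrichment score E_G (mean rank of
  member genes; small = enriched), set-level rankings and POG, and the
  intersection-union ratio of a set's realisation across platforms.
- **pipeline/CLI**: orchestration of the full design — simulate →
  preprocess → rank (8 methods × 2 comparisons × sites × platforms) →
  truth → AUC/POG/correlation tables → enrichment reproducibility — with a
  JSON manifest of file digests for reproducibility checks.

## CLI

```sh
degrank simulate --outdir sim --seed 1            # synthetic study (TSV/GMT)
degrank run --outdir out --seed 1                 # full pipeline
degrank report out                                # markdown summary

# stage-by-stage
degrank preprocess --in sim/expression_PLB_site1.tsv \
    --meta sim/expression_PLB_site1.meta.tsv --floor 0.169 --out m.tsv
degrank rank --method wad --class-a A --class-b B \
    --in m.tsv --design sim/expression_PLB_site1.meta.tsv --out scores.tsv
degrank truth --in sim/rtpcr.tsv --design sim/rtpcr.meta.tsv \
    --metric fdr --threshold 0.05 --out truth.tsv
degrank evaluate auc --scores scores.tsv --truth truth.tsv \
    --annotation sim/annotation_PLB.tsv
degrank enrich --gmt sim/gene_sets.gmt --scores gene_scores.tsv --out eg.tsv
```

Custom studies are configured with a YAML file mirroring `SimConfig`
(`degrank run --config cfg.yaml`); `degrank simulate` writes a
`config.yaml` you can start from.

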