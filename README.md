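# reversig

Signature-reversal drug repositioning for bulk transcriptomics.

Given a disease expression dataset (normal vs disease tissue) and a bank of
compound perturbation rank profiles (CMAP Build 02-style, one ranked probe
list per treatment instance), `reversig` finds compounds whose strongest
perturbations run *opposite* to the disease signature:

1. **Filter** — both platforms are z-scored against their reference samples
   (untreated cell line / normal tissue), and genes whose expression clearly
   differs between the untreated cell line and the disease tissue are removed
   (Welch t-test, Benjamini–Hochberg FDR < 0.01).
2. **Rank** — disease genes are ordered by the Welch t-statistic of disease
   vs normal; each compound's instance probe ranks are collapsed to genes
   (best rank), averaged across instances in the matched cell line, and
   re-ranked.
3. **Overlap test** — the top-k up-regulated disease genes (UC) are tested
   against the compound's bottom-k (DB), and the bottom-k disease genes (DC)
   against the compound's top-k (UB), with the exact one-sided hypergeometric
   tail (equivalently a one-sided Fisher test); BH-FDR is applied per
   direction across compounds.
4. **Window optimization** — k is scanned (default 100..10000 step 100) and
   selected per direction as the maximum-specificity window subject to
   non-zero sensitivity (≥1 known drug recovered), non-zero duality and
   existing FDR-0.01 discoveries, scored against annotated FDA-approved and
   failed-trial compounds.
5. **Merge & interpret** — direction calls are merged into a candidate table
   (duality = significant in both directions) and the overlapping gene
   windows are interpreted by hypergeometric gene-set over-representation
   (pathway mode: raw p < 0.05; GO mode: BH FDR < 0.01 on sets with > 400
   genes in the universe).

A fully self-contained synthetic generator (`reversig.synthetic`) produces
tissue cohorts with planted differential genes, compound banks with planted
reversers at tunable noise, drug annotations and gene sets, so the entire
pipeline runs and is tested without any download.

## CLI

```sh
# generate a synthetic dataset plus a ready pipeline config
reversig simulate --seed 7 --outdir demo

# full pipeline: filter -> rank -> scan -> select -> test -> merge -> enrich
reversig run --config demo/pipeline.yaml

cat demo/results/summary.txt
```

Stage subcommands operate on serialized intermediates so the expensive scan
can be re-run in isolation:

```sh
reversig filter --config demo/pipeline.yaml --outdir demo/stage
reversig rank   --config demo/pipeline.yaml --retained demo/stage/retained_genes.txt --outdir demo/stage
reversig scan   --config demo/pipeline.yaml --retained demo/stage/retained_genes.txt \
                --ranking demo/stage/disease_ranking.tsv --outdir demo/stage
reversig call   --config demo/pipeline.yaml --retained demo/stage/retained_genes.txt \
                --ranking demo/stage/disease_ranking.tsv --k-ucdb 100 --k-dcub 100 --outdir demo/stage
reversig enrich --config demo/pipeline.yaml --retained demo/stage/retained_genes.txt \
                --ranking demo/stage/disease_ranking.tsv --k-ucdb 100 --k-dcub 100 --outdir demo/stage
```

Real data are read from: GDS/SOFT-style expression tables (or a plain matrix
with a two-column sample→group sidecar), a tab-delimited probes × instances
rank matrix plus instance annotation table, GMT gene sets, and a drug
annotation table (`compound, fda_approved, approved_indications,
failed_trial_indications`, semicolon-separated lists). All outputs are TSV
plus one plain-text summary; identical configs produce byte-identical
outputs.

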