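# tfenrich

A transcription-factor-centric expression analysis pipeline for two-group
one-colour microarray designs, built around a synthetic-data generator with
planted ground truth so the whole analysis is testable without any download.

The pipeline stages:

1. **Synthetic study generation** (`tfenrich.synthetic`) — log2-normal
   intensities for a 4-vs-2 two-group design with gene variances drawn from
   a scaled inverse-chi-square prior, a planted fraction of differentially
   expressed (DE) genes, a transcription-factor (TF) catalog, a random
   rooted `is_a` ontology DAG with multi-word labels, and annotations in
   which planted terms are enriched for the DE TFs of one stream
   (up/down).  Ground truth is emitted for recovery testing.
2. **Preprocessing + differential expression** (`tfenrich.dea`) — clamp
   non-positive intensities to 1.0, normalize each sample to its 75th
   percentile, keep probes flagged Present/Marginal in at least one
   sample, log2-transform, then a moderated t-test: pooled two-sample fit,
   empirical-Bayes variance shrinkage with moment-based (digamma/trigamma)
   hyperparameter estimation, Benjamini–Hochberg adjustment, and strict
   up/down/ns classification (`adj_p < 0.05`, `|log2FC| > 0.1`).  Includes
   the secondary-contrast noise filter (intra-group SD < 0.3, mean
   distance > 0.5) and contrast intersection.
3. **Ontology handling** (`tfenrich.ontology`) — minimal OBO 1.2
   parse/write, cycle detection, and true-path-rule annotation propagation
   up `is_a` edges.
4. **Enrichment** (`tfenrich.enrichment`) — "classic" per-term one-sided
   two-sample Kolmogorov–Smirnov enrichment over gene scores (the adjusted
   p-values from DEA), with exact p-values computed by an integer lattice
   DP whenever affordable and the asymptotic tail otherwise.  Two
   orchestrations: Method 1 (GSEA over all stream DEGs, TFs identified
   afterwards) and Method 2 (GSEA over the stream's TF-DEGs only), each
   run on the up and down streams separately.
5. **Label text mining** (`tfenrich.semantics`) — GO-label cleaning
   (lowercasing, punctuation stripping with hyphenated compounds kept
   whole, stopword removal), a binary term-document matrix whose word
   significance is the sum of reciprocal enrichment ranks ("orders"),
   top-k word tables for word clouds, and Pearson word associations.
6. **Reporting** (`tfenrich.report`) — keyword-curated term selection
   with the enrichment score `log1p(-log10 p)`, TF-to-term bubble tables,
   Method 1 vs Method 2 set comparison (Jaccard, containment), and the
   `run_all` orchestrator that writes all TSV/JSON artifacts plus a
   reproducibility manifest.

## Test

```sh
python -m pytest -q
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle
equivalence against scipy/statsmodels, enumeration oracles for the KS
test, brute-force propagation and word-significance checks, planted-signal
recovery, null calibration, determinism).

## CLI

```sh
tfenrich run-all --seed 1 --outdir out/            # full synthetic pipeline
tfenrich simulate --seed 1 --outdir sim/           # just the synthetic study
tfenrich preprocess --expression sim/expression.tsv --design sim/design.tsv \
    --flags sim/flags.tsv --outdir prep/
tfenrich dea --expression prep/processed.tsv --design prep/design.tsv --outdir dea/
tfenrich gsea --stats dea/gene_stats.tsv --obo sim/ontology.obo \
    --annotations sim/annotations.tsv --catalog sim/tf_catalog.txt --outdir gsea/
tfenrich semantics --results gsea/gsea_method1_up.tsv --outdir sem/
tfenrich curate --results gsea/gsea_method1_up.tsv --outdir cur/
tfenrich compare --m1-up ... --m1-down ... --m2-up ... --m2-down ... --outdir cmp/
```

Configuration is YAML/JSON with sections `sim`, `dea`, `gsea`,
`semantics`, `curation` (see `tfenrich.report.DEFAULT_CONFIG`).  Exit
codes: 0 success, 2 configuration error, 3 data error.

## Reproducibility

All randomness flows through numpy's `default_rng` (PCG64) seeded from
the config; fixed seeds give byte-identical outputs.  The 75th-percentile
normalization uses linear interpolation at position `1+(n-1)q`; the
convention is recorded in the run manifest.
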