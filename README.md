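# spitzsig

Analysis pipeline for NanoString nCounter panel counts from three-class
melanocytic cohorts (SN / AST / MST): library-size normalization with
voom-style precision weights, empirical-Bayes moderated differential
expression, competitive gene-set enrichment with inter-gene correlation
correction (camera), and a repeated-cross-validation stability-LASSO
procedure that yields a weighted gene signature and a per-sample 0–1
malignancy score with a 0.4 low/high cut.

A negative-binomial cohort simulator with planted ground truth (DE genes,
ordered-mean signature genes, realistic library-size spread) makes every
stage testable without any external data.

## Modules

| module | contents |
| --- | --- |
| `spitzsig.synthetic` | `SyntheticConfig`, `generate_cohort`, `write_fixture` — NB cohorts with planted effects |
| `spitzsig.io_normalize` | `read_counts`, `read_gmt`, `normalize_voom`, `mds_coordinates` and the `CountCohort` / `WeightedExpression` / `GeneSetCollection` types |
| `spitzsig.diffexpr` | `fit_contrast` (weighted two-group fit + EB moderation), `adjust_bh`, `significant_genes`, `scale_center` |
| `spitzsig.gsea` | `camera_test` (VIF-corrected competitive test), `rank_pathways` |
| `spitzsig.signature` | `lasso_logistic_path` (coordinate descent), `cv_deviance`, `stability_select`, `score_samples` |
| `spitzsig.report` | `PipelineConfig`, `run_pipeline`, `summarize_scores` (manifest, deterministic TSV artifacts) |
| `spitzsig.cli` | `spitzsig` command-line interface |

## CLI

```sh
# simulate a 770-gene, 27/10/14 cohort fixture
spitzsig simulate --seed 1 --out sim/

# normalization, precision weights, MDS
spitzsig normalize --counts sim/counts.tsv --samples sim/samples.tsv --out norm/

# one moderated contrast (p < 0.05, FDR q <= 0.25)
spitzsig de --counts sim/counts.tsv --samples sim/samples.tsv \
    --contrast SN:MST --out de_sn_mst.tsv

# camera gene-set enrichment against a GMT collection
spitzsig gsea --counts sim/counts.tsv --samples sim/samples.tsv \
    --gmt hallmark.gmt --contrast SN:MST --out gsea.tsv

# stability-LASSO signature (500 reps, >= 250 rule) and 0-1 scores
spitzsig signature --counts sim/counts.tsv --samples sim/samples.tsv \
    --train SN:MST --reps 500 --threshold 250 --seed 1 --out sig/

# full pipeline from one YAML config
spitzsig run --config cfg.yaml
```

A minimal `cfg.yaml`:

```yaml
counts: sim/counts.tsv
samples: sim/samples.tsv
gmt: hallmark.gmt        # optional
outdir: out
seed: 1
reps: 500
threshold: 250
```

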