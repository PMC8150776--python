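# mcseed

Analysis pipeline for restriction-enzyme-based (MCSeEd-style)
reduced-representation methylation data: from per-locus read-count tables to
differentially methylated positions (DMPs), window-clustered differentially
methylated regions (DMRs), extended-gene-body (EGB) gene methylation calls,
cross-comparison gene sets, and intersection with differential-expression
tables. A synthetic-data generator with a planted truth table makes every
stage testable without sequencing data.

## Pipeline

1. **locus_matrix** — read per-locus count TSVs (one column per library),
   library-size normalize to counts-per-million, and discard hyper-variable
   loci by coefficient of variation (retain `CV <= 10**0.35`; see note below).
2. **dmp_calling** — per-site relative methylation
   `1 - count / row_max` (methylation blocks the sensitive enzyme, so counts
   anti-correlate with methylation); DMPs by a grouped binomial logistic
   regression (1-df likelihood-ratio test, McCullagh–Nelder overdispersion
   correction, F reference distribution), BH-adjusted, FDR < 0.05.
3. **dmr_calling** — directional sliding-window clustering of DMPs
   (window re-anchors at each included DMP; an opposite-direction DMP inside
   the window terminates the cluster), window length optimized over a
   100–2000 bp grid by maximizing the DMR count, then a pooled region-level
   test per cluster.
4. **egb_annotation** — genes split into 2 kb upstream / gene body /
   2 kb downstream (strand-resolved), DMR-to-region assignment, per-region
   methylation status with the mixed-direction ambiguity filter, Table-style
   summaries and 100-bp metagene profiles around the start/stop codons.
5. **comparative_sets** — regulatory gene sets (2 kb flanks plus the
   first/last 400 bp of the gene body), shared/specific Venn partitions,
   and the DMG × DEG inner join.
6. **simulate** — negative-binomial (NB1) synthetic counts with planted
   DMP singletons and DMR blocks plus gene models, for calibration and
   parameter-recovery testing.

### CV filter direction

The printed rule ("discard sites with a co-logarithm of the CV higher than
−0.35") read literally as `-log10(CV) > -0.35` would discard every
*low*-variability site, contradicting the filter's purpose. This package
discards `CV > 10**0.35` (hyper-variable sites) by default and exposes an
`invert=True` flag for the literal reading.

## CLI

```sh
mcseed simulate --outdir data --seed 1                # synthetic dataset
mcseed dmp  --counts data/counts_CG.tsv --sample-sheet data/samples.tsv \
            --context CG --out dmps.tsv
mcseed dmr  --counts data/counts_CG.tsv --sample-sheet data/samples.tsv \
            --context CG --out dmrs.tsv                # --window 0 = optimize
mcseed annotate --dmrs dmrs.tsv --gff3 data/genes.gff3 --out calls.tsv
mcseed sets --dmrs-a a.tsv --dmrs-b b.tsv --gff3 data/genes.gff3 --outdir venn
mcseed cross-deg --calls calls.tsv --deg data/deg.tsv --out dmg_deg.tsv
mcseed run-all --config config.json                    # full pipeline
```

`run-all` takes a JSON file with the `PipelineConfig` fields (`counts`,
`sample_sheet`, `gff3`, `outdir`, optional `deg_table`, `window_lengths`
per context or `"auto"`, `fdr`, `flank`, `core`, ...) and writes all TSV/BED
outputs plus a `manifest.json` with per-stage counts.

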