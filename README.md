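# mirtarget

Tumor-suppressive microRNAs (TS-miRNAs) are miRNAs whose restoration slows
cancer-cell growth and whose expression is lost in tumors. `mirtarget`
implements, as a tested and reusable Python pipeline, an integrative strategy
for finding such miRNAs and their direct mRNA targets in hepatocellular
carcinoma cells:

1. **Screening triage** — a function-based arm (miRNA mimic growth screen
   across cell lines: hit if the control-normalized growth ratio is < 0.8 in
   ≥ 4 of 6 lines) intersected with an expression-based arm (miRNA > 2-fold
   below normal-liver references in all lines), plus panel-frequency filters
   on cell-line and paired tumor/non-tumor panels (> 50% downregulated).
2. **Ago2-IP-seq enrichment scoring** — per gene,
   RPKM = 10⁹·C/(N·L); the *abundant-Ago2 fraction* is
   RPKM(Ago2-IP)/RPKM(total RNA) within a condition, and the
   *fold-enrichment score* is the ratio of abundant-Ago2 fractions between
   miRNA-transfected and non-transfected cells. Genes recruited into RISC by
   the transfected miRNA score ≫ 1.
3. **Seed-site filtering** — genes are kept only if their 3′UTR carries the
   miR-195/miR-497-family targeting heptamer (default `ACGACGA`;
   case-insensitive, U≡T, overlapping hits counted).
4. **GSEA cut-off optimization** — a from-scratch weighted-KS gene set
   enrichment analysis (running ES, gene-set-resampling NES/p/FDR) scans
   top-X% slices of the fold-enrichment ranking against the transcriptome-wide
   log2 transfected/control expression ranking; the slice with the most
   negative NES defines the Ago2-IP top set.
5. **Candidate selection and pathways** — final direct-target candidates are
   top-set genes repressed > 2-fold on the expression array, followed by
   hypergeometric over-representation against GMT gene sets
   (Benjamini–Hochberg corrected), Pearson miRNA–target correlation, and
   tumor up-regulation frequencies on paired cases.

All stages run end-to-end on a synthetic-data generator
(`mirtarget.synthetic`) that emulates the experiment — negative-binomial
counts for the four sequencing fractions, planted IP-enriched and repressed
true targets, UTRs with planted seed sites, and a 470-miRNA × 6-cell-line
screen with planted TS-miRNAs — so every claim the pipeline makes can be
scored against known ground truth.

## Worked example

Generate a ground-truthed dataset and run the full analysis:

```bash
mirtarget simulate --seed 17 --outdir demo
mirtarget run --seed 17 --outdir demo_run
```

which prints

```
wrote synthetic dataset to demo
cut-off 48%: 207 top-set genes, 138 candidates (precision 1.000) -> demo_run
```

`demo_run/report.json` holds the stage-by-stage summary; for seed 17:

```json
{
 "cutoff_rate_percent": 48.0,
 "top_set_size": 207,
 "n_candidates": 138,
 "n_motif_universe": 432,
 "optimum_nes": -3.7277316823932094,
 "optimum_p": 0.0,
 "ora_top_set": "CELL_CYCLE",
 "recovery": {"n_true_targets": 200, "true_positives": 138,
              "precision": 1.0, "sensitivity": 0.69}
}
```

Reading: of 4,000 simulated genes, 432 carry the seed heptamer in their 3′UTR;
the NES scan picks the top 48% of that motif universe (207 genes — the planted
targets are ~46% of the motif universe, so the scan finds the true target
depth); intersecting with > 2-fold-repressed genes leaves 138 candidates, all
of them true planted targets (precision 1.0), recovering 69% of the 200
planted targets. The candidate set's strongest pathway over-representation is
the generator's target-enriched `CELL_CYCLE` set. Other subcommands
(`screen`, `enrich`, `scan-seeds`, `gsea`, `cutoff-scan`, `select`, `ora`)
expose each stage separately on TSV/FASTA/GMT/RNK files; every command is
byte-reproducible given `--seed`.

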