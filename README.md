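# isletseq

Transcript-level quantification and cytokine-response analysis for bulk
RNA-seq of human pancreatic islets.

In type 1 diabetes, pro-inflammatory cytokines (IL-1β + IFN-γ) released
during insulitis reshape the islet transcriptome — both which genes are
expressed and how they are spliced. `isletseq` implements the analysis
chain used to characterise that response in a paired-donor design (five
islet preparations, each cultured with and without cytokines, compared
against a panel of background tissues), for anyone who wants to run,
audit, or benchmark this style of pipeline on segment-level count data:

1. **Segmentation** — project each gene's annotated transcripts (GTF) onto
   maximal exonic segments with constant transcript membership.
2. **Deconvolution** — recover per-transcript abundances θ from segment
   counts *c* by non-negative least squares, min‖Aθ − c‖² s.t. θ ≥ 0 with
   A[s,t] = len(s) for transcripts containing segment *s*; report
   RPKM = reads / (kb · million mapped reads) and the splice index
   SI(t) = RPKM(t) / Σ RPKM(gene).
3. **Differential calling** — per donor pair, a two-sided Fisher exact
   test on gene-vs-rest (or transcript-vs-rest-of-gene) read counts;
   Benjamini–Hochberg correction across the five pairs; a unit is called
   *up*/*down* only if significant (adjusted p < 0.05) in the same
   direction in ≥ 4 of 5 pairs with none opposite. Effect sizes are log2
   RPKM-sum ratios and splice-index differences.
4. **Tissue comparison & clustering** — the same caller applied islet-vs-
   background per tissue; sample similarity from Pearson correlation of
   log10 (power-law normalised) RPKM over genes with RPKM > 1 everywhere,
   clustered with (1 − PCC) distance and complete linkage.

A synthetic-data generator reproduces the study design with known ground
truth (isoform mix, injected expression and splicing effects, paired donor
variability, background tissues), so the whole chain is testable without
external data. Real data enters through the same interfaces: a GTF
annotation plus per-sample segment-count TSVs.

## Worked example

Run the numbered analysis scripts in order (each is a thin driver over the
library; outputs land under `results/`):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_quantify_transcripts.py
python analysis/03_cytokine_response.py
python analysis/04_tissue_similarity.py
python analysis/05_candidate_report.py
python analysis/06_operating_characteristics.py
```

Output of the first four (1000 genes, 5 donor pairs + 5 tissues, seed
20120308):

```
cohort: 1000 genes (350 multi-isoform), 15 samples, libraries 149,969-929,035 reads
injected truth: 160 cytokine-modified genes, 105 splice-shifted genes

quantified 1000 genes x 15 samples (0 genes flagged unidentifiable)
expressed (median control RPKM>1): 998 genes; in all control samples: 980; in some: 20

cytokine-modified genes: 317/1000 (32%): 75 up, 242 down
cytokine-modified spliceforms: 66 up, 65 down (of 824 transcripts in multi-isoform genes)
vs truth: 143/160 injected genes recovered (143 in the correct direction);
174 calls outside the injected set

islet-islet PCC range: 0.92-0.94; islet-tissue: -0.03-0.03
islet samples form a single clade: True
```

Reading the numbers: every injected expression effect that is recovered is
recovered in the correct direction, and the islet preparations cluster
tightly away from background tissues. The 174 calls outside the injected
set are the compositional footprint of a proportion-based test at
desk scale — strong asymmetric changes shift every other gene's library
share (discussed in `docs/methods.md`); on null cohorts with no injected
effects the false-call rate is ~0% for genes and ~2% for transcripts
(script 06).

The same pipeline runs as one command over a config file, or from Python:

```bash
isletseq run-all --out results/run --seed 7
```

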