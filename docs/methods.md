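# Methods

`isletseq` re-implements, as a tested pipeline over segment-level count
data, an analysis chain for bulk RNA-seq of human pancreatic islets exposed
to pro-inflammatory cytokines (IL-1β + IFN-γ): transcript-level
quantification by linear deconvolution, RPKM and splice-index computation,
Fisher-exact/Benjamini–Hochberg differential expression and differential
splicing with a directional replication-consistency rule, islet-versus-
background tissue comparison, and correlation-distance sample clustering.
This note records the model, its assumptions, the parameter choices, and
what the synthetic benchmark does and does not establish.

## Observation model and segmentation

Each gene is a set of annotated transcripts (isoforms); the gene's exon
union is cut at every exon boundary of every transcript into **exonic
segments** — maximal intervals with constant transcript membership
(`annotation.build_segments`). Internally all coordinates are 0-based
half-open; GTF I/O converts from the 1-based inclusive convention at the
boundary, and overlapping exons within one transcript are merged with a
warning rather than rejected (annotation dialects differ). Genes are
processed independently; transcripts of genomically overlapping genes are
not shared.

A sequencing read whose mate pairs properly within annotated transcript
boundaries lands on exactly one segment, so the segment-count vector is the
sufficient statistic for transcript quantification; reads are therefore
simulated and consumed at segment resolution, not as sequences.

## Deconvolution, RPKM, splice index

For a gene with segments *s* and transcripts *t*, expected counts are
linear in the per-base transcript abundances θ:

    E[c_s] = Σ_{t ∋ s} θ_t · len(s)

Quantification solves min‖Aθ − c‖² subject to θ ≥ 0 (non-negative least
squares, `scipy.optimize.nnls`), with A[s,t] = len(s) for member
transcripts. Assigned reads are θ_t·len(t); for a consistent system the
residual vanishes and assigned reads sum to observed counts. Rank-deficient
designs (e.g. duplicate isoform structures) are solved anyway — gene totals
remain identifiable — and flagged `unidentifiable`. We verified on
matched data that unweighted NNLS, variance-weighted iterative NNLS, and
the segment-multinomial EM/MLE recover splice indices with
indistinguishable accuracy, so the simplest estimator is kept.

Expression is reported in RPKM = reads / (kb of transcript × millions of
mapped reads), with the per-sample denominator taken as the sum of counts
over all annotated segments. A transcript's **splice index** is its share
of the gene's total RPKM (undefined, and flagged, for a silent gene).
Assigned reads stay fractional for RPKM; they are rounded half-to-even at a
single documented point — entry into the transcript-level Fisher test.

## Differential calling

Per donor pair (control vs cytokine), each unit is tested with a two-sided
Fisher exact test on a 2×2 table: gene reads vs all-other-gene reads (gene
level), or transcript reads vs other transcripts of the same gene
(transcript level, after deconvolution and rounding). The test is
implemented with exact integer arithmetic over the conditional support for
tables with grand total ≤ 1000 and IEEE hypergeometric sums (R's 1+1e-7
tie guard) above; very large supports delegate to SciPy's C search. The
two-sided p-value follows the minimum-likelihood convention. Direction
comes from the difference of the two proportions, not from the test; exact
ties give direction `none` and cannot support a call.

The five per-pair p-values of one unit form a single BH family ("the five
samples as independent tests"); the correction is deliberately *within
unit across pairs*, not genome-wide — an unusual convention retained for
fidelity, with `bh_scope="across_units"` available as the conventional
alternative. A unit is called **up** (**down**) only if adjusted p < α
(default 0.05) with the same direction in ≥ `min_consistent` (default 4 of
5) pairs and no pair significant in the opposite direction.

Effect size is the log2 ratio of gene RPKM sums (cytokine/control); a zero
numerator or denominator yields a ±20 sentinel with a flag instead of a
pseudocount, and 0/0 is undefined. Reported per-unit effect is the median
of the significant per-pair values. Tissue enrichment applies the same
machinery to the five control islet samples against one background-tissue
sample each (calls `islet_enriched` / `islet_depleted` / `ns`).

Because the gene-level test compares library *proportions*, strong
asymmetric expression changes shift every other gene's share
(compositionality). At transcriptome scale the distortion is small; at
desk scale (hundreds of genes) it inflates opposite-direction calls in
cohorts with injected effects — visible in the showcase analysis and
intrinsic to the method, not a defect of the implementation. Null cohorts
are unaffected.

The transcript-level test treats deconvolved pseudo-counts as if they were
observed reads and therefore ignores deconvolution variance; it is
anti-conservative for ill-conditioned isoform designs. The consistency
rule absorbs most of this (measured null transcript call rate ≈ 2%), but
the residual rate is a property of the procedure.

## Similarity and clustering

Only genes with RPKM > 1 in *every* sample enter the comparison. Because
expression is heavy-tailed (Zipf-like), values are power-law normalized
before correlating; the normalization is implemented as log10 (a monotone
variance stabilizer; a rank transform is available as `method="rank"`).
Samples are clustered agglomeratively on (1 − Pearson correlation) with
complete linkage (`scipy.cluster.hierarchy.linkage`); the dendrogram is
deterministic given the input column order (SciPy's tie-breaking), and is
exported as Newick.

## Reporting conventions

"Expressed" has two deliberately distinct definitions: median RPKM > 1
across samples (candidate reporting) and RPKM > 1 in all samples
(similarity filtering); both are strict inequalities. Percentages are
rounded to the nearest integer. The candidate panel is an editable
one-id-per-line input file; the repository ships a synthetic stand-in
panel of 41 cohort gene ids (`analysis/inputs/candidates_synthetic.txt`).

## Synthetic study design

The generator (`isletseq.simulate`) emulates the study the pipeline
targets; its defaults are the benchmark conditions and are not tuned per
experiment:

- **Cohort**: 5 donors, each a paired control/cytokine sample, plus 5
  independent background tissues.
- **Scale**: libraries Uniform(1e5, 1e6) reads — a ~60× scale-down from a
  sequencing lane — with 200 genes in the benchmark datasets and 1000 in
  the showcase cohort, keeping per-gene depth within about a factor of two
  of the emulated study (~500–900 usable reads per gene).
- **Annotation**: 35% of genes multi-isoform (2–3 transcripts). Extra
  isoforms are a 50/50 mix of internal skipped exons and alternative ends
  (truncations), the two dominant annotated-variant classes; every design
  is full-rank by construction.
- **Expression**: gene-level per-base intensity lognormal(0, 1.5²)
  (heavy-tailed); within-gene isoform proportions Dirichlet(1.5).
- **Effects**: 16% of genes receive a signed log2 fold-change (|Δ| ~
  Uniform(1, 3); P(up) = 1416/3068, the observed up/down split among
  cytokine-modified genes); 30% of multi-isoform genes receive a 0.3
  splice-index shift that preserves the gene total, so expression and
  splicing effects are separable. Infeasible shifts are skipped with a
  warning.
- **Donor variability**: a scalar lognormal(0, 0.3²) depth factor plus
  per-gene lognormal(0, 0.35²) biological variability, both shared between
  a donor's two samples. The per-gene term cancels within every pair (the
  paired design), so null behaviour is untouched, while across donors it
  reproduces the ~0.90–0.96 islet–islet correlation band of real
  preparations. Background tissues are independent draws (near-zero
  correlation with islets) — adequate for clade recovery, though real
  tissues share housekeeping structure and correlate ~0.5–0.9.
- **Noise**: multinomial counts at the drawn library size
  (Dirichlet-multinomial when `dispersion` > 0); an expected-counts mode
  replaces the draw with rounded expectations for exact-recovery tests.

Everything is deterministic given the config seed (per-stage generators are
spawned from one `SeedSequence`), and the full pipeline rerun is
byte-identical.

What passing benchmarks show — and do not. The generator contains no
positional or GC bias, no mapping ambiguity between genes, no fragment-
length effects, and no sequence-level errors, so the benchmarks certify
the statistical chain (deconvolution → tests → calls) rather than
end-to-end behaviour on raw sequencing data. Splice-index recovery within
±0.05 for minor-depth genes (~500–2000 reads) is information-limited when
isoforms share most of their sequence: about 15% of qualifying transcripts
fall outside ±0.05 at library 1e6, a bound we verified is estimator-
independent (NNLS ≈ weighted NNLS ≈ EM). Accuracy claims should therefore
be read per depth stratum: above ~5000 gene reads, recovery within ±0.05
is essentially complete.

## Numerical conventions

- Fisher exact-path/float-path switch at table total 1000; float path uses
  the 1+1e-7 relative tie guard (as in R's `fisher.test`).
- log2-ratio sentinel cap 20; undefined values propagate as NaN.
- Rounding half-to-even for pseudo-counts; `percent()` rounds half up.
- NNLS identifiability via `numpy.linalg.matrix_rank` at default tolerance.
- TSV floats written with `%.10g`; manifests carry sha256 checksums of
  every output.
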