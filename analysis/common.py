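"""Shared configuration for the numbered analysis scripts.

Downstream scripts (02-05) consume only the files script 01 writes — the
GTF annotation and the per-sample segment-count TSVs — exercising the same
external interface an external counting step would use.
"""

import glob
import os

from isletseq.annotation import build_segments, parse_gtf
from isletseq.pipeline import load_counts_tsv
from isletseq.simulate import SimConfig

RESULTS_DIR = os.path.join(os.path.dirname(__file__), "..", "results")
COHORT_DIR = os.path.join(RESULTS_DIR, "cohort")

#: The emulated study: 5 paired donor samples + 5 background tissues, with
#: the gene count chosen so per-gene read depth matches the sequencing study
#: the design emulates (see docs/methods.md).
COHORT_CONFIG = SimConfig(n_genes=1000, seed=20120308)


def load_cohort():
    """(genes, segments, samples) from the files written by script 01."""
    gtf = os.path.join(COHORT_DIR, "annotation.gtf")
    if not os.path.exists(gtf):
        raise SystemExit("cohort not found - run analysis/01_simulate_cohort.py first")
    genes = parse_gtf(gtf)
    segments = {g.gene_id: build_segments(g) for g in genes}
    samples = sorted(
        (load_counts_tsv(p) for p in glob.glob(os.path.join(COHORT_DIR, "counts", "*.tsv"))),
        key=lambda s: (s.condition == "background", s.sample_id),
    )
    return genes, segments, samples


def donor_pairs(samples):
    by_key = {(s.donor_id, s.condition): s.sample_id for s in samples}
    donors = sorted({s.donor_id for s in samples if s.condition != "background"})
    return [(by_key[(d, "control")], by_key[(d, "cytokine")]) for d in donors]
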