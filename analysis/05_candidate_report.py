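#!/usr/bin/env python
"""Report expression of a candidate-gene panel in the islet cohort.

The panel file (analysis/inputs/candidates_synthetic.txt) is an editable
one-id-per-line list; here it holds a synthetic stand-in panel of 41 cohort
gene ids mirroring the size of a GWAS candidate list.  A candidate counts
as expressed when its median control RPKM exceeds 1; the summary percentage
is rounded to the nearest integer.  Writes results/candidates/.
"""

import os
import sys

sys.path.insert(0, os.path.dirname(__file__))
from common import RESULTS_DIR, donor_pairs, load_cohort

from isletseq.quantify import gene_rpkm_matrix, quantify_all
from isletseq.report import candidate_gene_report

PANEL = os.path.join(os.path.dirname(__file__), "inputs", "candidates_synthetic.txt")
OUT = os.path.join(RESULTS_DIR, "candidates")


def main() -> None:
    genes, segments, samples = load_cohort()
    quants = quantify_all(genes, segments, samples)
    pairs = donor_pairs(samples)
    control_ids = [c for c, _ in pairs]
    cytokine_ids = [k for _, k in pairs]
    matrix = gene_rpkm_matrix(quants, control_ids + cytokine_ids)

    with open(PANEL) as fh:
        panel = [line.strip() for line in fh if line.strip() and not line.startswith("#")]
    table, pct, unresolved = candidate_gene_report(
        panel, matrix[control_ids], matrix[cytokine_ids]
    )
    os.makedirs(OUT, exist_ok=True)
    table.to_csv(os.path.join(OUT, "candidate_report.tsv"), sep="\t", index=False,
                 float_format="%.6g")
    n_expressed = int(table["expressed"].sum())
    print(f"candidate panel: {len(panel)} genes ({len(unresolved)} unresolved)")
    print(f"expressed in islets (median control RPKM>1): {n_expressed}/{len(panel) - len(unresolved)} = {pct}%")
    print(f"wrote {OUT}/")


if __name__ == "__main__":
    main()
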