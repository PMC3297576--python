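#!/usr/bin/env python
"""Compare islet expression profiles with background tissues.

Two views: (a) per-gene islet-vs-tissue enrichment calls using the same
Fisher/BH/consistency machinery as the cytokine analysis; (b) sample-level
similarity — genes with RPKM>1 in all samples, log10 (power-law)
normalization, pairwise Pearson correlation, and a (1 - PCC)
complete-linkage dendrogram.  Writes results/similarity/.
"""

import os
import sys

sys.path.insert(0, os.path.dirname(__file__))
from common import RESULTS_DIR, donor_pairs, load_cohort

import numpy as np

from isletseq.differential import tissue_enrichment_table
from isletseq.quantify import gene_read_counts, gene_rpkm_matrix, quantify_all
from isletseq.similarity import cluster_samples, forms_clade, to_newick

OUT = os.path.join(RESULTS_DIR, "similarity")


def main() -> None:
    genes, segments, samples = load_cohort()
    quants = quantify_all(genes, segments, samples)
    reads = {s.sample_id: gene_read_counts(genes, segments, s) for s in samples}
    totals = {s.sample_id: s.total_mapped_reads for s in samples}
    control_ids = [c for c, _ in donor_pairs(samples)]
    background_ids = [s.sample_id for s in samples if s.condition == "background"]
    os.makedirs(OUT, exist_ok=True)

    enrichment = tissue_enrichment_table(
        genes, reads, totals, quants, control_ids, background_ids
    )
    enrichment.to_csv(os.path.join(OUT, "tissue_enrichment.tsv"), sep="\t", index=False,
                      float_format="%.6g")
    per_tissue = enrichment.groupby("tissue")["call"].value_counts().unstack(fill_value=0)
    print("islet-vs-tissue enrichment calls per background tissue:")
    print(per_tissue.to_string())

    matrix = gene_rpkm_matrix(quants, control_ids + background_ids)
    z, corr, labels = cluster_samples(matrix)
    corr.rename_axis("sample_id").to_csv(os.path.join(OUT, "pcc_matrix.tsv"), sep="\t",
                                         float_format="%.6g")
    with open(os.path.join(OUT, "dendrogram.nwk"), "w") as fh:
        fh.write(to_newick(z, labels) + "\n")

    islet_block = corr.loc[control_ids, control_ids].to_numpy()
    islet_pcc = islet_block[np.triu_indices_from(islet_block, k=1)]
    cross = corr.loc[control_ids, background_ids].to_numpy().ravel()
    print(f"islet-islet PCC range: {islet_pcc.min():.2f}-{islet_pcc.max():.2f}; "
          f"islet-tissue: {cross.min():.2f}-{cross.max():.2f}")
    print("islet samples form a single clade:", forms_clade(z, labels, control_ids))
    print(f"wrote {OUT}/")


if __name__ == "__main__":
    main()
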