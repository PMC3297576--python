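"""Expressed-gene summaries and candidate-gene reporting.

The study uses two distinct notions of "expressed", kept separate here:

* *median rule* (candidate reporting): median RPKM across samples strictly
  greater than the threshold;
* *all-samples rule* (similarity filtering): RPKM above the threshold in
  every sample (see :func:`isletseq.similarity.expressed_in_all_filter`).

Percentages are rounded to the nearest integer, matching the reporting
style of dataset-level summaries (e.g. 25 of 41 candidates -> 61%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def percent(numerator: int, denominator: int) -> int | None:
    """Nearest-integer percentage; None when the denominator is zero."""
    if denominator == 0:
        return None
    return int(np.floor(100.0 * numerator / denominator + 0.5))


@dataclass(frozen=True)
class ExpressedSummary:
    expressed_median: frozenset[str]
    expressed_in_all: frozenset[str]
    expressed_in_some: frozenset[str]
    per_sample_detected: dict[str, int]

    @property
    def n_expressed_median(self) -> int:
        return len(self.expressed_median)

    @property
    def median_genes_per_sample(self) -> float:
        return float(np.median(list(self.per_sample_detected.values())))


def expressed_gene_set(
    gene_rpkm: pd.DataFrame, threshold: float = 1.0
) -> ExpressedSummary:
    """Classify genes by the median rule and by per-sample detection.

    ``gene_rpkm`` is genes x samples.  A gene is *detected* in a sample when
    its RPKM exceeds the threshold there; "expressed in all" is the
    intersection of the per-sample detections, "in some" the rest of the
    union.
    """
    if gene_rpkm.shape[1] < 1:
        raise ValueError("at least one sample required")
    detected = gene_rpkm > threshold
    expressed_median = frozenset(gene_rpkm.index[gene_rpkm.median(axis=1) > threshold])
    in_all = frozenset(gene_rpkm.index[detected.all(axis=1)])
    in_any = frozenset(gene_rpkm.index[detected.any(axis=1)])
    return ExpressedSummary(
        expressed_median=expressed_median,
        expressed_in_all=in_all,
        expressed_in_some=in_any - in_all,
        per_sample_detected={s: int(detected[s].sum()) for s in gene_rpkm.columns},
    )


def candidate_gene_report(
    candidate_ids: list[str],
    control_rpkm: pd.DataFrame,
    cytokine_rpkm: pd.DataFrame | None = None,
    threshold: float = 1.0,
) -> tuple[pd.DataFrame, int | None, list[str]]:
    """Per-candidate expression report.

    Returns ``(table, percent_expressed, unresolved_ids)``.  A candidate is
    expressed when its median control RPKM exceeds the threshold; the
    percentage is over the resolvable candidates, rounded to the nearest
    integer.
    """
    unresolved = [g for g in candidate_ids if g not in control_rpkm.index]
    resolved = [g for g in candidate_ids if g in control_rpkm.index]
    rows = []
    for gid in resolved:
        med_ctl = float(control_rpkm.loc[gid].median())
        med_cyt = (
            float(cytokine_rpkm.loc[gid].median())
            if cytokine_rpkm is not None and gid in cytokine_rpkm.index
            else float("nan")
        )
        rows.append((gid, med_ctl, med_cyt, med_ctl > threshold))
    table = pd.DataFrame(
        rows, columns=["gene_id", "median_rpkm_control", "median_rpkm_cytokine", "expressed"]
    )
    n_expressed = int(table["expressed"].sum()) if not table.empty else 0
    return table, percent(n_expressed, len(resolved)), unresolved


def modified_fraction_summary(n_up: int, n_down: int, n_present: int) -> dict:
    """Dataset-level summary arithmetic: counts of modified genes and the
    nearest-integer percentage of present genes they represent."""
    n_modified = n_up + n_down
    if n_modified > n_present:
        raise ValueError("modified genes cannot exceed present genes")
    return {
        "n_up": n_up,
        "n_down": n_down,
        "n_modified": n_modified,
        "n_present": n_present,
        "percent_modified": percent(n_modified, n_present),
    }
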