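"""Cytokine-response calling: Fisher exact tests, BH correction, and the
directional-consistency rule.

For every donor sample pair the change in a unit (gene or transcript) is
tested with a two-sided Fisher exact test on a 2x2 read-count table:

* gene level: reads mapped to the gene vs reads mapped to all other genes,
  cytokine condition against control;
* transcript level: reads assigned to the transcript after deconvolution
  (rounded half-to-even to integers) vs reads assigned to all other
  transcripts of the same gene.

The five per-pair p-values of a unit form one Benjamini-Hochberg family
("the 5 samples as independent tests") — the correction is within-unit
across sample pairs, not across the genome; a ``bh_scope`` switch provides
the conventional across-units alternative.  A unit is called *up* (*down*)
only if its adjusted p-value is < alpha with the same sign of the proportion
difference in at least ``min_consistent`` of the pairs and no pair is
significant in the opposite direction; everything else is *unchanged*.

Effect size is reported as the log2 ratio of gene RPKM sums (cytokine over
control); divisions by zero are capped at a documented +/-20 sentinel rather
than hidden behind pseudocounts.  Differential splicing uses the difference
in splice indices alongside the transcript-level test.  Tissue enrichment
applies the same machinery to the five control islet samples against one
background-tissue sample, reporting the median of the significant log2
differences.
"""

from __future__ import annotations

import bisect
import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .annotation import GeneModel
from .quantify import GeneQuant

#: Sentinel magnitude for log2 ratios with a zero numerator or denominator.
LOG2_CAP = 20.0

#: Tables with grand total up to this bound take the exact integer path;
#: larger tables use IEEE hypergeometric pmf sums (R's 1+1e-7 tie guard).
_EXACT_TOTAL_LIMIT = 1000

_REL_TIE_GUARD = 1.0 + 1e-7


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value for the table [[a, b], [c, d]].

    Two-sided in the minimum-likelihood sense: the p-value sums the
    probabilities of all tables with the observed margins that are no more
    probable than the observed one.  Small tables are evaluated in exact
    integer arithmetic; large ones through the hypergeometric pmf.
    """
    for name, v in (("a", a), ("b", b), ("c", c), ("d", d)):
        if v < 0 or v != int(v):
            raise ValueError(f"table cell {name} must be a non-negative integer, got {v}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    if n <= _EXACT_TOTAL_LIMIT:
        obs = math.comb(r1, a) * math.comb(r2, c1 - a)
        total = sum(
            v
            for x in range(lo, hi + 1)
            if (v := math.comb(r1, x) * math.comb(r2, c1 - x)) <= obs
        )
        return min(1.0, total / math.comb(n, c1))
    if hi - lo + 1 > 4096:
        # very large supports (highly expressed genes): scipy's C search
        from scipy.stats import fisher_exact as _scipy_fisher

        return float(_scipy_fisher([[a, b], [c, d]])[1])
    support = np.arange(lo, hi + 1)
    log_pmf = (
        _log_comb(r1, support)
        + _log_comb(r2, c1 - support)
        - _log_comb(n, c1)
    )
    pmf = np.exp(log_pmf)
    p_obs = pmf[a - lo]
    return float(min(1.0, pmf[pmf <= p_obs * _REL_TIE_GUARD].sum()))


def fisher_pvalues_for_margins(r1: int, r2: int, c1: int) -> dict[int, float]:
    """Exact two-sided Fisher p-values for every table with the given margins.

    The p-value of a 2x2 table depends only on its margins and the observed
    top-left cell ``a``; this evaluates the whole conditional support in one
    pass of exact integer arithmetic (suitable for exhaustive verification
    and batch testing of small tables).
    """
    if r1 < 0 or r2 < 0 or not 0 <= c1 <= r1 + r2:
        raise ValueError("invalid margins")
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    numerators = {a: math.comb(r1, a) * math.comb(r2, c1 - a) for a in range(lo, hi + 1)}
    denominator = math.comb(r1 + r2, c1)
    ordered = sorted(numerators.values())
    prefix = list(itertools.accumulate(ordered))
    return {
        a: min(1.0, prefix[bisect.bisect_right(ordered, num) - 1] / denominator)
        for a, num in numerators.items()
    }


def fisher_gene_pair(
    gene_reads_cyt: int,
    total_reads_cyt: int,
    gene_reads_ctl: int,
    total_reads_ctl: int,
) -> tuple[float, int]:
    """Gene vs all-other-genes table for one sample pair.

    Returns ``(p, sign)`` where sign is the sign of the difference in gene
    read proportions (cytokine minus control); the test itself is two-sided.
    """
    if total_reads_cyt <= 0 or total_reads_ctl <= 0:
        raise ValueError("condition totals must be > 0")
    if gene_reads_cyt > total_reads_cyt or gene_reads_ctl > total_reads_ctl:
        raise ValueError("gene reads exceed condition total")
    p = fisher_exact_two_sided(
        gene_reads_cyt,
        total_reads_cyt - gene_reads_cyt,
        gene_reads_ctl,
        total_reads_ctl - gene_reads_ctl,
    )
    diff = gene_reads_cyt / total_reads_cyt - gene_reads_ctl / total_reads_ctl
    return p, (diff > 0) - (diff < 0)


def fisher_transcript_pair(
    transcript_reads_cyt: int,
    other_reads_cyt: int,
    transcript_reads_ctl: int,
    other_reads_ctl: int,
) -> tuple[float, int]:
    """Transcript vs other-transcripts-of-the-gene table for one pair."""
    for v in (transcript_reads_cyt, other_reads_cyt, transcript_reads_ctl, other_reads_ctl):
        if v < 0:
            raise ValueError("read counts must be non-negative")
    tot_cyt = transcript_reads_cyt + other_reads_cyt
    tot_ctl = transcript_reads_ctl + other_reads_ctl
    p = fisher_exact_two_sided(
        transcript_reads_cyt, other_reads_cyt, transcript_reads_ctl, other_reads_ctl
    )
    prop_cyt = transcript_reads_cyt / tot_cyt if tot_cyt else 0.0
    prop_ctl = transcript_reads_ctl / tot_ctl if tot_ctl else 0.0
    diff = prop_cyt - prop_ctl
    return p, (diff > 0) - (diff < 0)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment within one family."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def log2_expression_change(rpkm_sum_cyt: float, rpkm_sum_ctl: float, cap: float = LOG2_CAP) -> float:
    """log2(cytokine / control) of gene RPKM sums, with a +/-cap sentinel
    when one side is zero and NaN when both are."""
    if rpkm_sum_cyt < 0 or rpkm_sum_ctl < 0:
        raise ValueError("RPKM sums must be non-negative")
    if rpkm_sum_cyt == 0 and rpkm_sum_ctl == 0:
        return float("nan")
    if rpkm_sum_ctl == 0:
        return cap
    if rpkm_sum_cyt == 0:
        return -cap
    return math.log2(rpkm_sum_cyt / rpkm_sum_ctl)


def delta_splice_index(si_cyt: float | None, si_ctl: float | None) -> float:
    """Cytokine minus control splice index; undefined values propagate."""
    if si_cyt is None or si_ctl is None:
        return float("nan")
    if math.isnan(si_cyt) or math.isnan(si_ctl):
        return float("nan")
    for v in (si_cyt, si_ctl):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"splice index {v} outside [0, 1]")
    return si_cyt - si_ctl


@dataclass(frozen=True)
class PairTestResult:
    unit_id: str
    pair_id: str
    p_raw: float
    p_adj: float
    log2_ratio: float
    sign: int  # sign of the proportion difference (cytokine - control)

    def direction(self, alpha: float = 0.05) -> str:
        if self.sign == 0 or not self.p_adj < alpha:
            return "none"
        return "up" if self.sign > 0 else "down"


@dataclass(frozen=True)
class DifferentialCall:
    unit_id: str
    per_pair: tuple[PairTestResult, ...]
    call: str  # up | down | unchanged
    n_significant_up: int
    n_significant_down: int
    median_significant_log2: float


def call_unit(
    per_pair: Sequence[PairTestResult],
    alpha: float = 0.05,
    min_consistent: int = 4,
) -> DifferentialCall:
    """Apply the >=4-of-5 directional-consistency rule to one unit."""
    if len(per_pair) < min_consistent:
        raise ValueError(
            f"unit {per_pair[0].unit_id if per_pair else '?'}: "
            f"{len(per_pair)} pairs < min_consistent={min_consistent}"
        )
    n_up = sum(1 for r in per_pair if r.direction(alpha) == "up")
    n_down = sum(1 for r in per_pair if r.direction(alpha) == "down")
    if n_up >= min_consistent and n_down == 0:
        call = "up"
    elif n_down >= min_consistent and n_up == 0:
        call = "down"
    else:
        call = "unchanged"
    sig_ratios = [
        r.log2_ratio
        for r in per_pair
        if r.direction(alpha) != "none" and not math.isnan(r.log2_ratio)
    ]
    median = float(np.median(sig_ratios)) if sig_ratios else float("nan")
    return DifferentialCall(
        unit_id=per_pair[0].unit_id,
        per_pair=tuple(per_pair),
        call=call,
        n_significant_up=n_up,
        n_significant_down=n_down,
        median_significant_log2=median,
    )


def _adjust_families(
    long: pd.DataFrame, bh_scope: str, unit_col: str = "unit_id"
) -> pd.DataFrame:
    """Attach p_adj per the selected BH family definition."""
    long = long.copy()
    if bh_scope == "per_unit":
        long["p_adj"] = long.groupby(unit_col, sort=False)["p_raw"].transform(
            lambda s: bh_adjust(s.to_numpy())
        )
    elif bh_scope == "across_units":
        long["p_adj"] = long.groupby("pair_id", sort=False)["p_raw"].transform(
            lambda s: bh_adjust(s.to_numpy())
        )
    else:
        raise ValueError(f"unknown bh_scope {bh_scope!r}")
    return long


def differential_expression(
    genes: Sequence[GeneModel],
    gene_reads: Mapping[str, Mapping[str, int]],
    totals: Mapping[str, int],
    quants: Mapping[str, Mapping[str, GeneQuant]],
    pairs: Sequence[tuple[str, str]],
    alpha: float = 0.05,
    min_consistent: int = 4,
    bh_scope: str = "per_unit",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene-level cytokine-response calls.

    Parameters
    ----------
    gene_reads : sample_id -> gene_id -> integer segment-count sum
    totals : sample_id -> total mapped reads
    quants : sample_id -> gene_id -> GeneQuant (for RPKM-sum log2 ratios)
    pairs : (control_sample_id, cytokine_sample_id) per donor

    Returns the long per-pair table and the per-gene call table.
    """
    rows = []
    for gene in genes:
        gid = gene.gene_id
        for ctl_id, cyt_id in pairs:
            p, sign = fisher_gene_pair(
                gene_reads[cyt_id][gid],
                totals[cyt_id],
                gene_reads[ctl_id][gid],
                totals[ctl_id],
            )
            ratio = log2_expression_change(
                quants[cyt_id][gid].gene_rpkm, quants[ctl_id][gid].gene_rpkm
            )
            rows.append((gid, f"{ctl_id}|{cyt_id}", p, ratio, sign))
    long = pd.DataFrame(rows, columns=["unit_id", "pair_id", "p_raw", "log2_ratio", "sign"])
    long = _adjust_families(long, bh_scope)

    calls = _calls_from_long(long, alpha, min_consistent)
    return long, calls


def _calls_from_long(long: pd.DataFrame, alpha: float, min_consistent: int) -> pd.DataFrame:
    records = []
    for unit_id, grp in long.groupby("unit_id", sort=False):
        per_pair = [
            PairTestResult(unit_id, r.pair_id, r.p_raw, r.p_adj, r.log2_ratio, int(r.sign))
            for r in grp.itertuples()
        ]
        call = call_unit(per_pair, alpha=alpha, min_consistent=min_consistent)
        records.append(
            (
                unit_id,
                call.call,
                call.n_significant_up,
                call.n_significant_down,
                call.median_significant_log2,
            )
        )
    return pd.DataFrame(
        records,
        columns=["unit_id", "call", "n_significant_up", "n_significant_down", "median_significant_log2"],
    )


def _rounded_assigned(quant: GeneQuant) -> dict[str, int]:
    # half-to-even: the single documented rounding point before the
    # transcript-level Fisher test
    return {
        t.transcript_id: int(round(t.assigned_reads)) for t in quant.transcripts
    }


def differential_splicing(
    genes: Sequence[GeneModel],
    quants: Mapping[str, Mapping[str, GeneQuant]],
    pairs: Sequence[tuple[str, str]],
    alpha: float = 0.05,
    min_consistent: int = 4,
    bh_scope: str = "per_unit",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Transcript-level (splice-index) cytokine-response calls.

    Single-transcript genes are skipped (the within-gene table is undefined
    for them).  Pairs where a gene is silent in either condition contribute
    an undefined splice-index difference and a p-value of 1.
    """
    rows = []
    for gene in genes:
        if not gene.is_multi_isoform:
            continue
        gid = gene.gene_id
        for ctl_id, cyt_id in pairs:
            q_ctl, q_cyt = quants[ctl_id][gid], quants[cyt_id][gid]
            reads_ctl = _rounded_assigned(q_ctl)
            reads_cyt = _rounded_assigned(q_cyt)
            tot_ctl = sum(reads_ctl.values())
            tot_cyt = sum(reads_cyt.values())
            si_ctl = q_ctl.splice_indices
            si_cyt = q_cyt.splice_indices
            for tx in gene.transcripts:
                tid = tx.transcript_id
                if tot_ctl == 0 or tot_cyt == 0:
                    p, sign = 1.0, 0
                else:
                    p, sign = fisher_transcript_pair(
                        reads_cyt[tid],
                        tot_cyt - reads_cyt[tid],
                        reads_ctl[tid],
                        tot_ctl - reads_ctl[tid],
                    )
                dsi = delta_splice_index(
                    None if si_cyt is None else si_cyt[tid],
                    None if si_ctl is None else si_ctl[tid],
                )
                rows.append((tid, gid, f"{ctl_id}|{cyt_id}", p, dsi, sign))
    long = pd.DataFrame(
        rows, columns=["unit_id", "gene_id", "pair_id", "p_raw", "delta_si", "sign"]
    )
    if long.empty:
        return long.assign(p_adj=[]), pd.DataFrame(
            columns=["unit_id", "call", "n_significant_up", "n_significant_down", "median_significant_log2"]
        )
    long["log2_ratio"] = long["delta_si"]  # effect column consumed by call_unit
    long = _adjust_families(long, bh_scope)
    calls = _calls_from_long(long, alpha, min_consistent)
    calls = calls.rename(columns={"median_significant_log2": "median_significant_delta_si"})
    gene_of = long.drop_duplicates("unit_id").set_index("unit_id")["gene_id"]
    calls.insert(1, "gene_id", calls["unit_id"].map(gene_of))
    return long.drop(columns="log2_ratio"), calls


def tissue_enrichment_call(
    islet_gene_reads: Sequence[int],
    islet_totals: Sequence[int],
    islet_rpkm: Sequence[float],
    background_gene_reads: int,
    background_total: int,
    background_rpkm: float,
    alpha: float = 0.05,
    min_consistent: int = 4,
) -> tuple[str, float]:
    """Compare one gene across islet control samples against one background
    tissue.  Returns ``(call, median_significant_log2)`` with call in
    {islet_enriched, islet_depleted, ns}."""
    if len(islet_gene_reads) < min_consistent:
        raise ValueError("fewer islet samples than min_consistent")
    p_values, signs, ratios = [], [], []
    for reads, total, rp in zip(islet_gene_reads, islet_totals, islet_rpkm):
        p, sign = fisher_gene_pair(reads, total, background_gene_reads, background_total)
        p_values.append(p)
        signs.append(sign)
        ratios.append(log2_expression_change(rp, background_rpkm))
    p_adj = bh_adjust(p_values)
    sig_up = [i for i in range(len(p_values)) if p_adj[i] < alpha and signs[i] > 0]
    sig_down = [i for i in range(len(p_values)) if p_adj[i] < alpha and signs[i] < 0]
    if len(sig_up) >= min_consistent and not sig_down:
        call = "islet_enriched"
    elif len(sig_down) >= min_consistent and not sig_up:
        call = "islet_depleted"
    else:
        call = "ns"
    sig = [ratios[i] for i in sig_up + sig_down if not math.isnan(ratios[i])]
    return call, (float(np.median(sig)) if sig else float("nan"))


def tissue_enrichment_table(
    genes: Sequence[GeneModel],
    gene_reads: Mapping[str, Mapping[str, int]],
    totals: Mapping[str, int],
    quants: Mapping[str, Mapping[str, GeneQuant]],
    islet_control_ids: Sequence[str],
    background_ids: Sequence[str],
    alpha: float = 0.05,
    min_consistent: int = 4,
) -> pd.DataFrame:
    """Per-gene, per-tissue enrichment calls (islet controls vs background)."""
    rows = []
    for gene in genes:
        gid = gene.gene_id
        islet_reads = [gene_reads[s][gid] for s in islet_control_ids]
        islet_tot = [totals[s] for s in islet_control_ids]
        islet_rpkm = [quants[s][gid].gene_rpkm for s in islet_control_ids]
        for bg in background_ids:
            call, med = tissue_enrichment_call(
                islet_reads,
                islet_tot,
                islet_rpkm,
                gene_reads[bg][gid],
                totals[bg],
                quants[bg][gid].gene_rpkm,
                alpha=alpha,
                min_consistent=min_consistent,
            )
            rows.append((gid, bg, call, med))
    return pd.DataFrame(rows, columns=["gene_id", "tissue", "call", "median_significant_log2"])
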