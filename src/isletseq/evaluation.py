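"""Dataset-level benchmark runs: error control, power, and recovery of the
pipeline measured on the synthetic study design.

Every function here *runs the package end to end* on freshly generated data
and measures an operating characteristic: false-call rates under a null
cohort, power against injected expression and splicing effects, splice-index
recovery accuracy, clustering recovery of the islet clade, and byte-level
reproducibility of the pipeline.  They are consumed by the acceptance tests
and the reproduction script.
"""

from __future__ import annotations

import numpy as np

from .annotation import build_segments, segment_id
from .differential import differential_expression, differential_splicing
from .quantify import (
    deconvolve_gene,
    design_matrix,
    gene_read_counts,
    gene_rpkm_matrix,
    quantify_all,
    quantify_sample,
)
from .similarity import cluster_samples, forms_clade
from .simulate import SimConfig, simulate_annotation, simulate_dataset

#: Desk-scale cohort used for the benchmark datasets (see docs/methods.md
#: for the depth-matching rationale behind these study conditions).
BENCH_GENES = 200


def _differential_calls(config: SimConfig):
    ds = simulate_dataset(config)
    quants = quantify_all(ds.genes, ds.segments, ds.samples)
    reads = {s.sample_id: gene_read_counts(ds.genes, ds.segments, s) for s in ds.samples}
    totals = {s.sample_id: s.total_mapped_reads for s in ds.samples}
    pairs = [(c.sample_id, k.sample_id) for c, k in ds.donor_pairs]
    _, de_calls = differential_expression(ds.genes, reads, totals, quants, pairs)
    _, as_calls = differential_splicing(ds.genes, quants, pairs)
    return ds, reads, de_calls, as_calls


def null_call_rates(n_datasets: int = 20, base_seed: int = 0) -> dict:
    """Fraction of genes/transcripts called changed when nothing is.

    Replicate cohorts with ``frac_de_genes = frac_as_genes = 0`` (5 donor
    pairs, default scaled-down libraries); pooled across datasets.
    """
    n_gene = called_gene = n_tx = called_tx = 0
    for i in range(n_datasets):
        cfg = SimConfig(
            n_genes=BENCH_GENES,
            frac_de_genes=0.0,
            frac_as_genes=0.0,
            background_tissues=(),
            seed=base_seed + i,
        )
        _, _, de_calls, as_calls = _differential_calls(cfg)
        n_gene += len(de_calls)
        called_gene += int((de_calls["call"] != "unchanged").sum())
        if not as_calls.empty:
            n_tx += len(as_calls)
            called_tx += int((as_calls["call"] != "unchanged").sum())
    return {
        "gene_rate": called_gene / n_gene,
        "transcript_rate": called_tx / n_tx,
        "n_genes": n_gene,
        "n_transcripts": n_tx,
    }


def power_rates(n_datasets: int = 5, base_seed: int = 0) -> dict:
    """Detection rates for injected effects.

    Expression: genes with injected |log2FC| = 2 and median control reads
    >= 200, called in the true direction.  Splicing: genes given a 0.3
    splice-index shift, any transcript called.  Also reports the
    transcript-level call rate among DE-only genes (splicing specificity).
    """
    de_ok = de_tot = as_ok = as_tot = 0
    spec_tx = spec_called = 0
    for i in range(n_datasets):
        cfg = SimConfig(
            n_genes=BENCH_GENES,
            frac_de_genes=0.16,
            de_log2fc_magnitude_range=(2.0, 2.0),
            frac_as_genes=0.30,
            as_shift=0.30,
            background_tissues=(),
            seed=base_seed + i,
        )
        ds, reads, de_calls, as_calls = _differential_calls(cfg)
        ctl_ids = [c.sample_id for c, _ in ds.donor_pairs]
        de_idx = de_calls.set_index("unit_id")["call"]
        as_by_gene = (
            as_calls.groupby("gene_id")["call"].apply(lambda s: (s != "unchanged").any())
            if not as_calls.empty
            else {}
        )
        as_n_by_gene = (
            as_calls.groupby("gene_id")["call"].apply(lambda s: (s != "unchanged").sum())
            if not as_calls.empty
            else {}
        )
        for gene in ds.genes:
            gt = ds.truth.genes[gene.gene_id]
            if gt.de_sign != 0:
                med_ctl = float(np.median([reads[s][gene.gene_id] for s in ctl_ids]))
                if med_ctl >= 200:
                    de_tot += 1
                    de_ok += de_idx[gene.gene_id] == ("up" if gt.de_sign > 0 else "down")
            if gt.as_flag:
                as_tot += 1
                as_ok += bool(as_by_gene.get(gene.gene_id, False))
            elif gt.de_sign != 0 and gene.is_multi_isoform:
                spec_tx += len(gene.transcripts)
                spec_called += int(as_n_by_gene.get(gene.gene_id, 0))
    return {
        "de_power": de_ok / de_tot if de_tot else float("nan"),
        "as_power": as_ok / as_tot if as_tot else float("nan"),
        "de_only_transcript_call_rate": spec_called / spec_tx if spec_tx else float("nan"),
        "n_de": de_tot,
        "n_as": as_tot,
    }


def _recovery_config(seed: int, library: int = 1_000_000) -> SimConfig:
    return SimConfig(
        n_genes=BENCH_GENES,
        frac_multi_isoform=1.0,
        frac_de_genes=0.0,
        frac_as_genes=0.0,
        n_sample_pairs=2,
        library_size_range=(library, library),
        background_tissues=(),
        seed=seed,
    )


def noiseless_recovery_max_rel_err(seed: int = 0) -> dict:
    """Deconvolve exact (unrounded) expected segment counts for random
    identifiable 2-3-isoform genes and report the worst relative abundance
    error."""
    cfg = _recovery_config(seed)
    genes = simulate_annotation(cfg)
    rng = np.random.default_rng(seed + 1)
    worst = 0.0
    n = 0
    for gene in genes:
        segs = build_segments(gene)
        a = design_matrix(gene, segs)
        theta_true = rng.uniform(0.5, 10.0, size=len(gene.transcripts))
        counts = a @ theta_true
        theta, _, _, identifiable = deconvolve_gene(gene, segs, counts)
        if not identifiable:
            continue
        worst = max(worst, float(np.max(np.abs(theta - theta_true) / theta_true)))
        n += 1
    return {"max_rel_err": worst, "n_genes": n}


def si_recovery_rate(n_seeds: int = 3, base_seed: int = 0) -> dict:
    """Fraction of transcripts (true SI >= 0.2, gene reads >= 500) whose
    deconvolved splice index lands within +/-0.05 of truth under multinomial
    noise at library size 1e6."""
    ok = tot = 0
    for i in range(n_seeds):
        ds = simulate_dataset(_recovery_config(base_seed + i))
        sample = ds.samples[0]
        quants = quantify_sample(ds.genes, ds.segments, sample)
        for gene in ds.genes:
            q = quants[gene.gene_id]
            if q.gene_reads < 500:
                continue
            true_si = ds.truth.genes[gene.gene_id].splice_index("control")
            est = q.splice_indices
            if true_si is None or est is None:
                continue
            for tx, ts in zip(gene.transcripts, true_si):
                if ts < 0.2:
                    continue
                tot += 1
                ok += abs(est[tx.transcript_id] - ts) <= 0.05
    return {"rate": ok / tot, "n_transcripts": tot}


def clustering_recovery_rate(n_seeds: int = 50, base_seed: int = 0) -> dict:
    """Fraction of simulated cohorts (5 islet controls + 5 background
    tissues) in which the islet samples form one clade under (1 - PCC)
    complete linkage."""
    ok = 0
    for i in range(n_seeds):
        cfg = SimConfig(
            n_genes=BENCH_GENES,
            frac_de_genes=0.0,
            frac_as_genes=0.0,
            seed=base_seed + i,
        )
        ds = simulate_dataset(cfg)
        quants = quantify_all(ds.genes, ds.segments, ds.samples)
        ctl = [c.sample_id for c, _ in ds.donor_pairs]
        bg = [s.sample_id for s in ds.background_samples]
        matrix = gene_rpkm_matrix(quants, ctl + bg)
        z, _, labels = cluster_samples(matrix)
        ok += forms_clade(z, labels, ctl)
    return {"rate": ok / n_seeds, "n_seeds": n_seeds}


def pipeline_determinism(tmp_dir: str, seed: int = 0) -> bool:
    """Run the full pipeline twice with one config; outputs must be
    byte-identical (checksums compare every written file)."""
    import os

    from .pipeline import RunConfig, run_pipeline

    sim = SimConfig(
        n_genes=40,
        library_size_range=(20_000, 60_000),
        background_tissues=("adipose", "liver", "muscle"),
        seed=seed,
    )
    manifests = []
    for run in ("a", "b"):
        config = RunConfig(output_dir=os.path.join(tmp_dir, run), sim=sim)
        manifests.append(run_pipeline(config))
    return manifests[0]["checksums"] == manifests[1]["checksums"]
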