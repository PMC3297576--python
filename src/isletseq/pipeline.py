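"""End-to-end orchestration: segmentation -> quantification -> differential
calling -> tissue comparison -> similarity -> reports.

``run_pipeline`` drives the whole analysis for one dataset (synthetic by
default, or loaded from a GTF plus segment-count TSVs) and writes TSV
tables, a Newick dendrogram, and a JSON run manifest with parameter values
and per-stage row counts plus sha256 checksums of every output.  Rerunning
with an identical config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import pandas as pd
import yaml

from . import __version__
from .annotation import parse_gtf, build_segments, write_gtf, write_segments_bed
from .differential import (
    differential_expression,
    differential_splicing,
    tissue_enrichment_table,
)
from .quantify import gene_read_counts, gene_rpkm_matrix, quantify_all
from .report import candidate_gene_report, expressed_gene_set, modified_fraction_summary
from .similarity import cluster_samples, to_newick
from .simulate import (
    Dataset,
    SampleCounts,
    SimConfig,
    simulate_dataset,
    write_counts_tsv,
    write_manifest,
    write_truth_json,
)


@dataclass(frozen=True)
class RunConfig:
    output_dir: str
    sim: SimConfig = field(default_factory=SimConfig)
    alpha: float = 0.05
    min_consistent: int = 4
    bh_scope: str = "per_unit"
    rpkm_threshold: float = 1.0
    candidate_genes: tuple[str, ...] = ()
    annotation_path: str | None = None  # load instead of simulate
    counts_paths: tuple[str, ...] = ()
    sample_sheet: str | None = None  # YAML: sample_id/condition/donor_id rows

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        sim = SimConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.pop("sim", {}).items()
        })
        for key in ("candidate_genes", "counts_paths"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(sim=sim, **raw)


def load_counts_tsv(path: str) -> SampleCounts:
    """Read one segment-count table written by :func:`write_counts_tsv` (or an
    external counting step using the same columns and header comments)."""
    meta: dict[str, str] = {}
    with open(path) as handle:
        for line in handle:
            if not line.startswith("#"):
                break
            for token in line[1:].strip().split("\t"):
                if "=" in token:
                    key, value = token.split("=", 1)
                    meta[key] = value
    table = pd.read_csv(path, sep="\t", comment="#")
    counts = dict(zip(table["segment_id"], table["count"].astype(int)))
    sample_id = meta.get("sample_id", os.path.splitext(os.path.basename(path))[0])
    return SampleCounts(
        sample_id=sample_id,
        condition=meta.get("condition", "control"),
        donor_id=meta.get("donor_id", sample_id),
        counts=counts,
        total_mapped_reads=sum(counts.values()),
    )


def load_dataset(config: RunConfig) -> Dataset:
    """Assemble a Dataset from external files named in the config."""
    if config.annotation_path is None:
        raise ValueError("annotation_path required to load an external dataset")
    genes = tuple(parse_gtf(config.annotation_path))
    segments = {g.gene_id: build_segments(g) for g in genes}
    samples = tuple(load_counts_tsv(p) for p in config.counts_paths)
    if config.sample_sheet:
        with open(config.sample_sheet) as handle:
            sheet = {row["sample_id"]: row for row in yaml.safe_load(handle)["samples"]}
        samples = tuple(
            SampleCounts(
                sample_id=s.sample_id,
                condition=sheet[s.sample_id]["condition"],
                donor_id=sheet[s.sample_id]["donor_id"],
                counts=s.counts,
                total_mapped_reads=s.total_mapped_reads,
            )
            for s in samples
        )
    from .simulate import GroundTruth

    return Dataset(
        config=config.sim,
        genes=genes,
        segments=segments,
        truth=GroundTruth(genes={}),
        samples=samples,
    )


def _sha256(path: str) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _write_tsv(frame: pd.DataFrame, path: str, header_comment: str) -> None:
    with open(path, "w") as handle:
        handle.write(f"# {header_comment}\n")
        frame.to_csv(handle, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def run_pipeline(config: RunConfig, dataset: Dataset | None = None) -> dict:
    """Execute every stage and write all outputs under ``config.output_dir``.

    Returns the run manifest (also written as ``manifest.json``).
    """
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    if dataset is None:
        if config.annotation_path is not None:
            dataset = load_dataset(config)
        else:
            dataset = simulate_dataset(config.sim)

    genes, segments = dataset.genes, dataset.segments
    write_gtf(genes, os.path.join(out, "annotation.gtf"))
    write_segments_bed(genes, os.path.join(out, "segments.bed"))
    counts_dir = os.path.join(out, "counts")
    os.makedirs(counts_dir, exist_ok=True)
    for sample in dataset.samples:
        write_counts_tsv(dataset, sample, os.path.join(counts_dir, f"{sample.sample_id}.tsv"))
    if dataset.truth.genes:
        write_truth_json(dataset, os.path.join(out, "truth.json"))
    write_manifest(dataset, os.path.join(out, "samples.json"))

    # quantification
    quants = quantify_all(genes, segments, dataset.samples)
    totals = {s.sample_id: s.total_mapped_reads for s in dataset.samples}
    reads = {s.sample_id: gene_read_counts(genes, segments, s) for s in dataset.samples}
    sample_order = [s.sample_id for s in dataset.samples]
    quant_rows = []
    for sid in sample_order:
        for gene in genes:
            q = quants[sid][gene.gene_id]
            si = q.splice_indices
            for tq in q.transcripts:
                quant_rows.append(
                    (
                        sid,
                        gene.gene_id,
                        tq.transcript_id,
                        tq.assigned_reads,
                        tq.rpkm,
                        float("nan") if si is None else si[tq.transcript_id],
                        "" if q.identifiable else "unidentifiable",
                    )
                )
    quant_table = pd.DataFrame(
        quant_rows,
        columns=["sample_id", "gene_id", "transcript_id", "assigned_reads", "rpkm", "splice_index", "flags"],
    )
    _write_tsv(
        quant_table,
        os.path.join(out, "transcript_quant.tsv"),
        "per-sample transcript quantification (NNLS deconvolution; RPKM; splice index)",
    )

    # differential expression and splicing over donor pairs
    pairs = [(c.sample_id, k.sample_id) for c, k in dataset.donor_pairs]
    de_long, de_calls = differential_expression(
        genes, reads, totals, quants, pairs,
        alpha=config.alpha, min_consistent=config.min_consistent, bh_scope=config.bh_scope,
    )
    as_long, as_calls = differential_splicing(
        genes, quants, pairs,
        alpha=config.alpha, min_consistent=config.min_consistent, bh_scope=config.bh_scope,
    )
    _write_tsv(de_long, os.path.join(out, "de_gene_pairs.tsv"),
               "per-pair gene Fisher tests (p_raw/p_adj, log2 RPKM ratio, sign)")
    _write_tsv(de_calls, os.path.join(out, "de_gene_calls.tsv"),
               f"gene calls: BH<{config.alpha} in >={config.min_consistent} pairs, none opposite")
    _write_tsv(as_long, os.path.join(out, "as_transcript_pairs.tsv"),
               "per-pair transcript Fisher tests and splice-index differences")
    _write_tsv(as_calls, os.path.join(out, "as_transcript_calls.tsv"),
               "transcript (differential-splicing) calls under the consistency rule")

    # tissue enrichment: islet controls vs each background tissue
    control_ids = [c.sample_id for c, _ in dataset.donor_pairs]
    background_ids = [s.sample_id for s in dataset.background_samples]
    if background_ids:
        tissue_table = tissue_enrichment_table(
            genes, reads, totals, quants, control_ids, background_ids,
            alpha=config.alpha, min_consistent=config.min_consistent,
        )
        _write_tsv(tissue_table, os.path.join(out, "tissue_enrichment.tsv"),
                   "islet-vs-background enrichment calls (median significant log2)")
    else:
        tissue_table = pd.DataFrame()

    # similarity: islet controls + backgrounds
    rpkm_all = gene_rpkm_matrix(quants, sample_order)
    similarity_cols = control_ids + background_ids
    newick = ""
    pcc_table = pd.DataFrame()
    if len(similarity_cols) >= 3:
        z, pcc_table, labels = cluster_samples(
            rpkm_all[similarity_cols], threshold=config.rpkm_threshold
        )
        newick = to_newick(z, labels)
        with open(os.path.join(out, "dendrogram.nwk"), "w") as handle:
            handle.write(newick + "\n")
        _write_tsv(
            pcc_table.reset_index(names="sample_id"),
            os.path.join(out, "pcc_matrix.tsv"),
            "pairwise PCC of power-law-normalized gene RPKM (RPKM>threshold in all samples)",
        )

    # expressed-gene and candidate reporting (control samples)
    control_rpkm = rpkm_all[control_ids]
    expressed = expressed_gene_set(control_rpkm, threshold=config.rpkm_threshold)
    n_up = int((de_calls["call"] == "up").sum())
    n_down = int((de_calls["call"] == "down").sum())
    summary = modified_fraction_summary(n_up, n_down, len(expressed.expressed_median) or len(genes))
    summary.update(
        {
            "n_expressed_median": expressed.n_expressed_median,
            "n_expressed_in_all": len(expressed.expressed_in_all),
            "n_expressed_in_some": len(expressed.expressed_in_some),
            "median_genes_per_sample": expressed.median_genes_per_sample,
            "n_as_up": int((as_calls["call"] == "up").sum()) if not as_calls.empty else 0,
            "n_as_down": int((as_calls["call"] == "down").sum()) if not as_calls.empty else 0,
        }
    )
    with open(os.path.join(out, "summary.json"), "w") as handle:
        json.dump(summary, handle, indent=1, sort_keys=True)

    if config.candidate_genes:
        cyt_ids = [k.sample_id for _, k in dataset.donor_pairs]
        table, pct, unresolved = candidate_gene_report(
            list(config.candidate_genes), control_rpkm, rpkm_all[cyt_ids],
            threshold=config.rpkm_threshold,
        )
        _write_tsv(table, os.path.join(out, "candidate_report.tsv"),
                   f"candidate genes: {pct}% expressed (median control RPKM rule); "
                   f"unresolved: {','.join(unresolved) or 'none'}")

    outputs = sorted(
        os.path.join(dirpath, name)
        for dirpath, _dirs, files in os.walk(out)
        for name in files
        if name != "manifest.json"
    )
    manifest = {
        "isletseq_version": __version__,
        "parameters": {
            "alpha": config.alpha,
            "min_consistent": config.min_consistent,
            "bh_scope": config.bh_scope,
            "rpkm_threshold": config.rpkm_threshold,
            "sim": asdict(config.sim),
        },
        "stage_rows": {
            "genes": len(genes),
            "segments": sum(len(v) for v in segments.values()),
            "samples": len(dataset.samples),
            "transcript_quant": len(quant_table),
            "de_gene_pairs": len(de_long),
            "de_gene_calls": len(de_calls),
            "as_transcript_calls": len(as_calls),
            "tissue_enrichment": len(tissue_table),
        },
        "summary": summary,
        "checksums": {os.path.relpath(p, out): _sha256(p) for p in outputs},
    }
    with open(os.path.join(out, "manifest.json"), "w") as handle:
        json.dump(manifest, handle, indent=1, sort_keys=True)
    return manifest
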