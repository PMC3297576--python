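"""Transcript-level quantification from segment counts.

Reads observed on exonic segments shared by several transcripts are
deconvolved per gene by non-negative least squares: with design matrix
``A[s, t] = length(s)`` if transcript ``t`` contains segment ``s`` (else 0)
and count vector ``c``, solve ``min ||A . theta - c||^2`` subject to
``theta >= 0``.  ``theta_t`` is the transcript's per-base abundance;
``assigned_reads(t) = theta_t * length_bp(t)``.  For a consistent system the
residual vanishes and assigned reads sum to the observed counts.

Expression is reported in RPKM (reads per kilobase of transcript per million
mapped reads); the per-sample denominator is the sum of counts over all
annotated segments.  A transcript's splice index is its share of the gene's
total RPKM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import nnls

from .annotation import ExonicSegment, GeneModel, segment_id
from .simulate import SampleCounts


@dataclass(frozen=True)
class TranscriptQuant:
    transcript_id: str
    length_bp: int
    theta: float  # reads per exonic base
    assigned_reads: float
    rpkm: float


@dataclass(frozen=True)
class GeneQuant:
    gene_id: str
    transcripts: tuple[TranscriptQuant, ...]
    identifiable: bool
    residual: float

    @property
    def gene_reads(self) -> float:
        return sum(t.assigned_reads for t in self.transcripts)

    @property
    def gene_rpkm(self) -> float:
        return sum(t.rpkm for t in self.transcripts)

    @property
    def splice_indices(self) -> dict[str, float] | None:
        """Transcript share of gene RPKM; None (undefined) for a silent gene."""
        total = self.gene_rpkm
        if total == 0:
            return None
        return {t.transcript_id: t.rpkm / total for t in self.transcripts}


def design_matrix(gene: GeneModel, segments: Sequence[ExonicSegment]) -> np.ndarray:
    a = np.zeros((len(segments), len(gene.transcripts)))
    for i, seg in enumerate(segments):
        for j, tx in enumerate(gene.transcripts):
            if tx.transcript_id in seg.members:
                a[i, j] = seg.length_bp
    return a


def deconvolve_gene(
    gene: GeneModel,
    segments: Sequence[ExonicSegment],
    counts: Sequence[float],
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Solve the per-gene NNLS system.

    Returns ``(theta, assigned_reads, residual, identifiable)``.  A gene with
    zero counts yields all-zero abundances.  A rank-deficient design is still
    solved (gene-level totals remain identifiable) but flagged
    ``identifiable=False``.
    """
    if len(counts) != len(segments):
        raise ValueError(f"gene {gene.gene_id}: counts/segments length mismatch")
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError(f"gene {gene.gene_id}: negative counts")
    a = design_matrix(gene, segments)
    identifiable = int(np.linalg.matrix_rank(a)) == len(gene.transcripts)
    if c.sum() == 0:
        theta = np.zeros(len(gene.transcripts))
        return theta, theta.copy(), 0.0, identifiable
    theta, residual = nnls(a, c)
    lengths = np.array([t.length_bp for t in gene.transcripts], dtype=float)
    return theta, theta * lengths, float(residual), identifiable


def rpkm(assigned_reads: float, length_bp: int, total_mapped_reads: int) -> float:
    """reads / (kb of transcript x millions of mapped reads)."""
    if length_bp <= 0:
        raise ValueError(f"length_bp must be > 0, got {length_bp}")
    if total_mapped_reads <= 0:
        raise ValueError(f"total_mapped_reads must be > 0, got {total_mapped_reads}")
    if assigned_reads < 0:
        raise ValueError(f"assigned_reads must be >= 0, got {assigned_reads}")
    return assigned_reads / ((length_bp / 1_000) * (total_mapped_reads / 1_000_000))


def splice_index(gene_quant: GeneQuant) -> dict[str, float] | None:
    return gene_quant.splice_indices


def quantify_sample(
    genes: Sequence[GeneModel],
    segments: Mapping[str, Sequence[ExonicSegment]],
    sample: SampleCounts,
) -> dict[str, GeneQuant]:
    """Deconvolve every gene of one sample and attach RPKM values."""
    total = sample.total_mapped_reads
    quants: dict[str, GeneQuant] = {}
    for gene in genes:
        segs = segments[gene.gene_id]
        counts = [sample.counts.get(segment_id(gene, seg), 0) for seg in segs]
        theta, assigned, residual, identifiable = deconvolve_gene(gene, segs, counts)
        tq = tuple(
            TranscriptQuant(
                transcript_id=tx.transcript_id,
                length_bp=tx.length_bp,
                theta=float(th),
                assigned_reads=float(reads),
                rpkm=rpkm(float(reads), tx.length_bp, total) if total > 0 else 0.0,
            )
            for tx, th, reads in zip(gene.transcripts, theta, assigned)
        )
        quants[gene.gene_id] = GeneQuant(gene.gene_id, tq, identifiable, residual)
    return quants


def quantify_all(
    genes: Sequence[GeneModel],
    segments: Mapping[str, Sequence[ExonicSegment]],
    samples: Sequence[SampleCounts],
) -> dict[str, dict[str, GeneQuant]]:
    """sample_id -> gene_id -> GeneQuant for a whole cohort."""
    return {s.sample_id: quantify_sample(genes, segments, s) for s in samples}


def gene_rpkm_matrix(
    quants: Mapping[str, Mapping[str, GeneQuant]],
    sample_order: Sequence[str] | None = None,
):
    """Genes x samples DataFrame of gene RPKM (sum over transcripts)."""
    import pandas as pd

    sample_ids = list(sample_order) if sample_order is not None else list(quants)
    gene_ids = list(next(iter(quants.values())).keys())
    data = {
        sid: [quants[sid][gid].gene_rpkm for gid in gene_ids] for sid in sample_ids
    }
    return pd.DataFrame(data, index=gene_ids)


def gene_read_counts(
    genes: Sequence[GeneModel],
    segments: Mapping[str, Sequence[ExonicSegment]],
    sample: SampleCounts,
) -> dict[str, int]:
    """Integer reads per gene: sum of the gene's segment counts (no
    deconvolution involved) — the unit entering the gene-level Fisher test."""
    out: dict[str, int] = {}
    for gene in genes:
        out[gene.gene_id] = sum(
            sample.counts.get(segment_id(gene, seg), 0) for seg in segments[gene.gene_id]
        )
    return out
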