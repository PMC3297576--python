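"""Synthetic islet RNA-seq datasets with known ground truth.

The generator emulates the study design the pipeline is built for: five
donor islet preparations, each sequenced under a control condition and after
a 48-h pro-inflammatory cytokine exposure (paired samples), plus a panel of
unrelated background tissues.  It produces

* an annotation of single- and multi-isoform genes (a configurable fraction
  of genes carries annotated alternative splicing — skipped exons or
  alternative ends — with at least one transcript-distinguishing segment);
* per-gene, per-transcript ground-truth abundances (reads per exonic base),
  with a configurable fraction of genes given a signed cytokine log2
  fold-change, and a fraction of multi-isoform genes given a splice-index
  shift that preserves the gene total (so differential expression and
  differential splicing are separable signals);
* per-sample segment-level read counts: expected segment intensity is
  sum over member transcripts of abundance x segment length, scaled to a
  drawn library size and observed through a multinomial (or
  Dirichlet-multinomial when ``dispersion`` > 0).

Reads are simulated directly at segment resolution: the quantification
pipeline consumes reads already paired within annotated transcript
boundaries, for which segment counts are the sufficient statistic.
Everything is deterministic given the config (including its seed).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .annotation import ExonicSegment, GeneModel, Transcript, build_segments, segment_id

#: Up/down split among cytokine-modified genes in the emulated study.
DEFAULT_UP_PROBABILITY = 1416 / 3068


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for one synthetic dataset.

    Defaults mirror the emulated study: 5 paired donor samples, ~35% of
    genes with annotated alternative splicing, ~16% of genes
    cytokine-modified, and library sizes spanning a ~5-10x range
    (scaled down from the tens of millions of reads of a sequencing lane).
    """

    n_genes: int = 200
    frac_multi_isoform: float = 0.35
    n_sample_pairs: int = 5
    library_size_range: tuple[int, int] = (100_000, 1_000_000)
    frac_de_genes: float = 0.16
    de_log2fc_magnitude_range: tuple[float, float] = (1.0, 3.0)
    de_up_probability: float = DEFAULT_UP_PROBABILITY
    frac_as_genes: float = 0.30
    as_shift: float = 0.30
    dispersion: float = 0.0
    donor_log_sd: float = 0.30
    donor_gene_sd: float = 0.35
    expression_log_sd: float = 1.5
    background_tissues: tuple[str, ...] = (
        "adipose",
        "colon",
        "kidney",
        "liver",
        "muscle",
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_multi_isoform", "frac_de_genes", "frac_as_genes"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise ValueError(f"invalid library_size_range {self.library_size_range}")
        if self.n_sample_pairs < 2:
            raise ValueError("n_sample_pairs must be >= 2")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


@dataclass(frozen=True)
class GeneTruth:
    """Ground truth for one gene: per-transcript reads-per-base abundances."""

    gene_id: str
    control_theta: tuple[float, ...]  # aligned with GeneModel.transcripts
    cytokine_theta: tuple[float, ...]
    de_sign: int = 0  # +1 up, -1 down, 0 unchanged
    log2fc: float = 0.0
    as_flag: bool = False

    def splice_index(self, condition: str) -> tuple[float, ...] | None:
        theta = self.control_theta if condition == "control" else self.cytokine_theta
        total = sum(theta)
        if total == 0:
            return None
        return tuple(t / total for t in theta)


@dataclass(frozen=True)
class GroundTruth:
    genes: dict[str, GeneTruth]
    background_theta: dict[str, dict[str, tuple[float, ...]]] = field(default_factory=dict)


@dataclass(frozen=True)
class SampleCounts:
    sample_id: str
    condition: str  # control | cytokine | background
    donor_id: str
    counts: dict[str, int]  # segment_id -> count
    total_mapped_reads: int

    def __post_init__(self) -> None:
        if self.total_mapped_reads != sum(self.counts.values()):
            raise ValueError(
                f"sample {self.sample_id}: total_mapped_reads inconsistent with counts"
            )


@dataclass(frozen=True)
class Dataset:
    """A simulated cohort: annotation, segments, truth, and samples."""

    config: SimConfig
    genes: tuple[GeneModel, ...]
    segments: dict[str, list[ExonicSegment]]
    truth: GroundTruth
    samples: tuple[SampleCounts, ...]

    @property
    def donor_pairs(self) -> list[tuple[SampleCounts, SampleCounts]]:
        """(control, cytokine) sample pairs, one per donor."""
        by_key = {(s.donor_id, s.condition): s for s in self.samples}
        donors = sorted({s.donor_id for s in self.samples if s.condition != "background"})
        return [(by_key[(d, "control")], by_key[(d, "cytokine")]) for d in donors]

    @property
    def background_samples(self) -> list[SampleCounts]:
        return [s for s in self.samples if s.condition == "background"]


def _rngs(config: SimConfig) -> dict[str, np.random.Generator]:
    """Independent per-stage generators derived from the config seed."""
    root = np.random.SeedSequence(config.seed)
    names = ("annotation", "truth", "effects", "counts")
    return {name: np.random.default_rng(seq) for name, seq in zip(names, root.spawn(4))}


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def simulate_annotation(config: SimConfig, rng: np.random.Generator | None = None) -> list[GeneModel]:
    """Build a synthetic annotation with the requested isoform mix.

    Multi-isoform genes get 2-3 transcripts constructed so every transcript
    pair is distinguished by at least one segment with a proper member
    subset (a skipped internal exon or a dropped terminal exon), which makes
    the deconvolution design full rank.
    """
    if rng is None:
        rng = _rngs(config)["annotation"]
    n_multi = round(config.n_genes * config.frac_multi_isoform)
    multi_flags = np.zeros(config.n_genes, dtype=bool)
    multi_flags[:n_multi] = True
    rng.shuffle(multi_flags)

    genes: list[GeneModel] = []
    cursor = 1000
    for i in range(config.n_genes):
        gene_id = f"G{i + 1:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        if multi_flags[i]:
            n_exons = int(rng.integers(3, 7))
            n_tx = int(rng.integers(2, 4)) if n_exons >= 4 else 2
        else:
            n_exons = int(rng.integers(1, 4))
            n_tx = 1
        lengths = rng.integers(100, 401, size=n_exons)
        gaps = rng.integers(100, 501, size=n_exons)
        exons: list[tuple[int, int]] = []
        pos = cursor
        for length, gap in zip(lengths, gaps):
            exons.append((pos, pos + int(length)))
            pos += int(length) + int(gap)
        cursor = pos + 5000

        transcripts = [Transcript(f"{gene_id}.1", gene_id, tuple(exons))]
        used: set[tuple[tuple[int, int], ...]] = {tuple(exons)}
        skipped: set[int] = set()
        for k in range(2, n_tx + 1):
            # alternative spliceforms: either an internal skipped exon or an
            # alternative end (truncation), the two dominant RefSeq variant
            # classes; both leave a transcript-distinguishing segment
            variant: tuple[tuple[int, int], ...] | None = None
            if rng.random() < 0.5:
                choices = [j for j in range(1, n_exons - 1) if j not in skipped]
                if choices:
                    skip = int(rng.choice(choices))
                    skipped.add(skip)
                    variant = tuple(e for j, e in enumerate(exons) if j != skip)
            if variant is None or variant in used:
                cuts_avail = [
                    j for j in range(1, n_exons) if tuple(exons[:j]) not in used
                ]
                if cuts_avail:
                    variant = tuple(exons[: int(rng.choice(cuts_avail))])
            if variant is None or variant in used:
                continue
            used.add(variant)
            transcripts.append(Transcript(f"{gene_id}.{k}", gene_id, variant))
        genes.append(GeneModel(gene_id, "chr1", strand, tuple(transcripts)))
    return genes


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def baseline_truth(
    genes: Sequence[GeneModel], config: SimConfig, rng: np.random.Generator | None = None
) -> GroundTruth:
    """Draw control abundances; cytokine starts identical (no effects yet).

    Gene-level per-base intensity is lognormal (heavy-tailed, Zipf-like
    expression); transcript proportions within a gene are Dirichlet.
    Background tissues get independent draws, so their profiles decorrelate
    from the islet profile.
    """
    if rng is None:
        rng = _rngs(config)["truth"]

    def draw_profile() -> dict[str, tuple[float, ...]]:
        profile = {}
        for gene in genes:
            total = float(rng.lognormal(mean=0.0, sigma=config.expression_log_sd))
            k = len(gene.transcripts)
            si = rng.dirichlet(np.full(k, 1.5)) if k > 1 else np.ones(1)
            profile[gene.gene_id] = tuple(float(total * p) for p in si)
        return profile

    islet = draw_profile()
    gene_truths = {
        gene_id: GeneTruth(gene_id, theta, theta) for gene_id, theta in islet.items()
    }
    background = {tissue: draw_profile() for tissue in config.background_tissues}
    return GroundTruth(genes=gene_truths, background_theta=background)


def _gene_total_reads(gene: GeneModel, theta: Sequence[float]) -> float:
    return sum(t.length_bp * th for t, th in zip(gene.transcripts, theta))


def _shift_splice_index(
    gene: GeneModel, theta: tuple[float, ...], target_idx: int, shift: float
) -> tuple[float, ...] | None:
    """Move one transcript's splice index by ``shift`` (sign chosen to stay
    feasible), preserving the gene's total expected reads.  Returns None when
    the shift cannot be applied."""
    total_theta = sum(theta)
    if total_theta == 0:
        return None
    si = np.asarray(theta) / total_theta
    s = si[target_idx]
    if s + shift <= 1.0:
        new_s = s + shift
    elif s - shift >= 0.0:
        new_s = s - shift
    else:
        return None
    rest = 1.0 - s
    if rest <= 0:  # the transcript already carries everything
        return None
    new_si = si * (1.0 - new_s) / rest
    new_si[target_idx] = new_s
    # rescale so expected gene reads (theta . lengths) are preserved
    lengths = np.array([t.length_bp for t in gene.transcripts], dtype=float)
    old_reads = float(np.dot(np.asarray(theta), lengths))
    denom = float(np.dot(new_si, lengths))
    scale = old_reads / denom
    return tuple(float(p * scale) for p in new_si)


def inject_effects(
    truth: GroundTruth,
    genes: Sequence[GeneModel],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> GroundTruth:
    """Mark DE and AS genes and apply the effects to the cytokine abundances.

    DE: signed log2 fold-change scales the whole cytokine abundance vector.
    AS: a splice-index shift redistributes abundance among transcripts while
    preserving the gene's expected total reads, so the two effects are
    separable.  Genes where the shift is infeasible are skipped with a
    warning.
    """
    if rng is None:
        rng = _rngs(config)["effects"]
    gene_by_id = {g.gene_id: g for g in genes}
    gene_ids = [g.gene_id for g in genes]

    n_de = round(len(gene_ids) * config.frac_de_genes)
    de_ids = set(rng.choice(gene_ids, size=n_de, replace=False)) if n_de else set()
    multi_ids = [g.gene_id for g in genes if g.is_multi_isoform]
    n_as = round(len(multi_ids) * config.frac_as_genes)
    as_ids = set(rng.choice(multi_ids, size=n_as, replace=False)) if n_as else set()

    new_genes: dict[str, GeneTruth] = {}
    for gene_id in gene_ids:
        gt = truth.genes[gene_id]
        gene = gene_by_id[gene_id]
        theta = gt.control_theta
        as_flag = False
        if gene_id in as_ids:
            target = int(rng.integers(0, len(theta)))
            shifted = _shift_splice_index(gene, theta, target, config.as_shift)
            if shifted is None:
                warnings.warn(
                    f"gene {gene_id}: splice-index shift {config.as_shift} infeasible; skipped",
                    stacklevel=2,
                )
            else:
                theta = shifted
                as_flag = True
        de_sign, log2fc = 0, 0.0
        if gene_id in de_ids:
            magnitude = float(rng.uniform(*config.de_log2fc_magnitude_range))
            de_sign = 1 if rng.random() < config.de_up_probability else -1
            log2fc = de_sign * magnitude
            theta = tuple(t * 2.0**log2fc for t in theta)
        new_genes[gene_id] = GeneTruth(
            gene_id,
            control_theta=gt.control_theta,
            cytokine_theta=theta,
            de_sign=de_sign,
            log2fc=log2fc,
            as_flag=as_flag,
        )
    return GroundTruth(genes=new_genes, background_theta=truth.background_theta)


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def expected_segment_counts(
    gene: GeneModel, segments: Sequence[ExonicSegment], theta: Sequence[float]
) -> np.ndarray:
    """Expected reads per segment: sum over member transcripts of
    abundance x segment length (unnormalized)."""
    theta_by_tx = dict(zip(gene.transcript_ids, theta))
    return np.array(
        [
            seg.length_bp * sum(theta_by_tx[tx] for tx in seg.members)
            for seg in segments
        ]
    )


def _sample_intensities(
    genes: Sequence[GeneModel],
    segments: Mapping[str, Sequence[ExonicSegment]],
    profile: Mapping[str, Sequence[float]],
) -> tuple[list[str], np.ndarray]:
    seg_ids: list[str] = []
    lam: list[float] = []
    for gene in genes:
        expected = expected_segment_counts(gene, segments[gene.gene_id], profile[gene.gene_id])
        for seg, value in zip(segments[gene.gene_id], expected):
            seg_ids.append(segment_id(gene, seg))
            lam.append(float(value))
    return seg_ids, np.asarray(lam)


def _observe(
    lam: np.ndarray,
    library_size: int,
    rng: np.random.Generator,
    dispersion: float,
    expected_counts: bool,
    sample_id: str,
) -> np.ndarray:
    total = lam.sum()
    if total <= 0:
        raise ValueError(f"sample {sample_id}: all-zero abundance vector")
    p = lam / total
    if expected_counts:
        return np.rint(library_size * p).astype(int)
    if dispersion > 0:
        alpha = np.clip(p, 1e-12, None) / dispersion
        p = rng.dirichlet(alpha)
    return rng.multinomial(library_size, p)


def simulate_counts(
    genes: Sequence[GeneModel],
    segments: Mapping[str, Sequence[ExonicSegment]],
    truth: GroundTruth,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    expected_counts: bool = False,
) -> list[SampleCounts]:
    """Draw per-sample segment counts for all islet pairs and backgrounds.

    A per-donor lognormal factor scales both of a donor's samples (paired
    design).  ``expected_counts=True`` replaces the multinomial draw with
    rounded expectations (noiseless mode for exact-recovery tests).
    """
    if rng is None:
        rng = _rngs(config)["counts"]
    lo, hi = config.library_size_range
    samples: list[SampleCounts] = []

    gene_ids = [g.gene_id for g in genes]
    for d in range(1, config.n_sample_pairs + 1):
        donor = f"D{d}"
        factor = float(rng.lognormal(mean=0.0, sigma=config.donor_log_sd))
        # per-gene biological donor variability, shared between the donor's
        # control and cytokine samples (paired design: it cancels within a
        # pair but differentiates donors, as between real preparations)
        gene_factor = dict(
            zip(gene_ids, rng.lognormal(mean=0.0, sigma=config.donor_gene_sd, size=len(gene_ids)))
        )
        for condition in ("control", "cytokine"):
            profile = {
                gid: tuple(factor * gene_factor[gid] * t for t in (
                    gt.control_theta if condition == "control" else gt.cytokine_theta
                ))
                for gid, gt in truth.genes.items()
            }
            seg_ids, lam = _sample_intensities(genes, segments, profile)
            library = int(rng.integers(lo, hi + 1))
            sample_id = f"{donor}_{'ctl' if condition == 'control' else 'cyt'}"
            counts = _observe(lam, library, rng, config.dispersion, expected_counts, sample_id)
            samples.append(
                SampleCounts(
                    sample_id=sample_id,
                    condition=condition,
                    donor_id=donor,
                    counts=dict(zip(seg_ids, (int(c) for c in counts))),
                    total_mapped_reads=int(counts.sum()),
                )
            )

    for tissue in config.background_tissues:
        profile = truth.background_theta[tissue]
        seg_ids, lam = _sample_intensities(genes, segments, profile)
        library = int(rng.integers(lo, hi + 1))
        counts = _observe(lam, library, rng, config.dispersion, expected_counts, tissue)
        samples.append(
            SampleCounts(
                sample_id=tissue,
                condition="background",
                donor_id=tissue,
                counts=dict(zip(seg_ids, (int(c) for c in counts))),
                total_mapped_reads=int(counts.sum()),
            )
        )
    return samples


def simulate_dataset(config: SimConfig, expected_counts: bool = False) -> Dataset:
    """End-to-end generation: annotation -> truth -> effects -> counts."""
    rngs = _rngs(config)
    genes = simulate_annotation(config, rngs["annotation"])
    segments = {g.gene_id: build_segments(g) for g in genes}
    truth = baseline_truth(genes, config, rngs["truth"])
    truth = inject_effects(truth, genes, config, rngs["effects"])
    samples = simulate_counts(
        genes, segments, truth, config, rngs["counts"], expected_counts=expected_counts
    )
    return Dataset(
        config=config,
        genes=tuple(genes),
        segments=segments,
        truth=truth,
        samples=tuple(samples),
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_counts_tsv(dataset: Dataset, sample: SampleCounts, path: str) -> None:
    """Segment-count table: gene_id, segment_id, start, end, members, count."""
    with open(path, "w") as handle:
        handle.write("# isletseq segment counts\n")
        handle.write(
            f"# sample_id={sample.sample_id}\tcondition={sample.condition}\t"
            f"donor_id={sample.donor_id}\n"
        )
        handle.write("gene_id\tsegment_id\tstart\tend\tmembers\tcount\n")
        for gene in dataset.genes:
            for seg in dataset.segments[gene.gene_id]:
                sid = segment_id(gene, seg)
                handle.write(
                    f"{gene.gene_id}\t{sid}\t{seg.start}\t{seg.end}\t"
                    f"{','.join(sorted(seg.members))}\t{sample.counts.get(sid, 0)}\n"
                )


def write_truth_json(dataset: Dataset, path: str) -> None:
    payload = {
        "config": asdict(dataset.config),
        "genes": {
            gid: {
                "transcripts": list(
                    next(g for g in dataset.genes if g.gene_id == gid).transcript_ids
                ),
                "control_theta": list(gt.control_theta),
                "cytokine_theta": list(gt.cytokine_theta),
                "de_sign": gt.de_sign,
                "log2fc": gt.log2fc,
                "as_flag": gt.as_flag,
            }
            for gid, gt in dataset.truth.genes.items()
        },
    }
    with open(path, "w") as handle:
        json.dump(payload, handle, indent=1, sort_keys=True)


def write_manifest(dataset: Dataset, path: str) -> None:
    payload = {
        "n_genes": len(dataset.genes),
        "seed": dataset.config.seed,
        "samples": [
            {
                "sample_id": s.sample_id,
                "condition": s.condition,
                "donor_id": s.donor_id,
                "total_mapped_reads": s.total_mapped_reads,
            }
            for s in dataset.samples
        ],
    }
    with open(path, "w") as handle:
        json.dump(payload, handle, indent=1, sort_keys=True)
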