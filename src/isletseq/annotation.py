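"""Gene models and exonic segmentation.

A gene is represented by its annotated transcripts (ordered exon intervals on
one chromosome and strand).  For quantification, each gene is projected onto
*exonic segments*: the maximal genomic intervals over which the set of
covering transcripts is constant.  Segments are the observation unit — a
sequencing read landing in a segment is compatible with every transcript that
contains the segment, and with no other.

Coordinates are 0-based half-open internally; GTF input/output converts from
and to the 1-based inclusive convention at the boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator

from gffutils.feature import feature_from_line


class GtfParseError(ValueError):
    """Raised when a GTF line cannot be interpreted."""


class AnnotationError(ValueError):
    """Raised when an annotation is internally inconsistent."""


@dataclass(frozen=True)
class Transcript:
    """One annotated spliceform: ordered, disjoint exon intervals."""

    transcript_id: str
    gene_id: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"transcript {self.transcript_id} has no exons")
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise AnnotationError(
                    f"transcript {self.transcript_id} has empty exon [{start}, {end})"
                )
            if prev_end is not None and start < prev_end:
                raise AnnotationError(
                    f"transcript {self.transcript_id} exons overlap or are unsorted"
                )
            prev_end = end

    @property
    def length_bp(self) -> int:
        return sum(end - start for start, end in self.exons)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chromosome: str
    strand: str
    transcripts: tuple[Transcript, ...]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise AnnotationError(f"gene {self.gene_id} has no transcripts")
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"gene {self.gene_id} has invalid strand {self.strand!r}")
        ids = [t.transcript_id for t in self.transcripts]
        if len(set(ids)) != len(ids):
            raise AnnotationError(f"gene {self.gene_id} has duplicate transcript ids")
        for t in self.transcripts:
            if t.gene_id != self.gene_id:
                raise AnnotationError(
                    f"transcript {t.transcript_id} assigned to gene {self.gene_id} "
                    f"but carries gene_id {t.gene_id}"
                )

    @property
    def transcript_ids(self) -> tuple[str, ...]:
        return tuple(t.transcript_id for t in self.transcripts)

    @property
    def is_multi_isoform(self) -> bool:
        return len(self.transcripts) >= 2


@dataclass(frozen=True)
class ExonicSegment:
    """Maximal interval with constant transcript membership."""

    start: int
    end: int
    members: frozenset[str]

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise AnnotationError(f"empty segment [{self.start}, {self.end})")
        if not self.members:
            raise AnnotationError(f"segment [{self.start}, {self.end}) has no members")

    @property
    def length_bp(self) -> int:
        return self.end - self.start


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return tuple(merged)


def build_segments(gene: GeneModel) -> list[ExonicSegment]:
    """Project a gene's transcripts onto maximal constant-membership segments.

    The exon union is cut at every exon boundary of every transcript; atomic
    pieces covered by the same transcript set are re-merged when contiguous.
    Every exonic base of every transcript falls in exactly one segment whose
    members include that transcript.
    """
    boundaries: set[int] = set()
    for t in gene.transcripts:
        for start, end in t.exons:
            boundaries.add(start)
            boundaries.add(end)
    cuts = sorted(boundaries)

    atomic: list[ExonicSegment] = []
    for start, end in zip(cuts, cuts[1:]):
        members = frozenset(
            t.transcript_id
            for t in gene.transcripts
            if any(es <= start and end <= ee for es, ee in t.exons)
        )
        if members:
            atomic.append(ExonicSegment(start, end, members))

    segments: list[ExonicSegment] = []
    for seg in atomic:
        if (
            segments
            and segments[-1].end == seg.start
            and segments[-1].members == seg.members
        ):
            prev = segments[-1]
            segments[-1] = ExonicSegment(prev.start, seg.end, prev.members)
        else:
            segments.append(seg)
    return segments


def segment_id(gene: GeneModel, segment: ExonicSegment) -> str:
    return f"{gene.gene_id}:{segment.start}-{segment.end}"


def parse_gtf(path: str) -> list[GeneModel]:
    """Read exon features from a GTF file into gene models.

    Only ``exon`` features are consulted; they must carry ``gene_id`` and
    ``transcript_id`` attributes.  Exon coordinates are converted from GTF
    1-based inclusive to 0-based half-open.  Overlapping exons within one
    transcript are merged with a warning; a transcript spanning two
    chromosomes or strands is rejected.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    tx_gene: dict[str, str] = {}
    tx_loc: dict[str, tuple[str, str]] = {}
    tx_order: list[str] = []

    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.count("\t") < 8:
                raise GtfParseError(
                    f"{path}:{lineno}: malformed GTF line (expected 9 tab-separated fields)"
                )
            try:
                feature = feature_from_line(line)
            except Exception as exc:
                raise GtfParseError(f"{path}:{lineno}: malformed GTF line ({exc})") from exc
            if feature.featuretype != "exon":
                continue
            attributes = feature.attributes
            if "gene_id" not in attributes or not attributes["gene_id"]:
                raise GtfParseError(f"{path}:{lineno}: exon feature missing gene_id")
            if "transcript_id" not in attributes or not attributes["transcript_id"]:
                raise GtfParseError(f"{path}:{lineno}: exon feature missing transcript_id")
            gene_id = attributes["gene_id"][0]
            transcript_id = attributes["transcript_id"][0]
            if feature.start is None or feature.end is None:
                raise GtfParseError(f"{path}:{lineno}: exon feature missing coordinates")
            start0, end0 = feature.start - 1, feature.end  # GTF -> half-open
            if end0 <= start0:
                raise GtfParseError(f"{path}:{lineno}: empty exon interval")

            if transcript_id not in exons:
                exons[transcript_id] = []
                tx_gene[transcript_id] = gene_id
                tx_loc[transcript_id] = (feature.seqid, feature.strand)
                tx_order.append(transcript_id)
            else:
                if tx_loc[transcript_id] != (feature.seqid, feature.strand):
                    raise AnnotationError(
                        f"transcript {transcript_id} spans multiple chromosomes/strands"
                    )
                if tx_gene[transcript_id] != gene_id:
                    raise AnnotationError(
                        f"transcript {transcript_id} assigned to multiple genes"
                    )
            exons[transcript_id].append((start0, end0))

    genes: dict[str, list[Transcript]] = {}
    gene_loc: dict[str, tuple[str, str]] = {}
    gene_order: list[str] = []
    for transcript_id in tx_order:
        intervals = exons[transcript_id]
        merged = _merge_intervals(intervals)
        if len(merged) < len(intervals):
            warnings.warn(
                f"transcript {transcript_id}: overlapping exons merged", stacklevel=2
            )
        gene_id = tx_gene[transcript_id]
        transcript = Transcript(transcript_id, gene_id, merged)
        if gene_id not in genes:
            genes[gene_id] = []
            gene_loc[gene_id] = tx_loc[transcript_id]
            gene_order.append(gene_id)
        elif gene_loc[gene_id] != tx_loc[transcript_id]:
            raise AnnotationError(
                f"gene {gene_id} has transcripts on multiple chromosomes/strands"
            )
        genes[gene_id].append(transcript)

    return [
        GeneModel(gene_id, gene_loc[gene_id][0], gene_loc[gene_id][1], tuple(genes[gene_id]))
        for gene_id in gene_order
    ]


def write_gtf(genes: Iterable[GeneModel], path: str, source: str = "isletseq") -> None:
    """Write gene models as GTF exon features (1-based inclusive)."""
    with open(path, "w") as handle:
        for gene in genes:
            for t in gene.transcripts:
                for start, end in t.exons:
                    attrs = f'gene_id "{gene.gene_id}"; transcript_id "{t.transcript_id}";'
                    handle.write(
                        f"{gene.chromosome}\t{source}\texon\t{start + 1}\t{end}\t.\t"
                        f"{gene.strand}\t.\t{attrs}\n"
                    )


def write_segments_bed(genes: Iterable[GeneModel], path: str) -> None:
    """Export segments as BED (0-based half-open); members joined by ',' in the name."""
    with open(path, "w") as handle:
        for gene in genes:
            for seg in build_segments(gene):
                name = f"{gene.gene_id}|{','.join(sorted(seg.members))}"
                handle.write(
                    f"{gene.chromosome}\t{seg.start}\t{seg.end}\t{name}\t0\t{gene.strand}\n"
                )


def iter_gene_segments(genes: Iterable[GeneModel]) -> Iterator[tuple[GeneModel, list[ExonicSegment]]]:
    for gene in genes:
        yield gene, build_segments(gene)
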