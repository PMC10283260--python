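"""Intron-spanning read support, intron classification and fusion verdicts.

A genuine intron should be spanned by roughly as many gapped reads as there
is coverage at the borders of its flanking exons; an intergenic spacer that
was mis-annotated as an intron has essentially no spanning reads despite
well-covered flanks.  The ``link_ratio`` quantifies this:

    link_ratio = spanning_reads / min(left_edge_cov, right_edge_cov)

Intron ordinals are 1-based throughout the public API (intron ``i`` lies
between exons ``i`` and ``i+1``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from ._errors import ValidationError
from .coverage import ExonSupport, exon_support_stats
from .io_formats import CoverageTrack, GeneModel, GenomicInterval, SplicedAlignment

SUPPORTED = "SUPPORTED"
WEAK = "WEAK"
UNSUPPORTED = "UNSUPPORTED"
NO_DATA = "NO_DATA"

CONSISTENT = "CONSISTENT"
LIKELY_FUSION = "LIKELY_FUSION"
INSUFFICIENT_DATA = "INSUFFICIENT_DATA"


@dataclass(frozen=True)
class ScreenParams:
    """Quantification of the qualitative screening criteria.

    ``theta_supported``/``theta_unsupported`` bound the link_ratio for the
    SUPPORTED and UNSUPPORTED calls ("almost equivalent" vs "almost no
    connecting reads"); introns whose flanks are below ``min_edge_depth``
    yield NO_DATA rather than a verdict.
    """

    theta_supported: float = 0.5
    theta_unsupported: float = 0.05
    min_edge_depth: int = 10
    junction_slack: int = 0
    edge_window: int = 10
    taper_terminal: float = 0.5

    def __post_init__(self):
        if not (0 <= self.theta_unsupported < self.theta_supported):
            raise ValidationError(
                "need 0 <= theta_unsupported < theta_supported"
            )
        if self.min_edge_depth < 1:
            raise ValidationError("min_edge_depth must be >= 1")
        if self.junction_slack < 0:
            raise ValidationError("junction_slack must be >= 0")


@dataclass(frozen=True)
class IntronSupport:
    """Spanning-read evidence for one annotated intron (1-based ordinal)."""

    intron_index: int
    intron: GenomicInterval
    spanning_reads: int
    left_edge_cov: float
    right_edge_cov: float
    link_ratio: float  # NaN when status is NO_DATA
    status: str


@dataclass(frozen=True)
class FusionReport:
    """Per-gene verdict with the supporting intron and exon evidence."""

    gene_id: str
    verdict: str
    intron_evidence: tuple[IntronSupport, ...]
    exon_evidence: tuple[ExonSupport, ...]
    split_introns: tuple[int, ...]
    notes: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "verdict": self.verdict,
            "split_introns": list(self.split_introns),
            "notes": list(self.notes),
            "introns": [
                {
                    "index": iv.intron_index,
                    "start": iv.intron.start,
                    "end": iv.intron.end,
                    "spanning_reads": iv.spanning_reads,
                    "left_edge_cov": iv.left_edge_cov,
                    "right_edge_cov": iv.right_edge_cov,
                    "link_ratio": None if math.isnan(iv.link_ratio) else iv.link_ratio,
                    "status": iv.status,
                }
                for iv in self.intron_evidence
            ],
            "exons": [
                {
                    "index": ev.exon_index,
                    "mean_cov": ev.mean_cov,
                    "median_cov": ev.median_cov,
                    "left_edge_cov": ev.left_edge_cov,
                    "right_edge_cov": ev.right_edge_cov,
                    "left_taper": ev.left_taper,
                    "right_taper": ev.right_taper,
                    "supported_fraction": ev.supported_fraction,
                    "low_data": ev.low_data,
                }
                for ev in self.exon_evidence
            ],
        }


def spanning_read_count(
    gene: GeneModel,
    intron_index: int,
    alignments: Iterable[SplicedAlignment],
    slack: int = 0,
) -> int:
    """Count alignments whose N-gap matches intron ``intron_index`` (1-based).

    A gap matches when both of its boundaries are within ``slack`` bases of
    the annotated intron boundaries; by construction of the block/gap
    decomposition every gap is anchored by at least one aligned base on each
    side.
    """
    introns = gene.introns
    if not introns:
        raise ValidationError(f"gene {gene.gene_id} has fewer than two exons")
    if not (1 <= intron_index <= len(introns)):
        raise ValidationError(
            f"gene {gene.gene_id}: intron index {intron_index} out of range "
            f"1..{len(introns)}"
        )
    intron = introns[intron_index - 1]
    count = 0
    for aln in alignments:
        if aln.seq_id != gene.seq_id:
            continue
        for gap in aln.gaps:
            if (
                abs(gap.start - intron.start) <= slack
                and abs(gap.end - intron.end) <= slack
            ):
                count += 1
                break
    return count


def classify_introns(
    gene: GeneModel,
    track: CoverageTrack,
    alignments: Sequence[SplicedAlignment],
    params: ScreenParams = ScreenParams(),
) -> list[IntronSupport]:
    """Classify every annotated intron of ``gene`` by spanning-read support.

    Edge coverages are the exon-edge window means facing the intron; if the
    smaller of the two is below ``min_edge_depth`` the intron is NO_DATA.
    """
    introns = gene.introns
    if not introns:
        raise ValidationError(f"gene {gene.gene_id} has fewer than two exons")
    exon_stats = exon_support_stats(track, gene, edge_window=params.edge_window)
    out = []
    for idx, intron in enumerate(introns, start=1):
        left_cov = exon_stats[idx - 1].right_edge_cov
        right_cov = exon_stats[idx].left_edge_cov
        spanning = spanning_read_count(
            gene, idx, alignments, slack=params.junction_slack
        )
        edge_min = min(left_cov, right_cov)
        if edge_min < params.min_edge_depth:
            ratio = float("nan")
            status = NO_DATA
        else:
            ratio = spanning / edge_min
            if ratio >= params.theta_supported:
                status = SUPPORTED
            elif ratio < params.theta_unsupported:
                status = UNSUPPORTED
            else:
                status = WEAK
        out.append(
            IntronSupport(
                intron_index=idx,
                intron=intron,
                spanning_reads=spanning,
                left_edge_cov=left_cov,
                right_edge_cov=right_cov,
                link_ratio=ratio,
                status=status,
            )
        )
    return out


def screen_gene(
    gene: GeneModel,
    track: CoverageTrack,
    alignments: Sequence[SplicedAlignment],
    params: ScreenParams = ScreenParams(),
) -> FusionReport:
    """Issue a fusion verdict for one gene model.

    LIKELY_FUSION iff at least one intron is UNSUPPORTED (those ordinals
    become the proposed split points); INSUFFICIENT_DATA iff every intron is
    NO_DATA; CONSISTENT otherwise.  Single-exon genes are trivially
    CONSISTENT.  Taper evidence at the flanks of each split intron is
    recorded in the notes as corroboration only.
    """
    if gene.seq_id != track.seq_id:
        raise ValidationError(
            f"gene {gene.gene_id} on {gene.seq_id}, track on {track.seq_id}"
        )
    for aln in alignments:
        if aln.seq_id != gene.seq_id:
            raise ValidationError(
                f"alignment {aln.read_id} on {aln.seq_id}, gene on {gene.seq_id}"
            )
    exon_stats = tuple(exon_support_stats(track, gene, edge_window=params.edge_window))
    if len(gene.exons) == 1:
        return FusionReport(
            gene_id=gene.gene_id,
            verdict=CONSISTENT,
            intron_evidence=(),
            exon_evidence=exon_stats,
            split_introns=(),
            notes=("single-exon model: nothing to screen",),
        )
    intron_evidence = tuple(classify_introns(gene, track, alignments, params))
    splits = tuple(
        iv.intron_index for iv in intron_evidence if iv.status == UNSUPPORTED
    )
    notes = []
    for idx in splits:
        up = exon_stats[idx - 1]
        down = exon_stats[idx]
        terminal_like = (
            up.right_taper <= params.taper_terminal
            and down.left_taper <= params.taper_terminal
        )
        notes.append(
            f"intron {idx}: flanking tapers {up.right_taper:.2f}/{down.left_taper:.2f}"
            + (
                " -- terminal-like exon ends corroborate a gene boundary"
                if terminal_like
                else " -- no taper corroboration"
            )
        )
    if splits:
        verdict = LIKELY_FUSION
    elif all(iv.status == NO_DATA for iv in intron_evidence):
        verdict = INSUFFICIENT_DATA
        notes.append("no intron has adequately covered flanks")
    else:
        verdict = CONSISTENT
    return FusionReport(
        gene_id=gene.gene_id,
        verdict=verdict,
        intron_evidence=intron_evidence,
        exon_evidence=exon_stats,
        split_introns=splits,
        notes=tuple(notes),
    )


def propose_splits(gene: GeneModel, report: FusionReport) -> list[GeneModel]:
    """Partition the gene's exons at each split intron of ``report``.

    Returns one model per segment named ``<gene_id>.split1..n`` (genomic
    order); without splits the original model is returned unchanged.
    """
    if report.gene_id != gene.gene_id:
        raise ValidationError(
            f"report is for {report.gene_id}, not {gene.gene_id}"
        )
    if not report.split_introns:
        return [gene]
    cut_after = set(report.split_introns)  # intron i separates exon i and i+1
    segments: list[list] = [[]]
    for i, exon in enumerate(gene.exons, start=1):
        segments[-1].append(exon)
        if i in cut_after and i < len(gene.exons):
            segments.append([])
    return [
        GeneModel(
            gene_id=f"{gene.gene_id}.split{n}",
            seq_id=gene.seq_id,
            strand=gene.strand,
            exons=tuple(seg),
        )
        for n, seg in enumerate(segments, start=1)
    ]
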