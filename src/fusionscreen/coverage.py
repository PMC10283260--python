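"""Alignment filtering, per-locus subsetting, coverage tracks and per-exon
support statistics.

The default filter reproduces the mapping stringency used for the RNA-seq
evidence: minimum identity 0.95 and minimum aligned read fraction 0.90,
both inclusive lower bounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ._errors import ValidationError
from .io_formats import CoverageTrack, GeneModel, GenomicInterval, SplicedAlignment


@dataclass(frozen=True)
class FilterParams:
    """Mapping-stringency thresholds (inclusive lower bounds)."""

    min_identity: float = 0.95
    min_aligned_fraction: float = 0.90

    def __post_init__(self):
        for name in ("min_identity", "min_aligned_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be within [0, 1], got {v}")


@dataclass(frozen=True)
class ExonSupport:
    """Coverage summary for one exon.

    Taper ratios compare the mean coverage of the outermost ``edge_window``
    positions against the exon body mean (exon minus both edge windows; the
    whole exon when shorter than three windows).  A taper well below 1 on the
    outward side of a terminal exon is the signature of a transcript end,
    as opposed to the abrupt drop of a genuine splice site.
    """

    exon_index: int
    mean_cov: float
    median_cov: float
    left_edge_cov: float
    right_edge_cov: float
    left_taper: float
    right_taper: float
    supported_fraction: float
    low_data: bool = False


def filter_alignments(
    alignments: Iterable[SplicedAlignment], params: FilterParams = FilterParams()
) -> list[SplicedAlignment]:
    """Keep alignments passing both stringency thresholds; order preserved."""
    kept = []
    for aln in alignments:
        if aln.read_length == 0:
            raise ValidationError(f"alignment {aln.read_id}: read_length is zero")
        if (
            aln.identity >= params.min_identity
            and aln.aligned_length / aln.read_length >= params.min_aligned_fraction
        ):
            kept.append(aln)
    return kept


def subset_alignments(
    alignments: Iterable[SplicedAlignment], interval: GenomicInterval
) -> list[SplicedAlignment]:
    """Keep alignments whose blocks overlap ``interval`` by at least one base.

    This is the in-memory analog of extracting the per-locus reads from each
    sample's alignment file and merging them.
    """
    return [
        aln
        for aln in alignments
        if aln.seq_id == interval.seq_id
        and any(block.overlaps(interval) for block in aln.blocks)
    ]


def compute_coverage(
    alignments: Iterable[SplicedAlignment], seq_id: str, seq_len: int
) -> CoverageTrack:
    """Count, per reference position, the alignments with a block covering it.

    N-gaps contribute nothing; each alignment counts at most once per
    position (blocks of one alignment never overlap).
    """
    if seq_len < 0:
        raise ValidationError("seq_len must be non-negative")
    delta = np.zeros(seq_len + 1, dtype=np.int64)
    for aln in alignments:
        if aln.seq_id != seq_id:
            raise ValidationError(
                f"alignment {aln.read_id} on {aln.seq_id}, expected {seq_id}"
            )
        for block in aln.blocks:
            if block.end > seq_len:
                raise ValidationError(
                    f"alignment {aln.read_id}: block ends at {block.end}, "
                    f"beyond sequence length {seq_len}"
                )
            delta[block.start] += 1
            delta[block.end] -= 1
    return CoverageTrack(seq_id=seq_id, counts=np.cumsum(delta[:-1]))


def exon_support_stats(
    track: CoverageTrack, gene: GeneModel, edge_window: int = 10
) -> list[ExonSupport]:
    """Per-exon coverage statistics against a precomputed track.

    ``left``/``right`` refer to genomic orientation.  When the exon body has
    zero mean coverage the taper ratios are reported as 0.0 with
    ``low_data=True`` instead of raising, so screening never crashes on
    unexpressed exons.
    """
    if edge_window < 1:
        raise ValidationError("edge_window must be >= 1")
    if gene.seq_id != track.seq_id:
        raise ValidationError(
            f"gene {gene.gene_id} on {gene.seq_id}, track on {track.seq_id}"
        )
    out = []
    for idx, exon in enumerate(gene.exons, start=1):
        if exon.end > track.length:
            raise ValidationError(
                f"gene {gene.gene_id}: exon {idx} extends beyond the track"
            )
        window = min(edge_window, exon.length)
        counts = track.counts[exon.start : exon.end]
        left_edge = float(counts[:window].mean())
        right_edge = float(counts[-window:].mean())
        if exon.length >= 3 * edge_window:
            body = counts[edge_window:-edge_window]
        else:
            body = counts
        body_cov = float(body.mean())
        low_data = body_cov == 0.0
        out.append(
            ExonSupport(
                exon_index=idx,
                mean_cov=float(counts.mean()),
                median_cov=float(np.median(counts)),
                left_edge_cov=left_edge,
                right_edge_cov=right_edge,
                left_taper=left_edge / body_cov if body_cov > 0 else 0.0,
                right_taper=right_edge / body_cov if body_cov > 0 else 0.0,
                supported_fraction=float((counts >= 1).mean()),
                low_data=low_data,
            )
        )
    return out
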