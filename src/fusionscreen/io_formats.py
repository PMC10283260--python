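"""Readers/writers for FASTA, GFF3, SAM and coverage tracks, plus the shared
genomic data model.

Coordinate convention
---------------------
All coordinates inside the package are 0-based, half-open, on the forward
strand.  GFF3 (1-based, inclusive) and SAM (1-based POS) are converted at the
file boundary and nowhere else.  Coverage files use 1-based positions, one
dense row per reference position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam
from Bio import SeqIO

from ._errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

NUCLEOTIDE_SYMBOLS = frozenset("ACGTN")

# CIGAR op codes as encoded by pysam / the SAM spec.
_CIG_M, _CIG_I, _CIG_D, _CIG_N, _CIG_S, _CIG_H, _CIG_P, _CIG_EQ, _CIG_X = range(9)
_REF_BLOCK_OPS = {_CIG_M, _CIG_D, _CIG_EQ, _CIG_X}
_QUERY_OPS = {_CIG_M, _CIG_I, _CIG_S, _CIG_H, _CIG_EQ, _CIG_X}
_ALLOWED_OPS = {_CIG_M, _CIG_I, _CIG_D, _CIG_N, _CIG_S, _CIG_H, _CIG_EQ, _CIG_X}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide or protein sequence.

    Residues are stored upper-case.  ``alphabet`` is ``"nucleotide"`` or
    ``"protein"``; when omitted it is inferred from the residue content.
    """

    id: str
    residues: str
    alphabet: str = "auto"

    def __post_init__(self):
        if not self.residues:
            raise ValidationError(f"sequence record {self.id!r} has no residues")
        object.__setattr__(self, "residues", self.residues.upper())
        if self.alphabet == "auto":
            inferred = (
                "nucleotide"
                if set(self.residues) <= NUCLEOTIDE_SYMBOLS
                else "protein"
            )
            object.__setattr__(self, "alphabet", inferred)
        elif self.alphabet not in ("nucleotide", "protein"):
            raise ValidationError(f"unknown alphabet {self.alphabet!r}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named sequence (0-based)."""

    seq_id: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.seq_id}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene: ordered, non-overlapping exons on one sequence."""

    gene_id: str
    seq_id: str
    strand: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")
        exons = tuple(self.exons)
        if not exons:
            raise ValidationError(f"gene {self.gene_id}: at least one exon required")
        for e in exons:
            if e.seq_id != self.seq_id:
                raise ValidationError(
                    f"gene {self.gene_id}: exon on {e.seq_id}, gene on {self.seq_id}"
                )
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"gene {self.gene_id}: exons must be sorted and non-overlapping"
                )
        object.__setattr__(self, "exons", exons)

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        """Gaps between consecutive exons, in genomic order."""
        return tuple(
            GenomicInterval(self.seq_id, a.end, b.start)
            for a, b in zip(self.exons, self.exons[1:])
        )

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.seq_id, self.exons[0].start, self.exons[-1].end)

    @property
    def exonic_length(self) -> int:
        return sum(e.length for e in self.exons)


@dataclass(frozen=True)
class SplicedAlignment:
    """One read alignment decomposed into blocks separated by junction gaps.

    ``blocks`` are the reference intervals physically spanned by the read
    (deletions included); ``gaps`` are the N-gap junctions between
    consecutive blocks.  ``identity`` comes from the NM tag when present
    (1 - NM/aligned_length), else defaults to 1.0.
    """

    read_id: str
    seq_id: str
    blocks: tuple[GenomicInterval, ...]
    gaps: tuple[GenomicInterval, ...]
    aligned_length: int
    identity: float
    read_length: int

    def __post_init__(self):
        blocks = tuple(self.blocks)
        gaps = tuple(self.gaps)
        if not blocks:
            raise ValidationError(f"alignment {self.read_id}: no aligned blocks")
        if len(gaps) != len(blocks) - 1:
            raise ValidationError(
                f"alignment {self.read_id}: need exactly one gap between "
                f"consecutive blocks"
            )
        for i, (a, b) in enumerate(zip(blocks, blocks[1:])):
            g = gaps[i]
            if not (a.end == g.start and g.end == b.start):
                raise ValidationError(
                    f"alignment {self.read_id}: gap {i} does not fill the space "
                    f"between blocks {i} and {i + 1}"
                )
        if self.aligned_length > self.read_length:
            raise ValidationError(
                f"alignment {self.read_id}: aligned_length > read_length"
            )
        if not (0.0 <= self.identity <= 1.0):
            raise ValidationError(f"alignment {self.read_id}: identity outside [0,1]")
        object.__setattr__(self, "blocks", blocks)
        object.__setattr__(self, "gaps", gaps)

    @property
    def reference_span(self) -> GenomicInterval:
        return GenomicInterval(self.seq_id, self.blocks[0].start, self.blocks[-1].end)


@dataclass
class CoverageTrack:
    """Per-position aligned-read counts for one reference sequence."""

    seq_id: str
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise ValidationError("coverage counts must be one-dimensional")
        if len(self.counts) and self.counts.min() < 0:
            raise ValidationError("coverage counts must be non-negative")

    @property
    def length(self) -> int:
        return int(len(self.counts))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[SequenceRecord]:
    """Read a (multi-line) FASTA file into :class:`SequenceRecord` objects.

    Residues are concatenated and upper-cased; record order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"no such file: {path}")
    with open(path) as fh:
        head = fh.read(1)
        if head and head not in (">", ";", "\n"):
            raise FormatError(f"{path}: sequence data before first FASTA header")
    records = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            records.append(SequenceRecord(id=rec.id, residues=str(rec.seq)))
    except ValueError as exc:  # biopython parse failure
        raise FormatError(f"{path}: {exc}") from exc
    return records


def write_fasta(records: Iterable[SequenceRecord], path, line_width: int = 60) -> None:
    """Write records as FASTA with sequence lines wrapped at ``line_width``."""
    if line_width < 1:
        raise ValidationError("line_width must be >= 1")
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), line_width):
                fh.write(rec.residues[i : i + line_width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _parse_gff_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for item in text.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def read_gff3(path) -> list[GeneModel]:
    """Read gene models from GFF3 (gene/mRNA/exon, CDS fallback).

    GFF3 1-based inclusive coordinates are converted to internal 0-based
    half-open.  When a gene carries several mRNAs, the mRNA with the largest
    summed exon length wins (a warning is logged).
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"no such file: {path}")

    genes: dict[str, tuple[str, str]] = {}  # gene_id -> (seq_id, strand)
    gene_order: list[str] = []
    mrna_parent: dict[str, str] = {}
    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[GenomicInterval]] = {}
    child_lines: dict[str, int] = {}

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-separated columns")
            seq_id, _source, ftype, start_s, end_s, _score, strand, _phase, attr_s = cols[:9]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if end < start:
                raise FormatError(f"{path}:{lineno}: end < start")
            attrs = _parse_gff_attributes(attr_s)
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise FormatError(f"{path}:{lineno}: gene feature without ID")
                if strand == ".":
                    logger.warning("%s:%d: gene %s without strand, assuming +", path, lineno, gid)
                    strand = "+"
                genes[gid] = (seq_id, strand)
                gene_order.append(gid)
            elif ftype in ("mRNA", "transcript"):
                mid = attrs.get("ID")
                parent = attrs.get("Parent")
                if mid is None or parent is None:
                    raise FormatError(f"{path}:{lineno}: mRNA feature without ID/Parent")
                mrna_parent[mid] = parent.split(",")[0]
            elif ftype in ("exon", "CDS"):
                parent_s = attrs.get("Parent")
                if parent_s is None:
                    raise FormatError(f"{path}:{lineno}: {ftype} feature without Parent")
                interval = GenomicInterval(seq_id, start - 1, end)
                store = exons if ftype == "exon" else cds
                for parent in parent_s.split(","):
                    store.setdefault(parent, []).append(interval)
                    child_lines.setdefault(parent, lineno)

    # every exon/CDS parent must resolve to a known mRNA or gene
    for parent, lineno in child_lines.items():
        if parent not in mrna_parent and parent not in genes:
            raise FormatError(
                f"{path}:{lineno}: exon/CDS parent {parent!r} does not resolve "
                f"to any gene or mRNA"
            )

    models = []
    for gid in gene_order:
        seq_id, strand = genes[gid]
        candidates = []  # (total exon length, label, intervals)
        for mid, parent in mrna_parent.items():
            if parent != gid:
                continue
            ivs = exons.get(mid) or cds.get(mid)
            if ivs:
                candidates.append((sum(iv.length for iv in ivs), mid, ivs))
        direct = exons.get(gid) or cds.get(gid)
        if direct:
            candidates.append((sum(iv.length for iv in direct), gid, direct))
        if not candidates:
            logger.warning("gene %s has no exon/CDS children; skipped", gid)
            continue
        if len(candidates) > 1:
            logger.warning(
                "gene %s has %d transcripts; keeping the longest one", gid, len(candidates)
            )
        _, _, ivs = max(candidates, key=lambda c: (c[0], c[1]))
        models.append(
            GeneModel(
                gene_id=gid,
                seq_id=seq_id,
                strand=strand,
                exons=tuple(sorted(ivs, key=lambda iv: iv.start)),
            )
        )
    return models


def write_gff3(models: Iterable[GeneModel], path) -> None:
    """Write gene models as GFF3 gene/mRNA/exon rows (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in models:
            span = gene.span
            fields = [
                gene.seq_id,
                "fusionscreen",
                "gene",
                str(span.start + 1),
                str(span.end),
                ".",
                gene.strand,
                ".",
                f"ID={gene.gene_id}",
            ]
            fh.write("\t".join(fields) + "\n")
            mid = f"{gene.gene_id}.t1"
            fields[2] = "mRNA"
            fields[8] = f"ID={mid};Parent={gene.gene_id}"
            fh.write("\t".join(fields) + "\n")
            for i, exon in enumerate(gene.exons, start=1):
                fh.write(
                    "\t".join(
                        [
                            gene.seq_id,
                            "fusionscreen",
                            "exon",
                            str(exon.start + 1),
                            str(exon.end),
                            ".",
                            gene.strand,
                            ".",
                            f"ID={mid}.exon{i};Parent={mid}",
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def _decompose_cigar(read_id: str, reference_start: int, cigartuples):
    """Split a CIGAR into reference blocks (M/=/X/D merged) and N-gaps.

    Returns (blocks, gaps, aligned_length, read_length) where blocks/gaps are
    lists of (start, end) tuples.  Deletions stay inside blocks: a deleted
    base is still physically spanned by the read.
    """
    blocks: list[list[int]] = []
    gaps: list[tuple[int, int]] = []
    pos = reference_start
    aligned = 0
    read_len = 0
    pending_gap_start = None
    for op, length in cigartuples:
        if op not in _ALLOWED_OPS:
            raise FormatError(f"read {read_id}: unsupported CIGAR op code {op}")
        if length <= 0:
            raise FormatError(f"read {read_id}: non-positive CIGAR op length")
        if op in _QUERY_OPS:
            read_len += length
        if op in (_CIG_M, _CIG_EQ, _CIG_X):
            aligned += length
        if op in _REF_BLOCK_OPS:
            if blocks and pending_gap_start is None and blocks[-1][1] == pos:
                blocks[-1][1] = pos + length
            else:
                if pending_gap_start is not None and blocks:
                    gaps.append((pending_gap_start, pos))
                pending_gap_start = None
                blocks.append([pos, pos + length])
            pos += length
        elif op == _CIG_N:
            if blocks:
                if pending_gap_start is None:
                    pending_gap_start = pos
            pos += length
        # I, S, H consume no reference
    return [tuple(b) for b in blocks], gaps, aligned, read_len


def read_sam(path) -> list[SplicedAlignment]:
    """Read mapped records from a SAM file into spliced alignments.

    Unmapped and CIGAR-less records are skipped.  Identity is
    1 - NM/aligned_length when the NM tag is present, else 1.0 (logged once).
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"no such file: {path}")
    out: list[SplicedAlignment] = []
    missing_nm = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        it = iter(fh)
        while True:
            try:
                aln = next(it)
            except StopIteration:
                break
            except (ValueError, OSError) as exc:
                # pysam reports record-level parse failures as OSError
                raise FormatError(f"{path}: malformed SAM record: {exc}") from exc
            if aln.is_unmapped or aln.cigartuples is None:
                continue
            blocks, gaps, aligned, read_len = _decompose_cigar(
                aln.query_name, aln.reference_start, aln.cigartuples
            )
            if not blocks:
                continue
            if aln.has_tag("NM"):
                nm = int(aln.get_tag("NM"))
                identity = max(0.0, 1.0 - nm / aligned) if aligned else 1.0
            else:
                missing_nm += 1
                identity = 1.0
            seq_id = aln.reference_name
            out.append(
                SplicedAlignment(
                    read_id=aln.query_name,
                    seq_id=seq_id,
                    blocks=tuple(GenomicInterval(seq_id, s, e) for s, e in blocks),
                    gaps=tuple(GenomicInterval(seq_id, s, e) for s, e in gaps),
                    aligned_length=aligned,
                    identity=identity,
                    read_length=read_len,
                )
            )
    if missing_nm:
        logger.info(
            "%s: %d records without NM tag; identity assumed 1.0", path, missing_nm
        )
    return out


def sam_reference_lengths(path) -> dict[str, int]:
    """Return the @SQ reference name -> length mapping of a SAM file."""
    path = Path(path)
    if not path.exists():
        raise OSError(f"no such file: {path}")
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        return dict(zip(fh.references, fh.lengths))


def write_sam(
    alignments: Iterable[SplicedAlignment],
    seq_lengths: Mapping[str, int],
    path,
) -> None:
    """Write alignments as SAM; blocks become M ops, gaps become N ops.

    Query bases beyond the blocks (read_length > block span) are encoded as a
    trailing soft clip so filtering semantics survive a round-trip.  The NM
    tag is emitted so identity round-trips as well.
    """
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [{"SN": sid, "LN": int(ln)} for sid, ln in seq_lengths.items()],
        }
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln in alignments:
            if aln.seq_id not in seq_lengths:
                raise ValidationError(
                    f"alignment {aln.read_id}: unknown sequence {aln.seq_id!r}"
                )
            cig: list[tuple[int, int]] = []
            for i, block in enumerate(aln.blocks):
                cig.append((_CIG_M, block.length))
                if i < len(aln.gaps):
                    cig.append((_CIG_N, aln.gaps[i].length))
            block_span = sum(b.length for b in aln.blocks)
            if aln.read_length > block_span:
                cig.append((_CIG_S, aln.read_length - block_span))
            rec = pysam.AlignedSegment(header)
            rec.query_name = aln.read_id
            rec.flag = 0
            rec.reference_name = aln.seq_id
            rec.reference_start = aln.blocks[0].start
            rec.mapping_quality = 255
            rec.cigartuples = cig
            rec.query_sequence = None
            rec.set_tag("NM", round((1.0 - aln.identity) * block_span), "i")
            out.write(rec)


# ---------------------------------------------------------------------------
# coverage files
# ---------------------------------------------------------------------------

def write_coverage(track: CoverageTrack, path) -> None:
    """Write a dense two-column coverage file: 1-based position, count."""
    with open(path, "w") as fh:
        for pos, count in enumerate(track.counts, start=1):
            fh.write(f"{pos}\t{int(count)}\n")


def read_coverage(path, seq_id: str | None = None) -> CoverageTrack:
    """Read a two-column coverage file back into a track.

    The coverage format carries no sequence name; ``seq_id`` defaults to the
    file stem.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"no such file: {path}")
    counts = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected two tab-separated columns")
            try:
                pos, count = int(parts[0]), int(parts[1])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer value") from None
            if pos != len(counts) + 1:
                raise FormatError(f"{path}:{lineno}: positions must be dense and 1-based")
            counts.append(count)
    return CoverageTrack(
        seq_id=seq_id if seq_id is not None else path.stem,
        counts=np.asarray(counts, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# region extraction
# ---------------------------------------------------------------------------

def extract_region(genome: SequenceRecord, interval: GenomicInterval) -> SequenceRecord:
    """Extract ``[start, end)`` as a new record labelled with 1-based bounds."""
    if interval.seq_id != genome.id:
        raise ValidationError(
            f"interval on {interval.seq_id!r} but genome is {genome.id!r}"
        )
    if interval.end > len(genome):
        raise ValidationError(
            f"interval {interval.start}-{interval.end} beyond sequence "
            f"length {len(genome)}"
        )
    return SequenceRecord(
        id=f"{genome.id}:{interval.start + 1}-{interval.end}",
        residues=genome.residues[interval.start : interval.end],
        alphabet=genome.alphabet,
    )
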