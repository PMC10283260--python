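"""Protein-level domain-multiplication screen.

Pipeline: a strict length filter (multi-domain fusions are conspicuously
long), iterative Smith-Waterman counting of domain copies against a
single-domain reference (each accepted hit is masked before realigning), and
a catalytic-triad (C/H/N) conservation check via global alignment.

Alignments use BLOSUM62 with affine gaps (-11 open / -1 extend, the usual
protein-BLAST defaults), backed by Bio.Align.PairwiseAligner.  Gap cost for a
gap of length L is ``gap_open + (L - 1) * gap_extend``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from ._errors import ValidationError
from .io_formats import SequenceRecord

#: Sentinel residue used to mask already-counted hits.  It scores so low
#: against everything (including itself) that no optimal local alignment can
#: cross a masked region.
MASK_SYMBOL = "!"
_MASK_SCORE = -10_000.0

_TIE_BREAK_LIMIT = 64  # co-optimal alignments examined for the tie-break


def _blosum62_with_mask():
    base = substitution_matrices.load("BLOSUM62")
    alphabet = str(base.alphabet) + MASK_SYMBOL
    arr = substitution_matrices.Array(alphabet=alphabet, dims=2)
    for x in base.alphabet:
        for y in base.alphabet:
            arr[x, y] = base[x, y]
    for x in alphabet:
        arr[x, MASK_SYMBOL] = _MASK_SCORE
        arr[MASK_SYMBOL, x] = _MASK_SCORE
    return arr


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties."""

    substitution: object  # Bio.Align.substitution_matrices.Array
    gap_open: int = -11
    gap_extend: int = -1

    def __post_init__(self):
        if not (self.gap_open <= self.gap_extend < 0):
            raise ValidationError("need gap_open <= gap_extend < 0")

    @classmethod
    def blosum62(cls, gap_open: int = -11, gap_extend: int = -1) -> "ScoringScheme":
        return cls(
            substitution=_blosum62_with_mask(),
            gap_open=gap_open,
            gap_extend=gap_extend,
        )

    @property
    def alphabet(self) -> str:
        return str(self.substitution.alphabet)

    def self_score(self, record: SequenceRecord) -> float:
        """Score of aligning a sequence to itself without gaps."""
        self._check_symbols(record)
        return float(sum(self.substitution[c, c] for c in record.residues))

    def _check_symbols(self, record: SequenceRecord, allow_mask: bool = False):
        allowed = set(self.alphabet)
        if not allow_mask:
            allowed.discard(MASK_SYMBOL)
        bad = set(record.residues) - allowed
        if bad:
            raise ValidationError(
                f"{record.id}: symbols {sorted(bad)} absent from the "
                f"substitution matrix"
            )


def _make_aligner(scheme: ScoringScheme, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = scheme.substitution
    aligner.open_gap_score = scheme.gap_open
    aligner.extend_gap_score = scheme.gap_extend
    return aligner


@dataclass(frozen=True)
class LocalHit:
    """Best local alignment: half-open intervals on subject and query."""

    subject_start: int
    subject_end: int
    query_start: int
    query_end: int
    score: float

    @property
    def empty(self) -> bool:
        return self.subject_end == self.subject_start


def local_align(
    query: SequenceRecord,
    subject: SequenceRecord,
    scheme: ScoringScheme | None = None,
    _allow_mask: bool = False,
) -> LocalHit:
    """Optimal affine-gap local alignment of ``query`` against ``subject``.

    Ties between co-optimal alignments are broken deterministically by the
    smallest subject start, then the smallest query start.  A best score of
    zero (nothing aligns profitably) yields an empty hit.
    """
    if scheme is None:
        scheme = ScoringScheme.blosum62()
    scheme._check_symbols(query)
    scheme._check_symbols(subject, allow_mask=_allow_mask)
    aligner = _make_aligner(scheme, "local")
    score = float(aligner.score(subject.residues, query.residues))
    if score <= 0:
        return LocalHit(0, 0, 0, 0, 0.0)
    alignments = aligner.align(subject.residues, query.residues)
    best = min(
        itertools.islice(alignments, _TIE_BREAK_LIMIT),
        key=lambda a: (int(a.aligned[0][0][0]), int(a.aligned[1][0][0])),
    )
    sub_blocks, qry_blocks = best.aligned
    return LocalHit(
        subject_start=int(sub_blocks[0][0]),
        subject_end=int(sub_blocks[-1][1]),
        query_start=int(qry_blocks[0][0]),
        query_end=int(qry_blocks[-1][1]),
        score=score,
    )


@dataclass(frozen=True)
class RepeatScan:
    """Result of the iterative domain-copy count for one protein."""

    protein_id: str
    copy_count: int
    hits: tuple[tuple[int, int, float], ...]  # (subject_start, subject_end, score)
    min_score_fraction: float


def screen_by_length(
    proteins: Sequence[SequenceRecord], min_len: int = 500
) -> list[SequenceRecord]:
    """Keep proteins strictly longer than ``min_len`` residues."""
    return [p for p in proteins if len(p) > min_len]


def count_domain_copies(
    domain_ref: SequenceRecord,
    protein: SequenceRecord,
    scheme: ScoringScheme | None = None,
    min_score_fraction: float = 0.3,
) -> RepeatScan:
    """Count copies of ``domain_ref`` in ``protein`` by align-and-mask.

    Repeatedly finds the best local hit of the reference domain; a hit is
    accepted while its score is at least ``min_score_fraction`` of the
    reference self-score, then its subject interval is masked and the search
    repeats.  Accepted hits therefore never overlap and the loop terminates
    because each round removes at least one alignable residue.
    """
    if scheme is None:
        scheme = ScoringScheme.blosum62()
    if not (0 < min_score_fraction <= 1):
        raise ValidationError("min_score_fraction must be in (0, 1]")
    threshold = min_score_fraction * scheme.self_score(domain_ref)
    residues = list(protein.residues)
    hits: list[tuple[int, int, float]] = []
    while True:
        subject = SequenceRecord(
            id=protein.id, residues="".join(residues), alphabet="protein"
        )
        hit = local_align(domain_ref, subject, scheme, _allow_mask=True)
        if hit.empty or hit.score < threshold:
            break
        hits.append((hit.subject_start, hit.subject_end, hit.score))
        for i in range(hit.subject_start, hit.subject_end):
            residues[i] = MASK_SYMBOL
    hits.sort()
    return RepeatScan(
        protein_id=protein.id,
        copy_count=len(hits),
        hits=tuple(hits),
        min_score_fraction=min_score_fraction,
    )


@dataclass(frozen=True)
class TriadResult:
    """Mapping of the reference catalytic triad onto a subject protein."""

    positions_in_subject: tuple[int, int, int] | None
    residues: tuple[str, str, str]
    conserved: bool


def check_triad(
    reference: SequenceRecord,
    ref_triad_positions: Sequence[int],
    subject: SequenceRecord,
    scheme: ScoringScheme | None = None,
) -> TriadResult:
    """Check conservation of the Cys/His/Asn catalytic triad in ``subject``.

    The reference (which must carry C, H, N at the given 0-based positions)
    is globally aligned to the subject; the triad columns are mapped across
    the alignment.  ``conserved`` is true iff all three columns map to
    subject residues (no gaps) that are exactly C, H and N.
    """
    if scheme is None:
        scheme = ScoringScheme.blosum62()
    positions = tuple(int(p) for p in ref_triad_positions)
    if len(positions) != 3:
        raise ValidationError("exactly three triad positions required")
    for p in positions:
        if not (0 <= p < len(reference)):
            raise ValidationError(f"triad position {p} outside the reference")
    ref_residues = tuple(reference.residues[p] for p in positions)
    if ref_residues != ("C", "H", "N"):
        raise ValidationError(
            f"reference triad residues are {ref_residues}, expected ('C', 'H', 'N')"
        )
    scheme._check_symbols(reference)
    scheme._check_symbols(subject)
    aligner = _make_aligner(scheme, "global")
    alignment = aligner.align(reference.residues, subject.residues)[0]
    ref_blocks, sub_blocks = alignment.aligned

    mapped: list[int | None] = []
    for p in positions:
        hit = None
        for (rs, re_), (ss, _se) in zip(ref_blocks, sub_blocks):
            if rs <= p < re_:
                hit = int(ss + (p - rs))
                break
        mapped.append(hit)
    residues = tuple(
        subject.residues[m] if m is not None else "-" for m in mapped
    )
    all_mapped = all(m is not None for m in mapped)
    conserved = all_mapped and residues == ("C", "H", "N")
    return TriadResult(
        positions_in_subject=tuple(mapped) if all_mapped else None,
        residues=residues,  # type: ignore[arg-type]
        conserved=conserved,
    )
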