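"""Exact k-mer match extraction between two sequences for dotplot-style
repeat visualization.

One sequence is hash-indexed, the other streamed; the contract is the exact
match set.  Matching is case-insensitive and any k-mer containing ``N`` never
matches (including against another ``N``), which keeps masked regions from
producing spurious diagonals.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from ._errors import FormatError, ValidationError
from .io_formats import SequenceRecord

FORWARD = "forward"
REVCOMP = "revcomp"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class KmerMatch:
    """A shared k-mer at ``pos_a`` in sequence A and ``pos_b`` in B (0-based)."""

    pos_a: int
    pos_b: int
    orientation: str = FORWARD


def kmer_matches(
    a: SequenceRecord,
    b: SequenceRecord,
    k: int = 31,
    include_revcomp: bool = False,
) -> list[KmerMatch]:
    """All positions (i, j) with ``a[i:i+k] == b[j:j+k]`` (and, optionally,
    reverse-complement matches), in ascending (pos_a, pos_b) order.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    sa, sb = a.residues.upper(), b.residues.upper()
    if k > min(len(sa), len(sb)):
        raise ValidationError(
            f"k={k} exceeds the shorter sequence length {min(len(sa), len(sb))}"
        )
    if include_revcomp and not (
        a.alphabet == "nucleotide" and b.alphabet == "nucleotide"
    ):
        raise ValidationError("reverse-complement matching requires nucleotide input")

    index: dict[str, list[int]] = {}
    for i in range(len(sa) - k + 1):
        kmer = sa[i : i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)

    matches: list[KmerMatch] = []
    for j in range(len(sb) - k + 1):
        kmer = sb[j : j + k]
        if "N" in kmer:
            continue
        for i in index.get(kmer, ()):
            matches.append(KmerMatch(i, j, FORWARD))
        if include_revcomp:
            for i in index.get(reverse_complement(kmer), ()):
                matches.append(KmerMatch(i, j, REVCOMP))
    matches.sort()
    return matches


def dotplot_table(matches: Iterable[KmerMatch], path) -> None:
    """Write matches as a TSV with 1-based positions (header always present)."""
    with open(path, "w") as fh:
        fh.write("pos_a\tpos_b\torientation\n")
        for m in matches:
            fh.write(f"{m.pos_a + 1}\t{m.pos_b + 1}\t{m.orientation}\n")


def read_dotplot_table(path) -> list[KmerMatch]:
    """Read a match TSV written by :func:`dotplot_table`."""
    path = Path(path)
    if not path.exists():
        raise OSError(f"no such file: {path}")
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != "pos_a\tpos_b\torientation":
            raise FormatError(f"{path}: unexpected header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3 or parts[2] not in (FORWARD, REVCOMP):
                raise FormatError(f"{path}:{lineno}: malformed match row")
            try:
                out.append(KmerMatch(int(parts[0]) - 1, int(parts[1]) - 1, parts[2]))
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer position") from None
    return out
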