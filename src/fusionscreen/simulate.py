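"""Seeded simulator of a tandem gene array with truth-known annotations.

The locus carries ``n_copies`` paralogous genes (mutated copies of one
ancestral gene) separated by random spacers, plus an unrelated multi-exon
control gene.  Two annotations are emitted: the correct one (separate gene
models) and a fused decoy spanning all tandem exons as a single gene —
the artifact class this package screens for.

Reads are emitted directly as spliced alignments (post-aligner evidence),
single-end, drawn from each gene's mature transcript.  Transcripts include
untranslated flanks (``utr_len`` on each side) so that coverage at the
annotated coding exon edges reflects the full expression depth while the
terminal taper falls outside the annotation, and reads never join two genes.
Start positions are stratified (one uniform draw per equal-width stratum of
the transcript), which makes realized coverage concentrate tightly around
the target depth.  All randomness descends from ``SimConfig.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._errors import ValidationError
from .io_formats import GeneModel, GenomicInterval, SequenceRecord, SplicedAlignment

_BASES = np.array(list("ACGT"))
_AA20 = "ACDEFGHIKLMNPQRSTVWY"

# one unambiguous codon per amino acid, for back-translation
_CODON = {
    "A": "GCT", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTC",
    "G": "GGT", "H": "CAC", "I": "ATC", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCA", "Q": "CAG", "R": "CGT",
    "S": "TCT", "T": "ACC", "V": "GTT", "W": "TGG", "Y": "TAC",
}

_CODON_TABLE = {}  # codon -> aa, built lazily from Bio


def _translate(dna: str) -> str:
    """Translate in frame 0, truncating a trailing partial codon; stops -> X."""
    from Bio.Seq import Seq

    n = len(dna) - len(dna) % 3
    return str(Seq(dna[:n]).translate()).replace("*", "X")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated tandem locus and read set."""

    n_copies: int = 3
    exons_per_gene: int = 2
    exon_len: int = 200
    intron_len: int = 150
    spacer_len: int = 500
    copy_divergence: float = 0.05
    depths: tuple[int, ...] = (50, 10, 80)
    read_len: int = 100
    error_rate: float = 0.0
    seed: int = 0
    utr_len: int = 300
    control_exons: int = 3
    control_depth: int = 50

    def __post_init__(self):
        if self.n_copies < 1 or self.exons_per_gene < 1:
            raise ValidationError("n_copies and exons_per_gene must be >= 1")
        for name in ("exon_len", "intron_len", "spacer_len", "read_len"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if not (0.0 <= self.copy_divergence <= 0.3):
            raise ValidationError("copy_divergence must be within [0, 0.3]")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValidationError("error_rate must be within [0, 1)")
        object.__setattr__(self, "depths", tuple(self.depths))
        if len(self.depths) != self.n_copies:
            raise ValidationError("depths must have one entry per gene copy")
        if self.read_len > self.exons_per_gene * self.exon_len:
            raise ValidationError("read_len exceeds the tandem-gene mRNA length")
        if self.utr_len < 0 or self.utr_len > self.spacer_len:
            raise ValidationError("utr_len must be within [0, spacer_len]")

    @property
    def gene_len(self) -> int:
        return (
            self.exons_per_gene * self.exon_len
            + (self.exons_per_gene - 1) * self.intron_len
        )

    @property
    def control_len(self) -> int:
        return self.control_exons * self.exon_len + (self.control_exons - 1) * self.intron_len

    @property
    def genome_len(self) -> int:
        """spacer + (gene + spacer) * n_copies + control + spacer"""
        return (
            (self.n_copies + 2) * self.spacer_len
            + self.n_copies * self.gene_len
            + self.control_len
        )


@dataclass
class SimTruth:
    """Ground truth emitted by the simulator."""

    genome: SequenceRecord
    true_models: list[GeneModel]
    fused_model: GeneModel
    control_model: GeneModel
    junction_read_tally: dict[tuple[str, int], int]
    proteins: list[SequenceRecord]
    domain_ref: SequenceRecord
    triad_positions: tuple[int, int, int]
    config: SimConfig


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_AA20), size=n))


def _back_translate(protein: str) -> str:
    return "".join(_CODON[a] for a in protein)


def _build_gene_dna(
    rng: np.random.Generator, exons: int, exon_len: int, intron_len: int
) -> tuple[str, str]:
    """Random translatable gene: back-translated random protein split into
    exons, canonical GT..AG introns.  Returns (gene_dna, protein)."""
    coding_len = exons * exon_len
    n_codons = coding_len // 3
    protein = _random_protein(rng, n_codons)
    coding = _back_translate(protein) + _random_dna(rng, coding_len - 3 * n_codons)
    parts = []
    for i in range(exons):
        parts.append(coding[i * exon_len : (i + 1) * exon_len])
        if i < exons - 1:
            intron = "GT" + _random_dna(rng, max(0, intron_len - 4)) + "AG"
            parts.append(intron[:intron_len].ljust(intron_len, "A"))
    return "".join(parts), protein


def _mutate(
    rng: np.random.Generator, dna: str, rate: float, protected: frozenset[int]
) -> str:
    if rate <= 0:
        return dna
    chars = list(dna)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        if int(i) in protected:
            continue
        current = chars[i]
        alternatives = [b for b in "ACGT" if b != current]
        chars[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(chars)


def _exon_layout(config: SimConfig, gene_start: int, exons: int) -> list[GenomicInterval]:
    out = []
    pos = gene_start
    for _ in range(exons):
        out.append(GenomicInterval("chr_sim", pos, pos + config.exon_len))
        pos += config.exon_len + config.intron_len
    return out


def build_tandem_locus(config: SimConfig) -> SimTruth:
    """Construct the genome, true/fused/control annotations and proteins.

    Deterministic under ``config.seed``; coordinates depend only on the
    length parameters, never on the random content.
    """
    rng = np.random.default_rng([config.seed, 0])
    seq_id = "chr_sim"

    # ancestral gene with an enforced C/H/N catalytic triad
    ancestor_dna, ancestor_protein = _build_gene_dna(
        rng, config.exons_per_gene, config.exon_len, config.intron_len
    )
    n_codons = len(ancestor_protein)
    triad_aa = (n_codons // 4, n_codons // 2, (3 * n_codons) // 4)
    if len(set(triad_aa)) != 3:
        raise ValidationError("gene too short to place a catalytic triad")
    protein_chars = list(ancestor_protein)
    coding_to_gene = []  # gene-coordinate of each coding base
    pos, consumed = 0, 0
    for i in range(config.exons_per_gene):
        for j in range(config.exon_len):
            coding_to_gene.append(pos + j)
        pos += config.exon_len + config.intron_len
    dna_chars = list(ancestor_dna)
    protected: set[int] = set()
    for aa_pos, residue in zip(triad_aa, "CHN"):
        protein_chars[aa_pos] = residue
        codon = _CODON[residue]
        for off in range(3):
            g = coding_to_gene[3 * aa_pos + off]
            dna_chars[g] = codon[off]
            protected.add(g)
    ancestor_dna = "".join(dna_chars)
    ancestor_protein = "".join(protein_chars)
    protected_frozen = frozenset(protected)

    # diverged copies
    copy_dnas = [
        _mutate(rng, ancestor_dna, config.copy_divergence, protected_frozen)
        for _ in range(config.n_copies)
    ]

    control_dna, _control_protein = _build_gene_dna(
        rng, config.control_exons, config.exon_len, config.intron_len
    )

    # assemble the genome: spacer (gene spacer)*n control spacer
    parts = [_random_dna(rng, config.spacer_len)]
    true_models = []
    cursor = config.spacer_len
    for i, dna in enumerate(copy_dnas):
        exons = _exon_layout(config, cursor, config.exons_per_gene)
        true_models.append(
            GeneModel(f"gene{i + 1}", seq_id, "+", tuple(exons))
        )
        parts.append(dna)
        cursor += len(dna)
        parts.append(_random_dna(rng, config.spacer_len))
        cursor += config.spacer_len
    control_exons = _exon_layout(config, cursor, config.control_exons)
    control_model = GeneModel("control", seq_id, "+", tuple(control_exons))
    parts.append(control_dna)
    cursor += len(control_dna)
    parts.append(_random_dna(rng, config.spacer_len))
    cursor += config.spacer_len

    genome = SequenceRecord(seq_id, "".join(parts), alphabet="nucleotide")
    assert len(genome) == config.genome_len == cursor

    fused_exons = tuple(e for m in true_models for e in m.exons)
    fused_model = GeneModel("fused", seq_id, "+", fused_exons)

    tally = {
        (model.gene_id, idx): 0
        for model in (*true_models, control_model)
        for idx in range(1, len(model.introns) + 1)
    }

    def gene_protein(model: GeneModel) -> str:
        spliced = "".join(
            genome.residues[e.start : e.end] for e in model.exons
        )
        return _translate(spliced)

    proteins = [
        SequenceRecord(f"{m.gene_id}_protein", gene_protein(m), alphabet="protein")
        for m in true_models
    ]
    proteins.append(
        SequenceRecord(
            "fused_protein",
            "".join(p.residues for p in proteins),
            alphabet="protein",
        )
    )
    domain_ref = SequenceRecord(
        "ancestor_domain", ancestor_protein, alphabet="protein"
    )
    return SimTruth(
        genome=genome,
        true_models=true_models,
        fused_model=fused_model,
        control_model=control_model,
        junction_read_tally=tally,
        proteins=proteins,
        domain_ref=domain_ref,
        triad_positions=triad_aa,
        config=config,
    )


def _transcript_blocks(
    model: GeneModel, utr: int, genome_len: int
) -> list[tuple[int, int]]:
    """Genomic blocks of the mature transcript: exons with the terminal ones
    extended by ``utr`` into the flanks (clamped to the sequence)."""
    blocks = [(e.start, e.end) for e in model.exons]
    first = (max(0, blocks[0][0] - utr), blocks[0][1])
    last = (blocks[-1][0], min(genome_len, blocks[-1][1] + utr))
    if len(blocks) == 1:
        return [(first[0], last[1])]
    return [first, *blocks[1:-1], last]


def simulate_reads(truth: SimTruth, config: SimConfig) -> list[SplicedAlignment]:
    """Draw spliced reads per gene and return them as alignments.

    Per gene with depth ``d``: N = ceil(d * mRNA_len / read_len) reads with
    stratified start positions on the mature transcript, mapped back to
    genomic blocks with gaps exactly at the true introns.  Substitution
    errors are applied at ``error_rate`` and reflected in the identity.
    Updates ``truth.junction_read_tally`` in place.
    """
    rng = np.random.default_rng([config.seed, 1])
    genome_len = len(truth.genome)
    alignments: list[SplicedAlignment] = []
    plan = list(zip(truth.true_models, config.depths))
    plan.append((truth.control_model, config.control_depth))

    for model, depth in plan:
        tblocks = _transcript_blocks(model, config.utr_len, genome_len)
        mrna_len = sum(e - s for s, e in tblocks)
        if config.read_len > mrna_len:
            raise ValidationError(
                f"{model.gene_id}: read_len {config.read_len} exceeds the "
                f"transcript length {mrna_len}"
            )
        n_reads = math.ceil(depth * mrna_len / config.read_len)
        span = mrna_len - config.read_len + 1
        introns = {
            (iv.start, iv.end): idx
            for idx, iv in enumerate(model.introns, start=1)
        }
        # block offsets within the transcript
        offsets = []
        acc = 0
        for s, e in tblocks:
            offsets.append((acc, acc + (e - s), s))
            acc += e - s
        for r in range(n_reads):
            lo = r * span / n_reads
            hi = (r + 1) * span / n_reads
            start = min(span - 1, int(rng.uniform(lo, hi)))
            end = start + config.read_len
            gblocks: list[tuple[int, int]] = []
            for toff_start, toff_end, gstart in offsets:
                a = max(start, toff_start)
                b = min(end, toff_end)
                if a < b:
                    gblocks.append((gstart + (a - toff_start), gstart + (b - toff_start)))
            gaps = [
                (gblocks[i][1], gblocks[i + 1][0]) for i in range(len(gblocks) - 1)
            ]
            n_err = (
                int(rng.binomial(config.read_len, config.error_rate))
                if config.error_rate > 0
                else 0
            )
            identity = 1.0 - n_err / config.read_len
            seq_id = model.seq_id
            alignments.append(
                SplicedAlignment(
                    read_id=f"{model.gene_id}_r{r}",
                    seq_id=seq_id,
                    blocks=tuple(GenomicInterval(seq_id, s, e) for s, e in gblocks),
                    gaps=tuple(GenomicInterval(seq_id, s, e) for s, e in gaps),
                    aligned_length=config.read_len,
                    identity=identity,
                    read_length=config.read_len,
                )
            )
            for gap in gaps:
                idx = introns.get(gap)
                if idx is not None:
                    truth.junction_read_tally[(model.gene_id, idx)] += 1
    return alignments


def reads_to_fastq(
    truth: SimTruth, alignments: Sequence[SplicedAlignment], path
) -> None:
    """Optional FASTQ export for users who want to run a real aligner.

    Sequences are reconstructed from the genome via the alignment blocks;
    substitution errors applied during simulation are not replayed.
    """
    genome = truth.genome.residues
    with open(path, "w") as fh:
        for aln in alignments:
            seq = "".join(genome[b.start : b.end] for b in aln.blocks)
            fh.write(f"@{aln.read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
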