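# fusionscreen

A gene-model curation toolkit that detects **artificially fused gene models**
— e.g. a tandem array of paralogous genes mis-annotated as one gene with
multiplied protein domains — from three independent lines of evidence:

1. **RNA-seq junction/coverage evidence** (`coverage`, `junctions`):
   alignments are filtered at a minimum identity of 0.95 and a minimum
   aligned read fraction of 0.90, per-position coverage tracks are computed,
   and every annotated intron is classified by its *link ratio* — the number
   of intron-spanning split reads divided by the coverage at the borders of
   the flanking exons. A genuine intron is spanned by roughly as many reads
   as its flanks are covered; an intergenic spacer mis-annotated as an
   intron has essentially none. Unsupported introns yield a
   `LIKELY_FUSION` verdict and proposed split models.
2. **Locus self-similarity** (`dotplot`): exact k-mer matching (default
   k = 31) between two sequences (or a locus against itself); tandem copies
   appear as off-diagonals.
3. **Protein domain-copy counting** (`repeats`): a strict >500-residue
   length screen, iterative Smith–Waterman (BLOSUM62, affine gaps −11/−1)
   counting of domain copies against a single-domain reference with masking
   between rounds, and a Cys/His/Asn catalytic-triad conservation check via
   global alignment.

A seeded simulator (`simulate`) generates truth-known tandem loci — genome,
correct and fused annotations, spliced read alignments (SAM), and a
paralog-derived protein set including a domain-triplication decoy — so the
whole pipeline is testable hermetically, without downloads.

## CLI

```bash
# generate a truth-known locus (3 tandem genes + fused decoy annotation)
fusionscreen simulate --seed 7 -o out/

# screen the fused annotation against the read evidence
fusionscreen screen --gff out/annotation_fused.gff3 --sam out/reads.sam -o screen/
cat screen/summary.tsv          # gene_id  verdict  n_introns  n_unsupported  split_coordinates
# screen/report.json            # full per-intron/per-exon evidence, thresholds echoed
# screen/proposed_models.gff3   # split gene models for LIKELY_FUSION genes

# coverage track (one dense "position<TAB>count" file per reference)
fusionscreen coverage --sam out/reads.sam -o cov/

# gene-focused coverage plot (+ machine-readable sidecar TSV of the drawn data)
fusionscreen plot --coverage cov/chr_sim.cov.tsv --gff out/annotation_fused.gff3 \
    --gene fused -o fused.png

# k-mer self-similarity table
fusionscreen dotplot out/genome.fasta out/genome.fasta --k 31 -o matches.tsv

# domain-copy + catalytic-triad scan
fusionscreen repeatscan --domain out/proteins.fasta --proteins out/proteins.fasta \
    --min-len 0 --triad 33,66,99 -o repeats.tsv
```

Exit codes: 0 success, 1 validation/format error, 2 I/O or usage error.
Screening thresholds (`--theta-supported 0.5`, `--theta-unsupported 0.05`,
`--min-edge-depth 10`, `--junction-slack 0`, `--edge-window 10`) are all
configurable and echoed into the JSON report.

Coordinates are 0-based half-open internally; GFF3/SAM/coverage files use
their native 1-based conventions at the file boundary.

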