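import numpy as np
import pytest

from fusionscreen import coverage as cov
from fusionscreen import simulate as sim
from fusionscreen.io_formats import GenomicInterval, SplicedAlignment


def make_alignment(
    read_id,
    seq_id,
    blocks,
    identity=1.0,
    aligned_length=None,
    read_length=None,
):
    """Build a SplicedAlignment from (start, end) block tuples; gaps derived."""
    ivs = tuple(GenomicInterval(seq_id, s, e) for s, e in blocks)
    gaps = tuple(
        GenomicInterval(seq_id, a.end, b.start) for a, b in zip(ivs, ivs[1:])
    )
    span = sum(e - s for s, e in blocks)
    if aligned_length is None:
        aligned_length = span
    if read_length is None:
        read_length = aligned_length
    return SplicedAlignment(
        read_id=read_id,
        seq_id=seq_id,
        blocks=ivs,
        gaps=gaps,
        aligned_length=aligned_length,
        identity=identity,
        read_length=read_length,
    )


def random_alignments(rng, n, seq_id="chrT", seq_len=5000, max_blocks=3):
    """Random spliced alignments for round-trip and oracle tests."""
    out = []
    for i in range(n):
        n_blocks = int(rng.integers(1, max_blocks + 1))
        pos = int(rng.integers(0, seq_len - 600))
        blocks = []
        for _ in range(n_blocks):
            length = int(rng.integers(20, 80))
            blocks.append((pos, pos + length))
            pos += length + int(rng.integers(30, 120))
        aligned = sum(e - s for s, e in blocks)
        read_len = aligned + int(rng.integers(0, 15))
        nm = int(rng.integers(0, 6))
        out.append(
            make_alignment(
                f"rand{i}",
                seq_id,
                blocks,
                identity=1.0 - nm / aligned,
                aligned_length=aligned,
                read_length=read_len,
            )
        )
    return out


@pytest.fixture(scope="session")
def sim_config():
    return sim.SimConfig(seed=7)


@pytest.fixture(scope="session")
def sim_truth(sim_config):
    return sim.build_tandem_locus(sim_config)


@pytest.fixture(scope="session")
def sim_alignments(sim_truth, sim_config):
    return sim.simulate_reads(sim_truth, sim_config)


@pytest.fixture(scope="session")
def sim_track(sim_truth, sim_alignments):
    return cov.compute_coverage(
        sim_alignments, sim_truth.genome.id, len(sim_truth.genome)
    )
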