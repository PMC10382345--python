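from __future__ import annotations

import numpy as np
import pytest

from regg4.g4_scanner import G4Motif


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def make_motif(
    run_lengths,
    loop_lengths=None,
    start=0,
    strand="+",
    chrom="chr1",
) -> G4Motif:
    """Construct a structurally consistent G4Motif from a layout."""
    run_lengths = tuple(run_lengths)
    if loop_lengths is None:
        loop_lengths = tuple([3] * (len(run_lengths) - 1))
    loop_lengths = tuple(loop_lengths)
    g_runs = []
    pos = start
    seq_parts = []
    for k, rl in enumerate(run_lengths):
        g_runs.append((pos, pos + rl))
        seq_parts.append("G" * rl)
        pos += rl
        if k < len(loop_lengths):
            seq_parts.append("A" * loop_lengths[k])
            pos += loop_lengths[k]
    return G4Motif(
        start=start,
        end=pos,
        strand=strand,
        g_runs=tuple(g_runs),
        loop_lengths=loop_lengths,
        n_runs=len(run_lengths),
        sequence="".join(seq_parts),
        chrom=chrom,
    )


def random_4run_motif(rng: np.random.Generator, start=0, strand=None) -> G4Motif:
    runs = tuple(int(rng.integers(3, 9)) for _ in range(4))
    loops = tuple(int(rng.integers(1, 13)) for _ in range(3))
    if strand is None:
        strand = "+" if rng.random() < 0.5 else "-"
    return make_motif(runs, loops, start=start, strand=strand)
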