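"""G-quadruplex motif scanning under an explicit sequence grammar.

A G4-motif is a chain of >= ``min_runs`` maximal G-runs, each at least
``min_run`` guanines long, separated by loops of ``min_loop``..``max_loop``
nucleotides, with total span at most ``max_len``.  Runs must be literal
G's; loops may contain any base, including sub-threshold G stretches of
one or two guanines.  Defaults (3 G per run, 4 runs, loops 1-12 nt,
span <= 109 bp) describe canonical DNA quadruplexes with the extended
loop range that captures promoter G4s with long loops.

Motif selection is greedy leftmost-maximal: scanning runs left to right,
a motif opens at the first run that begins a chain of >= ``min_runs``
runs and extends through every subsequent run while loop bounds hold and
the total span stays within ``max_len``; if including the next run would
exceed ``max_len`` the motif is emitted without it and scanning resumes
at that run.  Reported motifs are therefore mutually non-overlapping on
a strand, start at a maximal-run start and end at a maximal-run end.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome_io import GenomicInterval

__all__ = [
    "G4Params",
    "G4Motif",
    "DEFAULT_PARAMS",
    "find_g_runs",
    "scan_sequence",
    "scan_both_strands",
    "scan_features",
    "tss_distance_profile",
    "revcomp",
]

_RC = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class G4Params:
    """Grammar bounds for G4-motif scanning."""

    min_run: int = 3
    min_loop: int = 1
    max_loop: int = 12
    min_runs: int = 4
    max_len: int = 109

    def __post_init__(self) -> None:
        if self.min_run < 2:
            raise ValueError("min_run must be >= 2")
        if not 1 <= self.min_loop <= self.max_loop:
            raise ValueError("need 1 <= min_loop <= max_loop")
        if self.min_runs < 4:
            raise ValueError("min_runs must be >= 4")
        floor = self.min_runs * self.min_run + (self.min_runs - 1) * self.min_loop
        if self.max_len < floor:
            raise ValueError(f"max_len {self.max_len} below minimal motif {floor}")


DEFAULT_PARAMS = G4Params()


@dataclass(frozen=True)
class G4Motif:
    """A detected motif; coordinates are + strand, 0-based half-open.

    ``g_runs`` are the maximal G-runs in + coordinate order; for a motif
    on the - strand they correspond to C-runs of the + strand sequence
    and ``sequence`` holds the motif-strand (reverse-complement) bases.
    """

    start: int
    end: int
    strand: str
    g_runs: tuple[tuple[int, int], ...]
    loop_lengths: tuple[int, ...]
    n_runs: int
    sequence: str
    chrom: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def run_lengths(self) -> tuple[int, ...]:
        """Run lengths in motif-strand order (reversed for - strand)."""
        lens = tuple(e - s for s, e in self.g_runs)
        return lens[::-1] if self.strand == "-" else lens

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom or ".", self.start, self.end, self.strand)

    def key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.strand, self.g_runs)


@lru_cache(maxsize=8)
def _run_re(min_run: int) -> re.Pattern:
    return re.compile("G{%d,}" % min_run)


def find_g_runs(seq: str, min_run: int = 3) -> list[tuple[int, int]]:
    """Maximal runs of 'G' with length >= min_run, left to right."""
    return [m.span() for m in _run_re(min_run).finditer(seq)]


def _chain_spans(
    runs: Sequence[tuple[int, int]], params: G4Params
) -> list[tuple[int, int]]:
    """Greedy leftmost-maximal chains as (first_run_idx, last_run_idx)."""
    spans = []
    i, n = 0, len(runs)
    while i < n:
        j = i
        while j + 1 < n:
            gap = runs[j + 1][0] - runs[j][1]
            if gap < params.min_loop or gap > params.max_loop:
                break
            if runs[j + 1][1] - runs[i][0] > params.max_len:
                break
            j += 1
        if j - i + 1 >= params.min_runs:
            spans.append((i, j))
            i = j + 1
        else:
            i += 1
    return spans


def scan_sequence(
    seq: str,
    params: G4Params = DEFAULT_PARAMS,
    *,
    chrom: str | None = None,
) -> list[G4Motif]:
    """Scan the + strand of ``seq``; motifs in sequence-local coordinates."""
    runs = find_g_runs(seq, params.min_run)
    motifs = []
    for i, j in _chain_spans(runs, params):
        g = tuple(runs[i : j + 1])
        loops = tuple(g[k + 1][0] - g[k][1] for k in range(len(g) - 1))
        s, e = g[0][0], g[-1][1]
        motifs.append(
            G4Motif(
                start=s,
                end=e,
                strand="+",
                g_runs=g,
                loop_lengths=loops,
                n_runs=len(g),
                sequence=seq[s:e],
                chrom=chrom,
            )
        )
    return motifs


def scan_both_strands(
    chrom: str | None, seq: str, params: G4Params = DEFAULT_PARAMS
) -> list[G4Motif]:
    """Scan both strands; - strand motifs projected to + coordinates.

    Overlapping motifs on opposite strands are both retained as distinct
    motifs (flattening for overlap statistics happens downstream).
    """
    motifs = scan_sequence(seq, params, chrom=chrom)
    L = len(seq)
    for m in scan_sequence(revcomp(seq), params):
        g = tuple((L - e, L - s) for s, e in reversed(m.g_runs))
        motifs.append(
            G4Motif(
                start=L - m.end,
                end=L - m.start,
                strand="-",
                g_runs=g,
                loop_lengths=m.loop_lengths[::-1],
                n_runs=m.n_runs,
                sequence=m.sequence,
                chrom=chrom,
            )
        )
    motifs.sort(key=lambda m: (m.start, m.end, m.strand))
    return motifs


def _shift(motif: G4Motif, offset: int) -> G4Motif:
    return replace(
        motif,
        start=motif.start + offset,
        end=motif.end + offset,
        g_runs=tuple((s + offset, e + offset) for s, e in motif.g_runs),
    )


def scan_features(
    features: Iterable[GenomicInterval],
    genome: Mapping[str, str],
    params: G4Params = DEFAULT_PARAMS,
) -> dict[GenomicInterval, list[G4Motif]]:
    """Scan both strands of each feature; motif coordinates genome-absolute."""
    out: dict[GenomicInterval, list[G4Motif]] = {}
    for f in features:
        if f.chrom not in genome:
            raise ValueError(f"feature on unknown chromosome {f.chrom}")
        if f.end > len(genome[f.chrom]):
            raise ValueError(
                f"feature {f.chrom}:{f.start}-{f.end} exceeds chromosome bounds"
            )
        seq = genome[f.chrom][f.start : f.end]
        out[f] = [_shift(m, f.start) for m in scan_both_strands(f.chrom, seq, params)]
    return out


def tss_distance_profile(
    motifs: Iterable[G4Motif],
    genes: Iterable,
    window: int = 500,
    bin_size: int = 50,
) -> np.ndarray:
    """Histogram of motif counts by strand-aware distance upstream of the TSS.

    A motif is assigned by its midpoint; distance d (1..window, where d=1
    is the base adjacent to the TSS) falls into bin floor((d-1)/bin_size),
    i.e. bins cover distances (0,50], (50,100], ...  Counts sum to the
    number of motifs whose midpoint lies in some gene's upstream window.
    """
    n_bins = window // bin_size
    hist = np.zeros(n_bins, dtype=int)
    motif_list = list(motifs)
    for g in genes:
        for m in motif_list:
            if m.chrom is not None and m.chrom != g.chrom:
                continue
            mid = m.midpoint
            if g.strand == "+":
                d = g.tss - mid
            else:
                d = mid - g.tss
            if 1 <= d <= window:
                hist[(d - 1) // bin_size] += 1
    return hist
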