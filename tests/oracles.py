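"""Independent reference implementations used only to check the package.

These deliberately share no code with regg4: runs are parsed by a
character walk instead of a regex, candidate motifs are enumerated
exhaustively instead of chained greedily, and selection re-derives the
leftmost-then-longest non-overlap rule from the candidate list.
"""
from __future__ import annotations

import numpy as np


def parse_runs_naive(seq: str, min_run: int = 3) -> list[tuple[int, int]]:
    runs = []
    i, n = 0, len(seq)
    while i < n:
        if seq[i] == "G":
            j = i
            while j < n and seq[j] == "G":
                j += 1
            if j - i >= min_run:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def brute_force_scan(
    seq: str,
    min_run: int = 3,
    min_loop: int = 1,
    max_loop: int = 12,
    min_runs: int = 4,
    max_len: int = 109,
) -> list[tuple[int, int]]:
    """All grammar-satisfying substrings, reduced by leftmost-longest
    non-overlapping selection.  Returns (start, end) spans.

    A valid motif substring starts at a maximal-run start and ends at a
    maximal-run end (anything else would leave a boundary run that is
    not maximal), contains >= min_runs qualifying runs with consecutive
    gaps in [min_loop, max_loop], and spans at most max_len bases.
    """
    runs = parse_runs_naive(seq, min_run)
    candidates: list[tuple[int, int]] = []
    for a in range(len(runs)):
        for b in range(a + min_runs - 1, len(runs)):
            broken = False
            for k in range(a, b):
                gap = runs[k + 1][0] - runs[k][1]
                if not (min_loop <= gap <= max_loop):
                    broken = True
                    break
            if broken:
                break  # every longer chain from a contains the broken gap
            if runs[b][1] - runs[a][0] > max_len:
                break  # longer chains from a are longer still
            candidates.append((runs[a][0], runs[b][1]))
    chosen: list[tuple[int, int]] = []
    candidates.sort()
    while candidates:
        start = candidates[0][0]
        end = max(e for s, e in candidates if s == start)
        chosen.append((start, end))
        candidates = [(s, e) for s, e in candidates if s >= end]
    return chosen


def disruptive_count_closed_form(run_lengths) -> int:
    """Sum of f(len) with f(3)=3, f(4)=2, f(5)=1, f(>=6)=0."""
    table = {3: 3, 4: 2, 5: 1}
    return sum(table.get(int(l), 0) for l in run_lengths)


def random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])
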