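"""Promoter-enhancer G4 co-occurrence analysis.

Each enhancer RNA (eRNA) is associated with one or more genes.  For
every eRNA we compute the fraction of its partner promoters that carry
a G4-motif, split the eRNAs by their own G4 status, and compare the two
ratio samples with a two-sample rank-sum (Mann-Whitney/Wilcoxon) test.
The rank-sum test is implemented here (exact permutation distribution
for small samples, tie- and continuity-corrected normal approximation
otherwise) so the pipeline carries no statistical black box.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import GenomicInterval
from .interval_stats import _as_intervals, merged_by_chrom

log = logging.getLogger(__name__)

ASSOC_COLUMNS = ("gene_id", "erna_id")


def read_associations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ASSOC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"association TSV {path} missing columns {missing}")
    return df[list(ASSOC_COLUMNS)]


def write_associations(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=list(ASSOC_COLUMNS))


def flag_features(features, motifs: Iterable) -> dict[str, bool]:
    """Per-feature G4 status: does any motif overlap the feature?

    Keyed by the feature's name (or 'chrom:start-end' when unnamed).
    """
    motif_ivs = [m.interval if hasattr(m, "interval") else m for m in motifs]
    merged = merged_by_chrom(motif_ivs) if motif_ivs else {}
    flags: dict[str, bool] = {}
    for f in _as_intervals(features):
        key = f.name or f"{f.chrom}:{f.start}-{f.end}"
        arr = merged.get(f.chrom)
        has = False
        if arr is not None and len(arr):
            # merged intervals are disjoint and sorted, so ends are sorted too
            i = int(np.searchsorted(arr[:, 0], f.end, "left"))
            has = i > 0 and int(arr[i - 1, 1]) > f.start
        flags[key] = has
    return flags


@dataclass(frozen=True)
class RatioSamples:
    """Per-eRNA promoter-G4 ratios, split by the eRNA's own G4 status."""

    with_g4: np.ndarray
    without_g4: np.ndarray
    n_excluded: int = 0


def per_erna_promoter_g4_ratio(
    assoc: pd.DataFrame,
    prom_has_g4: Mapping[str, bool],
    erna_has_g4: Mapping[str, bool],
) -> RatioSamples:
    """For each eRNA, the fraction of associated promoters carrying a G4.

    eRNAs with zero associated genes are excluded (logged).  Unknown
    gene or eRNA identifiers are an error.
    """
    ratios: dict[bool, list[float]] = {True: [], False: []}
    seen = set()
    for erna_id, grp in assoc.groupby("erna_id"):
        if erna_id not in erna_has_g4:
            raise ValueError(f"association table references unknown eRNA {erna_id!r}")
        vals = []
        for gid in grp["gene_id"]:
            if gid not in prom_has_g4:
                raise ValueError(f"association table references unknown gene {gid!r}")
            vals.append(bool(prom_has_g4[gid]))
        ratios[bool(erna_has_g4[erna_id])].append(float(np.mean(vals)))
        seen.add(erna_id)
    n_excluded = len(set(erna_has_g4) - seen)
    if n_excluded:
        log.info("per_erna_promoter_g4_ratio: %d eRNAs with no associations excluded", n_excluded)
    return RatioSamples(
        with_g4=np.asarray(ratios[True]),
        without_g4=np.asarray(ratios[False]),
        n_excluded=n_excluded,
    )


def _midranks(values: np.ndarray) -> np.ndarray:
    """Average ranks (1-based) with ties sharing their midrank."""
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values))
    sv = values[order]
    i = 0
    while i < len(sv):
        j = i
        while j + 1 < len(sv) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def _exact_ranksum_p(double_ranks: np.ndarray, n_a: int, w_a: int) -> float:
    """Two-sided exact p for the rank sum via subset-sum counting.

    Counts, over all C(N, n_a) assignments of the pooled (doubled,
    integer) midranks to group A, how many give a rank sum <= / >= the
    observed one.  Equivalent to exhaustive enumeration.
    """
    N = len(double_ranks)
    max_sum = int(double_ranks.sum())
    # ways[k][s] = number of k-subsets of the ranks seen so far summing to s
    ways = np.zeros((n_a + 1, max_sum + 1), dtype=float)
    ways[0, 0] = 1.0
    for r in double_ranks:
        r = int(r)
        # descending k so each rank is used at most once (0/1 knapsack)
        for k in range(n_a, 0, -1):
            ways[k, r:] += ways[k - 1, 0 : max_sum + 1 - r]
    dist = ways[n_a]
    total = dist.sum()
    p_le = dist[: w_a + 1].sum() / total
    p_ge = dist[w_a:].sum() / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def rank_sum_test(sample_a: Sequence[float], sample_b: Sequence[float]) -> float:
    """Two-sided two-sample rank-sum (Mann-Whitney) p value.

    Exact permutation distribution when both samples have at most 12
    observations (correct under ties via midranks); otherwise the normal
    approximation with tie correction and a 0.5 continuity correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("rank_sum_test: both samples must be non-empty")
    n, m = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    w = float(ranks[:n].sum())

    if n <= 12 and m <= 12:
        double = np.rint(2 * ranks).astype(int)
        return _exact_ranksum_p(double, n, int(round(2 * w)))

    N = n + m
    mu = n * (N + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (N * (N - 1))
    var = n * m / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = (abs(w - mu) - 0.5) / math.sqrt(var)
    if z < 0:
        z = 0.0
    return math.erfc(z / math.sqrt(2))


@dataclass(frozen=True)
class InteractionReport:
    n_with_g4: int
    n_without_g4: int
    mean_with_g4: float
    mean_without_g4: float
    median_with_g4: float
    median_without_g4: float
    p_value: float
    stars: str
    n_excluded: int


def interaction_report(samples: RatioSamples) -> InteractionReport:
    from .randomization import significance_stars

    p = rank_sum_test(samples.with_g4, samples.without_g4)
    return InteractionReport(
        n_with_g4=len(samples.with_g4),
        n_without_g4=len(samples.without_g4),
        mean_with_g4=float(np.mean(samples.with_g4)),
        mean_without_g4=float(np.mean(samples.without_g4)),
        median_with_g4=float(np.median(samples.with_g4)),
        median_without_g4=float(np.median(samples.without_g4)),
        p_value=p,
        stars=significance_stars(p),
        n_excluded=samples.n_excluded,
    )
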