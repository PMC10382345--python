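"""Empirical null models and randomization significance.

Three null frameworks share one empirical significance rule:

* length-matched random regions (motif-density enrichment),
* per-chromosome fragment resampling of equal number and length
  (SNP-density tests),
* GC- and length-matched random regions paired with random motif
  subsamples (motif polymorphism corrected for base composition).

The empirical p is the plain ratio r/n of randomizations at least as
extreme as the observation (ties count toward both tails); a p of 0 is
formatted as "< 1/n" while stored as 0.0.  Every operation is a pure
function of its inputs and a seed: one root seed derives per-operation
generators via ``rng_from(root, *labels)``, which feeds the CRC32 of
each label into a numpy SeedSequence alongside the root.
"""
from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .g4_scanner import DEFAULT_PARAMS, G4Motif, G4Params, scan_both_strands
from .genome_io import GenomicInterval
from .interval_stats import (
    FeatureSet,
    _as_intervals,
    merged_by_chrom,
    snps_by_chrom,
    total_flattened_length,
)

log = logging.getLogger(__name__)

__all__ = [
    "rng_from",
    "GenomeStats",
    "DensityTestResult",
    "GCMatchedTestResult",
    "empirical_p",
    "significance_stars",
    "format_p",
    "sample_length_matched",
    "sample_gc_matched",
    "run_density_enrichment",
    "run_snp_density_test",
    "run_gc_matched_snp_test",
]


def rng_from(seed: int, *labels: str | int) -> np.random.Generator:
    """Deterministic child generator: SeedSequence([seed, crc32(label), ...])."""
    entropy = [int(seed)]
    for lab in labels:
        entropy.append(zlib.crc32(str(lab).encode()) if isinstance(lab, str) else int(lab))
    return np.random.default_rng(np.random.SeedSequence(entropy))


class GenomeStats:
    """Prefix-sum views of a genome for O(1) windowed GC / N queries."""

    def __init__(self, genome: Mapping[str, str]):
        self.chroms = list(genome)
        self.lengths = {c: len(genome[c]) for c in self.chroms}
        self._gc: dict[str, np.ndarray] = {}
        self._n: dict[str, np.ndarray] = {}
        for c, seq in genome.items():
            arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            gc = (arr == ord("G")) | (arr == ord("C"))
            nn = arr == ord("N")
            self._gc[c] = np.concatenate([[0], np.cumsum(gc, dtype=np.int64)])
            self._n[c] = np.concatenate([[0], np.cumsum(nn, dtype=np.int64)])

    def n_fraction(self, chrom: str, starts, ends) -> np.ndarray:
        starts = np.asarray(starts)
        ends = np.asarray(ends)
        npfx = self._n[chrom]
        return (npfx[ends] - npfx[starts]) / np.maximum(ends - starts, 1)

    def gc_fraction(self, chrom: str, starts, ends) -> np.ndarray:
        """GC over non-N bases; NaN where the window is all N."""
        starts = np.asarray(starts)
        ends = np.asarray(ends)
        gc = self._gc[chrom][ends] - self._gc[chrom][starts]
        nn = self._n[chrom][ends] - self._n[chrom][starts]
        denom = (ends - starts) - nn
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, gc / np.maximum(denom, 1), np.nan)


def empirical_p(observed: float, null_values: Sequence[float]) -> tuple[float, float]:
    """(p_higher, p_lower): fractions of null values >= / <= the observation."""
    null = np.asarray(null_values, dtype=float)
    if null.size == 0:
        raise ValueError("empirical_p: empty null distribution")
    return float(np.mean(null >= observed)), float(np.mean(null <= observed))


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


def format_p(p: float, n_iter: int) -> str:
    return f"< {1 / n_iter:g}" if p == 0.0 else f"{p:g}"


@dataclass(frozen=True)
class DensityTestResult:
    """Observed statistic vs an empirical null distribution."""

    observed: float
    null_values: tuple[float, ...]
    p_higher: float
    p_lower: float
    n_iter: int
    seed: int
    scope: str = "genome"

    @classmethod
    def from_null(cls, observed, null_values, seed, scope="genome"):
        p_hi, p_lo = empirical_p(observed, null_values)
        return cls(
            observed=float(observed),
            null_values=tuple(float(v) for v in null_values),
            p_higher=p_hi,
            p_lower=p_lo,
            n_iter=len(null_values),
            seed=seed,
            scope=scope,
        )

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_values))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_values))

    @property
    def null_min(self) -> float:
        return float(np.min(self.null_values))

    @property
    def null_max(self) -> float:
        return float(np.max(self.null_values))

    @property
    def stars(self) -> str:
        return significance_stars(min(self.p_higher, self.p_lower))


@dataclass(frozen=True)
class GCMatchedTestResult:
    """Paired motif-sample vs GC/length-matched random-region densities."""

    observed: float  # pooled SNP density over all motifs
    motif_densities: tuple[float, ...]
    random_densities: tuple[float, ...]
    p_random_higher: float
    n_iter: int
    seed: int
    scope: str = "genome"

    @property
    def stars(self) -> str:
        return significance_stars(
            min(self.p_random_higher, 1.0 - self.p_random_higher)
        )


def _placement_weights(
    stats: GenomeStats, length: int, chrom: str | None
) -> tuple[list[str], np.ndarray]:
    chroms = [chrom] if chrom is not None else stats.chroms
    ok = [c for c in chroms if stats.lengths[c] >= length]
    if not ok:
        raise ValueError(f"no chromosome can host a fragment of length {length}")
    w = np.array([stats.lengths[c] - length + 1 for c in ok], dtype=float)
    return ok, w / w.sum()


def sample_length_matched(
    genome: Mapping[str, str] | None,
    lengths: Sequence[int],
    seed: int | None = None,
    chrom: str | None = None,
    *,
    rng: np.random.Generator | None = None,
    stats: GenomeStats | None = None,
    max_n_fraction: float = 0.5,
    max_redraws: int = 100,
) -> list[GenomicInterval]:
    """Random regions with the given lengths, uniform over valid placements.

    Regions with more than ``max_n_fraction`` N are rejected and redrawn
    (at most ``max_redraws`` times each).  Deterministic for a fixed seed.
    """
    if stats is None:
        stats = GenomeStats(genome)
    if rng is None:
        rng = np.random.default_rng(seed)
    out: list[GenomicInterval] = []
    for L in lengths:
        chroms, w = _placement_weights(stats, L, chrom)
        for _ in range(max_redraws + 1):
            c = chroms[int(rng.choice(len(chroms), p=w))]
            s = int(rng.integers(0, stats.lengths[c] - L + 1))
            if float(stats.n_fraction(c, [s], [s + L])[0]) <= max_n_fraction:
                out.append(GenomicInterval(c, s, s + L))
                break
        else:
            raise RuntimeError(
                f"sample_length_matched: redraw limit exceeded for length {L}"
            )
    return out


def _sample_starts(
    stats: GenomeStats,
    chrom: str,
    length: int,
    size: int,
    rng: np.random.Generator,
    max_n_fraction: float = 0.5,
    max_rounds: int = 100,
) -> np.ndarray:
    """Vectorized uniform starts on one chromosome with N-fraction rejection."""
    hi = stats.lengths[chrom] - length + 1
    if hi <= 0:
        raise ValueError(f"length {length} exceeds {chrom}")
    starts = rng.integers(0, hi, size=size)
    for _ in range(max_rounds):
        bad = stats.n_fraction(chrom, starts, starts + length) > max_n_fraction
        if not bad.any():
            return starts
        starts = starts.copy()
        starts[bad] = rng.integers(0, hi, size=int(bad.sum()))
    raise RuntimeError(f"N-rejection did not converge on {chrom} (length {length})")


def sample_gc_matched(
    genome: Mapping[str, str] | None,
    templates: Sequence[tuple[int, float]],
    tolerance: float = 0.02,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    stats: GenomeStats | None = None,
    batch: int = 1000,
    max_tolerance: float = 0.10,
    max_draws_at_cap: int = 20_000,
) -> list[GenomicInterval]:
    """Random regions matching (length, GC) templates.

    Rejection sampling in batches; the tolerance widens by 0.02 after
    every 1,000 failed draws for a template, up to ``max_tolerance``
    (each widening is logged).  A template with no qualifying region at
    the widest tolerance is an error.
    """
    if stats is None:
        stats = GenomeStats(genome)
    if rng is None:
        rng = np.random.default_rng(seed)
    out: list[GenomicInterval] = []
    for length, gc_target in templates:
        chroms, w = _placement_weights(stats, length, None)
        failed = 0
        draws_at_cap = 0
        tol = tolerance
        found = None
        while found is None:
            eff = min(max_tolerance, tolerance + 0.02 * (failed // batch))
            if eff > tol:
                log.info(
                    "sample_gc_matched: widened tolerance to %.2f for template "
                    "(len=%d, gc=%.3f)",
                    eff,
                    length,
                    gc_target,
                )
                tol = eff
            c = chroms[int(rng.choice(len(chroms), p=w))]
            starts = rng.integers(0, stats.lengths[c] - length + 1, size=batch)
            gcs = stats.gc_fraction(c, starts, starts + length)
            nfr = stats.n_fraction(c, starts, starts + length)
            ok = np.flatnonzero(
                (np.abs(gcs - gc_target) <= tol) & (nfr <= 0.5) & np.isfinite(gcs)
            )
            if ok.size:
                s = int(starts[ok[0]])
                found = GenomicInterval(c, s, s + length)
            else:
                failed += batch
                if tol >= max_tolerance:
                    draws_at_cap += batch
                    if draws_at_cap >= max_draws_at_cap:
                        raise ValueError(
                            "sample_gc_matched: no region matching template "
                            f"(len={length}, gc={gc_target:.3f}) at tolerance "
                            f"{max_tolerance}"
                        )
        out.append(found)
    return out


def _pooled_scan_density(
    regions: Sequence[GenomicInterval],
    genome: Mapping[str, str],
    params: G4Params,
) -> tuple[int, int]:
    count = 0
    total = 0
    for r in regions:
        seq = genome[r.chrom][r.start : r.end]
        count += len(scan_both_strands(r.chrom, seq, params))
        total += r.length
    return count, total


def run_density_enrichment(
    features,
    genome: Mapping[str, str],
    params: G4Params = DEFAULT_PARAMS,
    n_iter: int = 500,
    n_sample: int | None = None,
    seed: int = 0,
    *,
    stats: GenomeStats | None = None,
    statistic: str = "pooled",
    scope: str = "genome",
) -> DensityTestResult:
    """Motif density of the features vs length-matched random regions.

    Each of ``n_iter`` iterations draws ``n_sample`` random regions
    length-matched to the features — the exact feature lengths when
    ``n_sample`` equals the number of features, otherwise lengths
    resampled from the feature-length pool — scans them on both strands,
    and records the pooled (default) or mean per-kb density.
    """
    intervals = _as_intervals(features)
    if not intervals:
        raise ValueError("run_density_enrichment: empty feature set")
    if stats is None:
        stats = GenomeStats(genome)
    rng = np.random.default_rng(seed)
    obs_count, _ = _pooled_scan_density(intervals, genome, params)
    observed = 1000.0 * obs_count / total_flattened_length(intervals)

    lengths_pool = np.array([iv.length for iv in intervals])
    if n_sample is None:
        n_sample = min(len(intervals), 500)
    exact_match = n_sample == len(lengths_pool)
    nulls = []
    for _ in range(n_iter):
        lens = (
            lengths_pool
            if exact_match
            else rng.choice(lengths_pool, size=n_sample, replace=True)
        )
        regions = sample_length_matched(None, lens, rng=rng, stats=stats)
        if statistic == "pooled":
            cnt, total = _pooled_scan_density(regions, genome, params)
            nulls.append(1000.0 * cnt / total)
        else:
            dens = [
                1000.0
                * len(scan_both_strands(r.chrom, genome[r.chrom][r.start : r.end], params))
                / r.length
                for r in regions
            ]
            nulls.append(float(np.mean(dens)))
    return DensityTestResult.from_null(observed, nulls, seed, scope)


def run_snp_density_test(
    targets,
    genome: Mapping[str, str],
    snps,
    n_iter: int = 10_000,
    per_chrom: bool = True,
    seed: int = 0,
    *,
    stats: GenomeStats | None = None,
) -> list[DensityTestResult]:
    """SNP density of target intervals vs equal-number, equal-length
    random fragments drawn from the same chromosome.

    Targets are flattened first; the null resamples one fragment per
    flattened piece, pooling counts within each iteration.  With
    ``per_chrom`` one test per chromosome is returned, otherwise a
    single genome-wide test whose fragments stay on their own chromosome.
    """
    merged = merged_by_chrom(targets)
    if not merged:
        raise ValueError("run_snp_density_test: empty target set")
    if stats is None:
        stats = GenomeStats(genome)
    pos = snps if isinstance(snps, dict) else snps_by_chrom(snps)
    rng = np.random.default_rng(seed)

    groups = (
        [(c, {c: merged[c]}) for c in sorted(merged)]
        if per_chrom
        else [("genome", merged)]
    )
    results = []
    for scope, grp in groups:
        obs_count = 0
        total_len = 0
        null_counts = np.zeros(n_iter, dtype=np.int64)
        for chrom, arr in grp.items():
            p = pos.get(chrom, np.empty(0, dtype=np.int64))
            obs_count += int(
                (np.searchsorted(p, arr[:, 1]) - np.searchsorted(p, arr[:, 0])).sum()
            )
            for s, e in arr:
                L = int(e - s)
                total_len += L
                starts = _sample_starts(stats, chrom, L, n_iter, rng)
                null_counts += np.searchsorted(p, starts + L) - np.searchsorted(p, starts)
        observed = obs_count / total_len
        nulls = null_counts / total_len
        results.append(DensityTestResult.from_null(observed, nulls, seed, scope))
    return results


def run_gc_matched_snp_test(
    motifs: Sequence[G4Motif],
    genome: Mapping[str, str],
    snps,
    n_motif_sample: int = 100,
    n_iter: int = 500,
    seed: int = 0,
    tolerance: float = 0.02,
    *,
    stats: GenomeStats | None = None,
    scope: str = "genome",
) -> GCMatchedTestResult:
    """Polymorphism of motifs vs GC/length-matched random sequence.

    Each iteration draws ``n_motif_sample`` motifs without replacement
    and compares their pooled SNP density with that of random regions
    matched to each sampled motif's length and GC content.  The reported
    p is the fraction of iterations in which the random regions were
    denser than the motifs (strictly greater; all-tie iterations count
    against the motif-depletion direction, a documented consequence of
    the strict inequality).
    """
    motifs = list(motifs)
    if len(motifs) < n_motif_sample:
        raise ValueError(
            f"run_gc_matched_snp_test: need >= {n_motif_sample} motifs, got {len(motifs)}"
        )
    if stats is None:
        stats = GenomeStats(genome)
    pos = snps if isinstance(snps, dict) else snps_by_chrom(snps)
    rng = np.random.default_rng(seed)

    lens = np.array([m.length for m in motifs])
    gcs = np.empty(len(motifs))
    counts = np.empty(len(motifs), dtype=np.int64)
    for k, m in enumerate(motifs):
        gcs[k] = float(stats.gc_fraction(m.chrom, [m.start], [m.end])[0])
        p = pos.get(m.chrom, np.empty(0, dtype=np.int64))
        counts[k] = np.searchsorted(p, m.end) - np.searchsorted(p, m.start)

    observed = counts.sum() / lens.sum()
    motif_d = []
    random_d = []
    for _ in range(n_iter):
        idx = rng.choice(len(motifs), size=n_motif_sample, replace=False)
        motif_d.append(counts[idx].sum() / lens[idx].sum())
        templates = [(int(lens[i]), float(gcs[i])) for i in idx]
        regions = sample_gc_matched(
            None, templates, tolerance=tolerance, rng=rng, stats=stats
        )
        rc = 0
        rl = 0
        for r in regions:
            p = pos.get(r.chrom, np.empty(0, dtype=np.int64))
            rc += int(np.searchsorted(p, r.end) - np.searchsorted(p, r.start))
            rl += r.length
        random_d.append(rc / rl)
    motif_d = np.asarray(motif_d)
    random_d = np.asarray(random_d)
    return GCMatchedTestResult(
        observed=float(observed),
        motif_densities=tuple(motif_d),
        random_densities=tuple(random_d),
        p_random_higher=float(np.mean(random_d > motif_d)),
        n_iter=n_iter,
        seed=seed,
        scope=scope,
    )
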