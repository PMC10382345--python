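"""Interval arithmetic shared by every analysis: densities, overlaps,
complements and GC content.

Everything that counts SNPs or measures length flattens (merges) its
interval set first, so duplicated promoters or opposite-strand motif
overlaps are never double counted.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import GenomicInterval, Promoter, SNPRecord


@dataclass(frozen=True)
class FeatureSet:
    """A named collection of intervals with optional per-interval metadata."""

    name: str
    intervals: tuple[GenomicInterval, ...]
    meta: pd.DataFrame | None = None

    @classmethod
    def from_promoters(cls, promoters: Sequence[Promoter], name: str = "prom500"):
        meta = pd.DataFrame(
            {
                "gene_id": [p.gene_id for p in promoters],
                "biotype": [p.biotype for p in promoters],
                "clipped": [p.clipped for p in promoters],
            }
        )
        return cls(name, tuple(p.interval for p in promoters), meta)

    def __len__(self) -> int:
        return len(self.intervals)

    def subset(self, mask: Sequence[bool], name: str | None = None) -> "FeatureSet":
        ivs = tuple(iv for iv, m in zip(self.intervals, mask) if m)
        meta = self.meta.loc[list(mask)].reset_index(drop=True) if self.meta is not None else None
        return FeatureSet(name or self.name, ivs, meta)


def _as_intervals(features) -> list[GenomicInterval]:
    if isinstance(features, FeatureSet):
        return list(features.intervals)
    out = []
    for f in features:
        out.append(f.interval if isinstance(f, Promoter) else f)
    return out


def merged_by_chrom(intervals: Iterable) -> dict[str, np.ndarray]:
    """Merge overlapping/adjacent-duplicated intervals per chromosome.

    Returns {chrom: (n, 2) int array}, sorted, disjoint.  Touching
    intervals ([0,5) and [5,8)) stay separate; they cover no shared base.
    """
    by: dict[str, list[tuple[int, int]]] = {}
    for iv in _as_intervals(intervals):
        by.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged: dict[str, np.ndarray] = {}
    for chrom, pairs in by.items():
        pairs.sort()
        out: list[list[int]] = []
        for s, e in pairs:
            if out and s < out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = np.asarray(out, dtype=np.int64)
    return merged


def merge_intervals(intervals: Iterable) -> list[GenomicInterval]:
    out = []
    for chrom in sorted(merged_by_chrom(intervals)):
        for s, e in merged_by_chrom(intervals)[chrom]:
            out.append(GenomicInterval(chrom, int(s), int(e)))
    return out


def total_flattened_length(intervals: Iterable) -> int:
    return int(
        sum((arr[:, 1] - arr[:, 0]).sum() for arr in merged_by_chrom(intervals).values())
    )


def snps_by_chrom(snps: Iterable[SNPRecord]) -> dict[str, np.ndarray]:
    by: dict[str, list[int]] = {}
    for s in snps:
        by.setdefault(s.chrom, []).append(s.pos)
    return {c: np.sort(np.asarray(p, dtype=np.int64)) for c, p in by.items()}


def _count_in_merged(merged: Mapping[str, np.ndarray], pos: Mapping[str, np.ndarray]) -> int:
    total = 0
    for chrom, arr in merged.items():
        p = pos.get(chrom)
        if p is None or len(p) == 0 or len(arr) == 0:
            continue
        total += int(
            (np.searchsorted(p, arr[:, 1], "left") - np.searchsorted(p, arr[:, 0], "left")).sum()
        )
    return total


def overlap_count(intervals: Iterable, snps) -> int:
    """Number of SNPs falling in the flattened interval set."""
    pos = snps if isinstance(snps, dict) else snps_by_chrom(snps)
    return _count_in_merged(merged_by_chrom(intervals), pos)


def snp_density(intervals: Iterable, snps) -> float:
    """SNPs per bp of the flattened interval set."""
    merged = merged_by_chrom(intervals)
    length = int(sum((a[:, 1] - a[:, 0]).sum() for a in merged.values()))
    if length == 0:
        raise ValueError("snp_density: total interval length is zero")
    pos = snps if isinstance(snps, dict) else snps_by_chrom(snps)
    return _count_in_merged(merged, pos) / length


def motif_density_per_kb(features, motifs: Sequence) -> float:
    """Motifs per kilobase of (flattened) feature length."""
    length = total_flattened_length(features)
    if length == 0:
        raise ValueError("motif_density_per_kb: zero total feature length")
    return 1000.0 * len(list(motifs)) / length


def assign_motifs(features, motifs: Iterable) -> dict[GenomicInterval, list]:
    """Assign each motif to every feature it overlaps by at least one base."""
    ivs = _as_intervals(features)
    out = {iv: [] for iv in ivs}
    by_chrom: dict[str, list] = {}
    for m in motifs:
        by_chrom.setdefault(m.chrom, []).append(m)
    for iv in ivs:
        for m in by_chrom.get(iv.chrom, []):
            if m.start < iv.end and m.end > iv.start:
                out[iv].append(m)
    return out


def fraction_with_motif(feature_motifs: Mapping) -> float:
    """Fraction of features carrying at least one motif.

    Takes the feature -> motifs mapping produced by ``scan_features`` or
    ``assign_motifs``.
    """
    if len(feature_motifs) == 0:
        raise ValueError("fraction_with_motif: empty feature set")
    return sum(1 for v in feature_motifs.values() if len(v) > 0) / len(feature_motifs)


def subtract_intervals(features, motifs) -> list[GenomicInterval]:
    """Motif-free sub-ranges of each feature.

    The returned ranges, together with the flattened motif-within-feature
    ranges, tile each feature exactly.
    """
    motif_ivs = [
        m.interval if hasattr(m, "interval") and not isinstance(m, GenomicInterval) else m
        for m in motifs
    ]
    merged = merged_by_chrom(motif_ivs) if motif_ivs else {}
    out: list[GenomicInterval] = []
    for f in _as_intervals(features):
        arr = merged.get(f.chrom)
        cursor = f.start
        if arr is not None and len(arr):
            lo = np.searchsorted(arr[:, 1], f.start, "right")
            hi = np.searchsorted(arr[:, 0], f.end, "left")
            for s, e in arr[lo:hi]:
                s, e = max(int(s), f.start), min(int(e), f.end)
                if s > cursor:
                    out.append(GenomicInterval(f.chrom, cursor, s, name=f.name))
                cursor = max(cursor, e)
        if cursor < f.end:
            out.append(GenomicInterval(f.chrom, cursor, f.end, name=f.name))
    return out


def gc_content(seq: str) -> float:
    """(G + C) / (length excluding N).  Empty or all-N input is an error."""
    if not seq:
        raise ValueError("gc_content: empty sequence")
    n = seq.count("N")
    denom = len(seq) - n
    if denom == 0:
        raise ValueError("gc_content: sequence is all N")
    return (seq.count("G") + seq.count("C")) / denom
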