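"""Synthetic genomes with known ground truth.

Emulates the inputs of the real analysis — a multi-chromosome genome,
strand-aware 500-nt promoter windows, 6-kb enhancer-RNA intervals,
canonical G4-motifs planted at configurable per-kb rates inside and
outside features, SNPs placed by class-dependent Bernoulli rates, and
gene-eRNA associations with a tunable G4 co-occurrence bias — so every
pipeline stage can be verified against a truth manifest.

Planted motifs are written with a non-G/non-C guard base on each flank
and kept more than one maximal loop length apart, so maximal-run parsing
can neither fuse a plant with its context nor chain two plants.  With
``scrub=True`` (the default) every maximal G-run and C-run of three or
more bases outside planted spans is broken, which makes the scanner's
output equal the truth manifest exactly.

Default rates are chosen to mimic the ovine study system: genome GC
0.42; promoter motif rate 1.0/kb (so ~40% of 500-bp promoters carry a
motif), eRNA rate 0.23/kb (~75% of 6-kb eRNAs carry one) with background
at the eRNA level; SNP rate 0.027/bp (~70M SNPs on a ~2.6 Gb genome),
mildly depleted on motifs and further on disruptive guanines.
"""
from __future__ import annotations

import bisect
import json
import logging
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .disruptive_sites import REQUIRED_RUNS, classify_motif_positions
from .g4_scanner import DEFAULT_PARAMS, G4Motif, G4Params, revcomp
from .genome_io import (
    GeneRecord,
    GenomicInterval,
    Promoter,
    SNPRecord,
    chrom_sizes,
    derive_prom500,
    write_bed,
    write_fasta,
    write_genes,
    write_snps_tsv,
    write_snps_vcf,
)
from .interval_stats import FeatureSet
from .randomization import rng_from

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults are the study conditions."""

    n_chrom: int = 5
    chrom_length: int = 400_000
    chrom_lengths: tuple[int, ...] | None = None
    gc: float = 0.42
    n_genes: int = 300
    biotype_mix: tuple[tuple[str, float], ...] = (
        ("protein_coding", 0.80),
        ("lncRNA", 0.15),
        ("other", 0.05),
    )
    n_ernas: int = 120
    erna_length: int = 6000
    promoter_length: int = 500
    motif_rate_background: float = 0.20  # motifs per kb outside features
    motif_rate_prom: float = 1.00
    motif_rate_erna: float = 0.23
    run_count_dist: tuple[tuple[int, float], ...] = ((4, 0.8), (5, 0.2))
    run_length_dist: tuple[tuple[int, float], ...] = (
        (3, 0.55),
        (4, 0.25),
        (5, 0.12),
        (6, 0.08),
    )
    loop_length_dist: tuple[tuple[int, float], ...] = tuple(
        (l, 1 / 12) for l in range(1, 13)
    )
    minus_strand_fraction: float = 0.5
    snp_rate_background: float = 0.027
    snp_rate_g4_multiplier: float = 0.8
    snp_rate_disruptive_multiplier: float = 0.75
    assoc_per_erna: tuple[int, int] = (1, 5)
    cooccurrence_bias: float = 0.15
    scrub: bool = True
    seed: int = 0

    def lengths(self) -> tuple[int, ...]:
        if self.chrom_lengths is not None:
            return tuple(self.chrom_lengths)
        return tuple([self.chrom_length] * self.n_chrom)

    def validate(self) -> None:
        errors = []
        for L in self.lengths():
            if L < 10_000:
                errors.append(f"chromosome length {L} < 10 kb")
        if not 0.0 < self.gc < 1.0:
            errors.append(f"gc {self.gc} outside (0, 1)")
        for name in (
            "motif_rate_background",
            "motif_rate_prom",
            "motif_rate_erna",
            "snp_rate_background",
            "snp_rate_g4_multiplier",
            "snp_rate_disruptive_multiplier",
        ):
            if getattr(self, name) < 0:
                errors.append(f"{name} must be >= 0")
        if not -1.0 <= self.cooccurrence_bias <= 1.0:
            errors.append("cooccurrence_bias outside [-1, 1]")
        lo, hi = self.assoc_per_erna
        if lo < 1 or hi < lo:
            errors.append("assoc_per_erna must be a range with lower bound >= 1")
        for dist_name in ("biotype_mix", "run_count_dist", "run_length_dist", "loop_length_dist"):
            probs = [p for _, p in getattr(self, dist_name)]
            if abs(sum(probs) - 1.0) > 1e-6 or any(p < 0 for p in probs):
                errors.append(f"{dist_name} is not a probability distribution")
        if errors:
            raise ConfigError("invalid config: " + "; ".join(errors))


@dataclass
class SyntheticTruth:
    """Ground truth of a generated dataset."""

    motifs: tuple[G4Motif, ...]
    motif_feature_ids: tuple[str | None, ...]
    snp_labels: pd.DataFrame  # chrom, pos (0-based), label
    prom_g4: dict[str, bool]
    erna_g4: dict[str, bool]
    bias: float


@dataclass
class SyntheticDataset:
    genome: dict[str, str]
    genes: list[GeneRecord]
    promoters: list[Promoter]
    ernas: list[GenomicInterval]
    snps: list[SNPRecord]
    associations: pd.DataFrame
    truth: SyntheticTruth
    config: SyntheticConfig

    @property
    def prom500(self) -> FeatureSet:
        return FeatureSet.from_promoters(self.promoters)

    @property
    def erna_set(self) -> FeatureSet:
        return FeatureSet("eRNA", tuple(self.ernas))


def _draw(dist: Sequence[tuple], rng: np.random.Generator):
    vals = [v for v, _ in dist]
    probs = np.array([p for _, p in dist], dtype=float)
    return vals[int(rng.choice(len(vals), p=probs / probs.sum()))]


def generate_genome(config: SyntheticConfig) -> dict[str, str]:
    """IID base draws with the configured GC; byte-identical for a seed."""
    config.validate()
    rng = rng_from(config.seed, "genome")
    p = np.array(
        [(1 - config.gc) / 2, config.gc / 2, config.gc / 2, (1 - config.gc) / 2]
    )
    genome = {}
    for i, L in enumerate(config.lengths(), 1):
        idx = rng.choice(4, size=L, p=p)
        genome[f"chr{i}"] = _BASES[idx].tobytes().decode("ascii")
    return genome


# ---------------------------------------------------------------------------
# feature placement


def _place_features(
    config: SyntheticConfig, sizes: Mapping[str, int], rng: np.random.Generator
) -> tuple[list[GeneRecord], list[GenomicInterval]]:
    """Non-overlapping promoter blocks and eRNA intervals on each chromosome."""
    chroms = list(sizes)
    weights = np.array([sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    min_gap = 200
    items: list[tuple[str, str]] = [("gene", f"g{i:05d}") for i in range(config.n_genes)]
    items += [("erna", f"e{i:05d}") for i in range(config.n_ernas)]
    chrom_of = [chroms[int(k)] for k in rng.choice(len(chroms), size=len(items), p=weights)]

    biotypes = [b for b, _ in config.biotype_mix]
    bprobs = np.array([p for _, p in config.biotype_mix])
    genes: list[GeneRecord] = []
    ernas: list[GenomicInterval] = []
    for chrom in chroms:
        mine = [it for it, c in zip(items, chrom_of) if c == chrom]
        rng.shuffle(mine)
        blocks = [
            (config.promoter_length + 2 if kind == "gene" else config.erna_length)
            for kind, _ in mine
        ]
        need = sum(blocks) + (len(mine) + 1) * min_gap
        if need > sizes[chrom]:
            raise ConfigError(
                f"features do not fit on {chrom}: need {need} bp of {sizes[chrom]}"
            )
        slack = sizes[chrom] - need
        cuts = np.sort(rng.integers(0, slack + 1, size=len(mine)))
        extra = np.diff(np.concatenate([[0], cuts]))
        cursor = min_gap
        for (kind, ident), block, ex in zip(mine, blocks, extra):
            cursor += int(ex)
            start = cursor
            if kind == "gene":
                strand = "+" if rng.random() < 0.5 else "-"
                # promoter window occupies [start+1, start+1+plen)
                if strand == "+":
                    tss = start + 1 + config.promoter_length
                else:
                    tss = start
                genes.append(
                    GeneRecord(
                        gene_id=ident,
                        chrom=chrom,
                        tss=tss,
                        strand=strand,
                        biotype=biotypes[int(rng.choice(len(biotypes), p=bprobs))],
                        name=ident,
                    )
                )
            else:
                ernas.append(
                    GenomicInterval(chrom, start, start + config.erna_length, ".", ident)
                )
            cursor += block + min_gap
    genes.sort(key=lambda g: (g.chrom, g.tss))
    ernas.sort(key=lambda e: (e.chrom, e.start))
    return genes, ernas


# ---------------------------------------------------------------------------
# motif planting


def build_motif_sequence(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[str, tuple[int, ...], tuple[int, ...]]:
    """One motif-strand sequence plus its run/loop length layout.

    Loop bases are drawn from {A, C, T} with no three consecutive C's, so
    a loop can never host or extend a qualifying run on either strand.
    """
    n_runs = _draw(config.run_count_dist, rng)
    run_lengths = tuple(_draw(config.run_length_dist, rng) for _ in range(n_runs))
    loop_lengths = tuple(_draw(config.loop_length_dist, rng) for _ in range(n_runs - 1))
    parts = []
    for k, rl in enumerate(run_lengths):
        parts.append("G" * rl)
        if k < n_runs - 1:
            loop = []
            c_run = 0
            for _ in range(loop_lengths[k]):
                choices = "ACT" if c_run < 2 else "AT"
                b = choices[int(rng.integers(0, len(choices)))]
                c_run = c_run + 1 if b == "C" else 0
                loop.append(b)
            parts.append("".join(loop))
    return "".join(parts), run_lengths, loop_lengths


def _layout_to_motif(
    chrom: str,
    start: int,
    strand: str,
    seq: str,
    run_lengths: tuple[int, ...],
    loop_lengths: tuple[int, ...],
) -> G4Motif:
    """Truth G4Motif for a planted sequence written at ``start``."""
    offs = []
    off = 0
    for k, rl in enumerate(run_lengths):
        offs.append((off, off + rl))
        off += rl + (loop_lengths[k] if k < len(run_lengths) - 1 else 0)
    L = len(seq)
    if strand == "+":
        g_runs = tuple((start + a, start + b) for a, b in offs)
        loops = loop_lengths
    else:
        g_runs = tuple((start + L - b, start + L - a) for a, b in reversed(offs))
        loops = loop_lengths[::-1]
    return G4Motif(
        start=start,
        end=start + L,
        strand=strand,
        g_runs=g_runs,
        loop_lengths=loops,
        n_runs=len(run_lengths),
        sequence=seq,
        chrom=chrom,
    )


class _Occupancy:
    """Sorted non-overlapping reserved spans per chromosome."""

    def __init__(self) -> None:
        self.spans: dict[str, list[tuple[int, int]]] = {}

    def conflicts(self, chrom: str, start: int, end: int) -> bool:
        spans = self.spans.setdefault(chrom, [])
        i = bisect.bisect_left(spans, (start, start))
        if i > 0 and spans[i - 1][1] > start:
            return True
        return i < len(spans) and spans[i][0] < end

    def reserve(self, chrom: str, start: int, end: int) -> None:
        bisect.insort(self.spans.setdefault(chrom, []), (start, end))


def _plant_in_region(
    arrays: dict[str, np.ndarray],
    region: GenomicInterval,
    config: SyntheticConfig,
    rng: np.random.Generator,
    occupied: _Occupancy,
    params: G4Params = DEFAULT_PARAMS,
    max_tries: int = 50,
    avoid: _Occupancy | None = None,
) -> G4Motif | None:
    seq, run_lengths, loop_lengths = build_motif_sequence(config, rng)
    L = len(seq)
    # guard base on each flank, and a buffer > max_loop so plants cannot chain
    buffer = params.max_loop + 1
    if region.length < L + 2:
        log.info("plant skipped: feature %s too small for a %d bp motif", region.name, L)
        return None
    strand = "-" if rng.random() < config.minus_strand_fraction else "+"
    written = revcomp(seq) if strand == "-" else seq
    for _ in range(max_tries):
        s = int(rng.integers(region.start + 1, region.end - L))
        if occupied.conflicts(region.chrom, s - 1 - buffer, s + L + 1 + buffer):
            continue
        if avoid is not None and avoid.conflicts(region.chrom, s - 1 - buffer, s + L + 1 + buffer):
            continue
        arr = arrays[region.chrom]
        guard = _BASES[[0, 3]]  # A or T
        arr[s - 1] = guard[int(rng.integers(0, 2))]
        arr[s + L] = guard[int(rng.integers(0, 2))]
        arr[s : s + L] = np.frombuffer(written.encode("ascii"), dtype=np.uint8)
        occupied.reserve(region.chrom, s - 1 - buffer, s + L + 1 + buffer)
        return _layout_to_motif(region.chrom, s, strand, seq, run_lengths, loop_lengths)
    log.info("plant skipped: no free position in %s after %d tries", region.name, max_tries)
    return None


def plant_motifs(
    genome: Mapping[str, str],
    features: Sequence[GenomicInterval],
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    *,
    rate_per_kb: float | None = None,
    n_motifs: int | None = None,
) -> tuple[dict[str, str], list[G4Motif]]:
    """Plant motifs into the given regions; standalone convenience wrapper.

    Either a Poisson ``rate_per_kb`` per region or an exact total
    ``n_motifs`` (spread over regions by length) must be given.  Applies
    scrubbing per ``config.scrub``.
    """
    if rng is None:
        rng = rng_from(config.seed, "plant")
    arrays = {c: np.frombuffer(s.encode("ascii"), dtype=np.uint8).copy() for c, s in genome.items()}
    occupied = _Occupancy()
    planted: list[G4Motif] = []
    if n_motifs is not None:
        lengths = np.array([f.length for f in features], dtype=float)
        choices = rng.choice(len(features), size=n_motifs, p=lengths / lengths.sum())
        counts = np.bincount(choices, minlength=len(features))
    elif rate_per_kb is not None:
        counts = rng.poisson([rate_per_kb * f.length / 1000 for f in features])
    else:
        raise ValueError("plant_motifs: give rate_per_kb or n_motifs")
    for f, k in zip(features, counts):
        for _ in range(int(k)):
            m = _plant_in_region(arrays, f, config, rng, occupied)
            if m is not None:
                planted.append(m)
    if config.scrub:
        scrub_background(arrays, planted, rng)
    out = {c: a.tobytes().decode("ascii") for c, a in arrays.items()}
    planted.sort(key=lambda m: (m.chrom, m.start))
    return out, planted


_SCRUB_RE = re.compile(rb"GGG+|CCC+")


def scrub_background(
    arrays: dict[str, np.ndarray],
    planted: Sequence[G4Motif],
    rng: np.random.Generator,
) -> None:
    """Break every qualifying G/C run outside planted spans (in place).

    Mutating every third base of a run to A/T caps surviving sub-runs at
    two bases, so the background can contribute no qualifying run on
    either strand and the scanner's output equals the planted truth.
    """
    spans: dict[str, list[tuple[int, int]]] = {}
    for m in planted:
        spans.setdefault(m.chrom, []).append((m.start, m.end))
    for v in spans.values():
        v.sort()
    guard = _BASES[[0, 3]]
    for chrom, arr in arrays.items():
        starts = [s for s, _ in spans.get(chrom, [])]
        ends = [e for _, e in spans.get(chrom, [])]
        data = arr.tobytes()
        for match in _SCRUB_RE.finditer(data):
            s, e = match.span()
            # runs cannot cross a guard base, so they are either fully
            # inside a planted motif or fully outside
            i = bisect.bisect_right(starts, s) - 1
            if i >= 0 and ends[i] > s:
                continue
            for p in range(s + 2, e, 3):
                arr[p] = guard[int(rng.integers(0, 2))]


# ---------------------------------------------------------------------------
# SNPs

_LABELS = ("background", "g4_non_disruptive", "g4_disruptive")


def generate_snps(
    genome: Mapping[str, str],
    planted: Sequence[G4Motif],
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[SNPRecord], pd.DataFrame]:
    """Per-position Bernoulli SNPs with class-dependent rates.

    Rate = background x (G4 multiplier inside a planted motif) x
    (disruptive multiplier on disruptive positions of four-run motifs).
    Returns the SNPs and a label table aligned with them.
    """
    if rng is None:
        rng = rng_from(config.seed, "snps")
    snps: list[SNPRecord] = []
    labels: list[str] = []
    by_chrom: dict[str, list[G4Motif]] = {}
    for m in planted:
        by_chrom.setdefault(m.chrom, []).append(m)
    counter = 0
    for chrom in genome:
        seq = genome[chrom]
        L = len(seq)
        rate = np.full(L, config.snp_rate_background)
        label = np.zeros(L, dtype=np.uint8)
        for m in by_chrom.get(chrom, []):
            rate[m.start : m.end] *= config.snp_rate_g4_multiplier
            label[m.start : m.end] = 1
            if m.n_runs == REQUIRED_RUNS:
                ann = classify_motif_positions(m)
                idx = np.fromiter(ann.disruptive_positions, dtype=np.int64)
                rate[idx] *= config.snp_rate_disruptive_multiplier
                label[idx] = 2
        hits = np.flatnonzero(rng.random(L) < rate)
        for p in hits:
            p = int(p)
            ref = seq[p]
            alts = [b for b in "ACGT" if b != ref]
            alt = alts[int(rng.integers(0, len(alts)))] if ref in "ACGT" else "A"
            snps.append(SNPRecord(chrom, p, f"s{counter:07d}", ref if ref in "ACGT" else None, alt))
            labels.append(_LABELS[label[p]])
            counter += 1
    table = pd.DataFrame(
        {
            "chrom": [s.chrom for s in snps],
            "pos": [s.pos for s in snps],
            "label": labels,
        }
    )
    return snps, table


# ---------------------------------------------------------------------------
# associations


def generate_associations(
    prom_g4: Mapping[str, bool],
    erna_g4: Mapping[str, bool],
    bias: float,
    assoc_per_erna: tuple[int, int] = (1, 5),
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene-eRNA links with a planted co-occurrence bias.

    With q the marginal promoter-G4 frequency and f the eRNA-G4
    frequency, partners of a G4-bearing eRNA are G4-positive promoters
    with probability q_plus = q + b(1 - f), and partners of a G4-free
    eRNA with q_minus = q_plus - b, so the conditional difference equals
    ``bias`` in expectation while the overall marginal stays near q.
    """
    if rng is None:
        rng = rng_from(seed, "assoc")
    lo, hi = assoc_per_erna
    if lo < 1:
        raise ValueError("assoc_per_erna must be >= 1")
    if not prom_g4 or not erna_g4:
        return pd.DataFrame(columns=["gene_id", "erna_id"])
    genes = np.array(list(prom_g4))
    flags = np.array([bool(prom_g4[g]) for g in genes])
    pos_pool = genes[flags]
    neg_pool = genes[~flags]
    q = float(flags.mean())
    f = float(np.mean([bool(v) for v in erna_g4.values()])) if erna_g4 else 0.0
    q_minus = q - bias * f
    q_plus = q_minus + bias
    if not (0.0 <= q_minus <= 1.0 and 0.0 <= q_plus <= 1.0):
        b_lo = max(-q / f if f else -np.inf, (q - 1) / f if f else -np.inf)
        b_hi = min(q / (1 - f) if f < 1 else np.inf, (1 - q) / (1 - f) if f < 1 else np.inf)
        raise ValueError(
            f"infeasible bias {bias} for marginals q={q:.3f}, f={f:.3f}; "
            f"feasible range is [{b_lo:.3f}, {b_hi:.3f}]"
        )
    rows = []
    for erna_id in erna_g4:
        k = int(rng.integers(lo, hi + 1))
        qs = q_plus if erna_g4[erna_id] else q_minus
        n_pos = min(int(rng.binomial(k, qs)), len(pos_pool))
        n_neg = min(k - n_pos, len(neg_pool))
        chosen = []
        if n_pos:
            chosen += list(rng.choice(pos_pool, size=n_pos, replace=False))
        if n_neg:
            chosen += list(rng.choice(neg_pool, size=n_neg, replace=False))
        for gid in chosen:
            rows.append({"gene_id": gid, "erna_id": erna_id})
    return pd.DataFrame(rows, columns=["gene_id", "erna_id"])


# ---------------------------------------------------------------------------
# orchestration


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a complete dataset with ground truth from one config."""
    config.validate()
    genome = generate_genome(config)
    sizes = chrom_sizes(genome)
    rng_feat = rng_from(config.seed, "features")
    genes, ernas = _place_features(config, sizes, rng_feat)
    promoters = derive_prom500(genes, sizes, window=config.promoter_length)

    arrays = {
        c: np.frombuffer(s.encode("ascii"), dtype=np.uint8).copy()
        for c, s in genome.items()
    }
    occupied = _Occupancy()
    rng_plant = rng_from(config.seed, "motifs")
    planted: list[G4Motif] = []
    feature_ids: list[str | None] = []

    def _plant_set(regions: Iterable[GenomicInterval], rate: float) -> None:
        for region in regions:
            k = rng_plant.poisson(rate * region.length / 1000)
            for _ in range(int(k)):
                m = _plant_in_region(arrays, region, config, rng_plant, occupied)
                if m is not None:
                    planted.append(m)
                    feature_ids.append(region.name)

    _plant_set((p.interval for p in promoters), config.motif_rate_prom)
    _plant_set(ernas, config.motif_rate_erna)

    # background motifs go anywhere outside the features themselves
    feature_spans = _Occupancy()
    for p in promoters:
        feature_spans.reserve(p.interval.chrom, p.interval.start, p.interval.end)
    for e in ernas:
        feature_spans.reserve(e.chrom, e.start, e.end)
    for chrom, L in sizes.items():
        span = GenomicInterval(chrom, 0, L, name=None)
        k = rng_plant.poisson(config.motif_rate_background * L / 1000)
        for _ in range(int(k)):
            m = _plant_in_region(
                arrays, span, config, rng_plant, occupied, avoid=feature_spans
            )
            if m is not None:
                planted.append(m)
                feature_ids.append(None)

    rng_scrub = rng_from(config.seed, "scrub")
    if config.scrub:
        scrub_background(arrays, planted, rng_scrub)
    genome2 = {c: a.tobytes().decode("ascii") for c, a in arrays.items()}

    prom_ids_with = {fid for fid in feature_ids if fid and fid.startswith("g")}
    erna_ids_with = {fid for fid in feature_ids if fid and fid.startswith("e")}
    prom_g4 = {p.gene_id: p.gene_id in prom_ids_with for p in promoters}
    erna_g4 = {e.name: e.name in erna_ids_with for e in ernas}

    rng_snp = rng_from(config.seed, "snps")
    snps, snp_labels = generate_snps(genome2, planted, config, rng_snp)

    rng_assoc = rng_from(config.seed, "assoc")
    associations = generate_associations(
        prom_g4, erna_g4, config.cooccurrence_bias, config.assoc_per_erna, rng_assoc
    )

    truth = SyntheticTruth(
        motifs=tuple(planted),
        motif_feature_ids=tuple(feature_ids),
        snp_labels=snp_labels,
        prom_g4=prom_g4,
        erna_g4=erna_g4,
        bias=config.cooccurrence_bias,
    )
    return SyntheticDataset(
        genome=genome2,
        genes=genes,
        promoters=promoters,
        ernas=ernas,
        snps=snps,
        associations=associations,
        truth=truth,
        config=config,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Emit all standard-format files plus the truth manifest JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sizes = chrom_sizes(ds.genome)
    paths = {
        "fasta": outdir / "genome.fa",
        "genes": outdir / "genes.tsv",
        "prom500": outdir / "prom500.bed",
        "ernas": outdir / "ernas.bed",
        "vcf": outdir / "snps.vcf",
        "snps_tsv": outdir / "snps.tsv",
        "associations": outdir / "associations.tsv",
        "truth": outdir / "truth.json",
    }
    write_fasta(ds.genome, paths["fasta"])
    write_genes(ds.genes, paths["genes"])
    write_bed((p.interval for p in ds.promoters), paths["prom500"])
    write_bed(ds.ernas, paths["ernas"])
    write_snps_vcf(ds.snps, sizes, paths["vcf"])
    write_snps_tsv(ds.snps, paths["snps_tsv"])
    ds.associations.to_csv(paths["associations"], sep="\t", index=False)
    manifest = {
        "bias": ds.truth.bias,
        "motifs": [
            {
                "chrom": m.chrom,
                "start": m.start,
                "end": m.end,
                "strand": m.strand,
                "g_runs": [list(r) for r in m.g_runs],
                "loop_lengths": list(m.loop_lengths),
                "n_runs": m.n_runs,
                "sequence": m.sequence,
                "feature_id": fid,
            }
            for m, fid in zip(ds.truth.motifs, ds.truth.motif_feature_ids)
        ],
        "snp_labels": ds.truth.snp_labels.to_dict(orient="list"),
        "prom_g4": ds.truth.prom_g4,
        "erna_g4": ds.truth.erna_g4,
    }
    with open(paths["truth"], "w") as fh:
        json.dump(manifest, fh)
    return paths


def read_truth(path: str | Path) -> SyntheticTruth:
    with open(path) as fh:
        manifest = json.load(fh)
    motifs = tuple(
        G4Motif(
            start=m["start"],
            end=m["end"],
            strand=m["strand"],
            g_runs=tuple(tuple(r) for r in m["g_runs"]),
            loop_lengths=tuple(m["loop_lengths"]),
            n_runs=m["n_runs"],
            sequence=m["sequence"],
            chrom=m["chrom"],
        )
        for m in manifest["motifs"]
    )
    return SyntheticTruth(
        motifs=motifs,
        motif_feature_ids=tuple(m["feature_id"] for m in manifest["motifs"]),
        snp_labels=pd.DataFrame(manifest["snp_labels"]),
        prom_g4={k: bool(v) for k, v in manifest["prom_g4"].items()},
        erna_g4={k: bool(v) for k, v in manifest["erna_g4"].items()},
        bias=manifest["bias"],
    )
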