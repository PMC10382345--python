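"""Study designs shared by the acceptance tests and the acceptance script.

Each function runs one validation experiment end to end — generating its
inputs, running the package, and measuring the outcome — and returns
plain numbers.  All randomness derives from the given root seed.
"""
from __future__ import annotations

import numpy as np

from regg4.g4_scanner import scan_both_strands, scan_features, scan_sequence
from regg4.genome_io import GenomicInterval, SNPRecord
from regg4.disruptive_sites import disruptive_snp_ratio
from regg4.interaction_analysis import (
    flag_features,
    per_erna_promoter_g4_ratio,
    rank_sum_test,
)
from regg4.interval_stats import FeatureSet
from regg4.randomization import (
    rng_from,
    run_density_enrichment,
    run_snp_density_test,
    sample_length_matched,
)
from regg4.synthetic_data import (
    SyntheticConfig,
    generate_associations,
    generate_dataset,
    generate_genome,
    plant_motifs,
)

from .oracles import brute_force_scan, random_sequence


def oracle_agreement(seed: int, n_seqs: int = 1000) -> float:
    """Fraction of random sequences where the scanner equals brute force."""
    rng = rng_from(seed, "oracle")
    agree = 0
    for _ in range(n_seqs):
        length = int(rng.integers(30, 301))
        gc = float(rng.uniform(0.3, 0.7))
        seq = random_sequence(rng, length, gc)
        got = [(m.start, m.end) for m in scan_sequence(seq)]
        agree += got == brute_force_scan(seq)
    return agree / n_seqs


def planted_recovery(seed: int, genome_len: int = 1_000_000, n_motifs: int = 200):
    """(precision, recall, n_planted) of scanning a scrubbed planted genome."""
    cfg = SyntheticConfig(
        n_chrom=1, chrom_length=genome_len, seed=int(rng_from(seed, "plant").integers(2**31))
    )
    genome = generate_genome(cfg)
    genome2, planted = plant_motifs(
        genome, [GenomicInterval("chr1", 0, genome_len)], cfg, n_motifs=n_motifs
    )
    found = []
    for c, s in genome2.items():
        found += scan_both_strands(c, s)
    truth = {m.key() for m in planted}
    got = {m.key() for m in found}
    precision = len(got & truth) / len(got) if got else 0.0
    recall = len(got & truth) / len(truth)
    return precision, recall, len(planted)


def disruptive_closed_form_agreement(seed: int, n_motifs: int = 10_000) -> float:
    """Fraction of random four-run motifs whose disruptive count equals
    the closed form sum of f(run length)."""
    from regg4.disruptive_sites import classify_motif_positions

    from .conftest import random_4run_motif
    from .oracles import disruptive_count_closed_form

    rng = rng_from(seed, "disruptive")
    agree = 0
    for _ in range(n_motifs):
        m = random_4run_motif(rng, start=int(rng.integers(0, 10_000)))
        ann = classify_motif_positions(m)
        agree += len(ann.disruptive_positions) == disruptive_count_closed_form(
            m.run_lengths
        )
    return agree / n_motifs


# ---------------------------------------------------------------------------
# calibration designs: no planted effect, p values should be uniform.
# Each replicate gets its own genome (and SNP field), so replicate p
# values are independent; the genome carries background motifs dense
# enough that the per-iteration count statistic is effectively
# continuous — a near-empty statistic would be degenerate by ties.

_CAL_DENSITY = dict(
    genome_len=200_000,
    motif_rate=1.2,  # per kb; ~38 expected motifs per replicate
    n_windows=40,
    window_len_range=(500, 1200),  # heterogeneous lengths keep the pooled
    n_iter=100,                    # density statistic effectively tie-free
)


def density_calibration(seed: int, n_reps: int = 200) -> np.ndarray:
    d = _CAL_DENSITY
    pvals = []
    for rep in range(n_reps):
        cfg = SyntheticConfig(
            n_chrom=1,
            chrom_length=d["genome_len"],
            motif_rate_background=d["motif_rate"],
            seed=int(rng_from(seed, "cal-genome", rep).integers(2**31)),
        )
        genome = generate_genome(cfg)
        genome, _ = plant_motifs(
            genome,
            [GenomicInterval("chr1", 0, d["genome_len"])],
            cfg,
            rate_per_kb=d["motif_rate"],
        )
        rng = rng_from(seed, "cal-density", rep)
        # windows must not overlap one another: the observed statistic
        # flattens its denominator, so overlapping windows would double
        # count motifs relative to the pooled null
        windows: list[GenomicInterval] = []
        while len(windows) < d["n_windows"]:
            length = int(rng.integers(*d["window_len_range"]))
            (w,) = sample_length_matched(genome, [length], rng=rng)
            if all(w.end <= v.start or w.start >= v.end for v in windows):
                windows.append(w)
        res = run_density_enrichment(
            windows,
            genome,
            n_iter=d["n_iter"],
            n_sample=d["n_windows"],
            seed=int(rng.integers(2**31)),
        )
        pvals.append(res.p_higher)
    return np.asarray(pvals)


def snp_calibration(seed: int, n_reps: int = 200) -> np.ndarray:
    rng = rng_from(seed, "cal-snp-genome")
    genome = {c: random_sequence(rng, 100_000, 0.42) for c in ("chr1", "chr2")}
    pvals = []
    for rep in range(n_reps):
        r = rng_from(seed, "cal-snp", rep)
        snps = [
            SNPRecord(c, int(p))
            for c in genome
            for p in np.flatnonzero(r.random(100_000) < 0.01)
        ]
        targets = sample_length_matched(genome, [1000] * 20, rng=r, chrom="chr1")
        (res,) = run_snp_density_test(
            targets, genome, snps, n_iter=200, seed=int(r.integers(2**31))
        )
        pvals.append(res.p_higher)
    return np.asarray(pvals)


# ---------------------------------------------------------------------------
# power designs


def motif_enrichment_power(seed: int, n_reps: int = 100, enrichment: float = 3.0):
    """Fraction of replicates detecting promoter motif enrichment.

    Promoters carry motifs at ``enrichment`` times the background rate.
    """
    hits = 0
    for rep in range(n_reps):
        cfg = SyntheticConfig(
            n_chrom=1,
            chrom_length=300_000,
            n_genes=150,
            n_ernas=0,
            motif_rate_background=0.2,
            motif_rate_prom=0.2 * enrichment,
            seed=int(rng_from(seed, "power-motif", rep).integers(2**31)),
        )
        ds = generate_dataset(cfg)
        res = run_density_enrichment(
            ds.prom500,
            ds.genome,
            n_iter=100,
            n_sample=150,
            seed=int(rng_from(seed, "power-motif-null", rep).integers(2**31)),
        )
        hits += res.p_higher <= 0.05
    return hits / n_reps


def snp_depletion_power(seed: int, n_chroms: int = 10):
    """Fraction of chromosomes where halved target SNP density is detected.

    Per chromosome: 50 kb of 1-kb targets, background 0.01 SNPs/bp,
    in-target rate 0.005/bp, 1,000 randomization iterations.
    """
    rng = rng_from(seed, "power-snp")
    L = 150_000
    genome = {}
    targets = []
    snps = []
    for i in range(1, n_chroms + 1):
        chrom = f"chr{i}"
        genome[chrom] = random_sequence(rng, L, 0.42)
        chrom_targets = [
            GenomicInterval(chrom, 1000 + 2500 * k, 2000 + 2500 * k) for k in range(50)
        ]
        targets += chrom_targets
        rate = np.full(L, 0.01)
        for t in chrom_targets:
            rate[t.start : t.end] = 0.005
        snps += [SNPRecord(chrom, int(p)) for p in np.flatnonzero(rng.random(L) < rate)]
    results = run_snp_density_test(
        targets, genome, snps, n_iter=1000, per_chrom=True,
        seed=int(rng.integers(2**31)),
    )
    detected = sum(r.p_lower <= 0.05 for r in results)
    return detected / len(results)


# ---------------------------------------------------------------------------
# parameter recovery designs


def disruptive_ratio_recovery(seed: int, multiplier: float = 0.5):
    """(recovered ratio, number of G-run positions) with a planted
    disruptive SNP-rate multiplier."""
    cfg = SyntheticConfig(
        n_chrom=2,
        chrom_length=2_200_000,
        n_genes=0,
        n_ernas=600,
        motif_rate_background=0.0,
        motif_rate_erna=1.0,
        run_count_dist=((4, 1.0),),
        snp_rate_g4_multiplier=1.0,
        snp_rate_disruptive_multiplier=multiplier,
        cooccurrence_bias=0.0,
        seed=int(rng_from(seed, "disr-recovery").integers(2**31)),
    )
    ds = generate_dataset(cfg)
    df = disruptive_snp_ratio(list(ds.truth.motifs), ds.snps, by_chrom=False)
    n_positions = int(df.n_disruptive_pos.iloc[0] + df.n_nondisruptive_pos.iloc[0])
    return float(df.ratio.iloc[0]), n_positions


def bias_recovery_end_to_end(seed: int, bias: float = 0.3):
    """(recovered conditional difference, rank-sum p) at 2,000 eRNAs,
    with G4 flags derived from the scanner rather than the truth."""
    cfg = SyntheticConfig(
        n_chrom=4,
        chrom_length=4_000_000,
        n_genes=3000,
        n_ernas=2000,
        cooccurrence_bias=bias,
        snp_rate_background=0.005,
        seed=int(rng_from(seed, "bias-recovery").integers(2**31)),
    )
    ds = generate_dataset(cfg)
    prom_ivs = [p.interval for p in ds.promoters]
    prom_motifs = [m for v in scan_features(prom_ivs, ds.genome).values() for m in v]
    erna_motifs = [m for v in scan_features(ds.ernas, ds.genome).values() for m in v]
    samples = per_erna_promoter_g4_ratio(
        ds.associations,
        flag_features(prom_ivs, prom_motifs),
        flag_features(ds.ernas, erna_motifs),
    )
    diff = float(np.mean(samples.with_g4) - np.mean(samples.without_g4))
    return diff, rank_sum_test(samples.with_g4, samples.without_g4)


def ranksum_replicates(seed: int, bias: float, n_reps: int, n_ernas: int,
                       n_genes: int = 600) -> np.ndarray:
    """Rank-sum p values over replicated association simulations."""
    pvals = []
    for rep in range(n_reps):
        rng = rng_from(seed, "ranksum", int(bias * 1000), rep)
        prom = {f"g{i}": bool(rng.random() < 0.4) for i in range(n_genes)}
        erna = {f"e{i}": bool(rng.random() < 0.5) for i in range(n_ernas)}
        assoc = generate_associations(prom, erna, bias, rng=rng)
        s = per_erna_promoter_g4_ratio(assoc, prom, erna)
        if len(s.with_g4) == 0 or len(s.without_g4) == 0:
            continue
        pvals.append(rank_sum_test(s.with_g4, s.without_g4))
    return np.asarray(pvals)
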