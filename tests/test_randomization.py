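from __future__ import annotations

import numpy as np
import pytest

from regg4.genome_io import GenomicInterval, SNPRecord
from regg4.interval_stats import gc_content
from regg4.randomization import (
    DensityTestResult,
    GenomeStats,
    empirical_p,
    format_p,
    rng_from,
    run_density_enrichment,
    run_gc_matched_snp_test,
    run_snp_density_test,
    sample_gc_matched,
    sample_length_matched,
    significance_stars,
)

from .oracles import random_sequence


@pytest.fixture(scope="module")
def uniform_genome():
    rng = np.random.default_rng(11)
    return {f"chr{i}": random_sequence(rng, 60_000, 0.5) for i in (1, 2)}


class TestEmpiricalP:
    def test_observed_above_all(self):
        p_hi, p_lo = empirical_p(1000.0, list(range(500)))
        assert p_hi == 0.0 and p_lo == 1.0

    def test_all_ties(self):
        assert empirical_p(2.0, [2.0] * 7) == (1.0, 1.0)

    def test_counting(self):
        assert empirical_p(2.5, [1, 2, 3, 4]) == (0.5, 0.5)

    def test_empty_error(self):
        with pytest.raises(ValueError):
            empirical_p(1.0, [])

    def test_tails_sum_to_at_least_one(self, rng):
        for _ in range(50):
            null = rng.integers(0, 5, size=20).tolist()
            obs = float(rng.integers(0, 5))
            p_hi, p_lo = empirical_p(obs, null)
            assert p_hi + p_lo >= 1.0

    def test_zero_formatted_as_bound(self):
        assert format_p(0.0, 500) == "< 0.002"
        assert format_p(0.25, 500) == "0.25"

    def test_stars(self):
        assert [significance_stars(p) for p in (0.0005, 0.005, 0.04, 0.5)] == [
            "***",
            "**",
            "*",
            "NS",
        ]


class TestLengthMatchedSampler:
    def test_deterministic_for_seed(self, uniform_genome):
        a = sample_length_matched(uniform_genome, [100, 200, 300], seed=5)
        b = sample_length_matched(uniform_genome, [100, 200, 300], seed=5)
        assert a == b

    def test_lengths_respected_and_in_bounds(self, uniform_genome):
        out = sample_length_matched(uniform_genome, [100] * 50 + [5000] * 5, seed=1)
        sizes = {c: len(s) for c, s in uniform_genome.items()}
        for iv, L in zip(out, [100] * 50 + [5000] * 5):
            assert iv.length == L
            assert 0 <= iv.start and iv.end <= sizes[iv.chrom]

    def test_oversized_length_error(self, uniform_genome):
        with pytest.raises(ValueError):
            sample_length_matched(uniform_genome, [10**7], seed=0)

    def test_empty_request(self, uniform_genome):
        assert sample_length_matched(uniform_genome, [], seed=0) == []

    def test_chrom_restriction(self, uniform_genome):
        out = sample_length_matched(uniform_genome, [100] * 20, seed=3, chrom="chr2")
        assert all(iv.chrom == "chr2" for iv in out)

    def test_n_rich_regions_rejected(self):
        genome = {"chrN": "N" * 5_000 + "ACGT" * 2_500}
        out = sample_length_matched(genome, [500] * 30, seed=2)
        stats = GenomeStats(genome)
        for iv in out:
            assert float(stats.n_fraction(iv.chrom, [iv.start], [iv.end])[0]) <= 0.5


class TestGcMatchedSampler:
    def test_within_tolerance_on_uniform_genome(self, uniform_genome):
        templates = [(200, 0.5)] * 30
        out = sample_gc_matched(uniform_genome, templates, seed=4)
        for iv in out:
            gc = gc_content(uniform_genome[iv.chrom][iv.start : iv.end])
            assert abs(gc - 0.5) <= 0.02

    def test_impossible_target_is_error(self):
        genome = {"chrAT": "AT" * 10_000}
        with pytest.raises(ValueError, match="no region matching"):
            sample_gc_matched(genome, [(100, 0.95)], seed=0, max_draws_at_cap=3000)

    def test_reproducible(self, uniform_genome):
        a = sample_gc_matched(uniform_genome, [(150, 0.48)] * 5, seed=9)
        assert a == sample_gc_matched(uniform_genome, [(150, 0.48)] * 5, seed=9)


class TestDensityEnrichment:
    def test_zero_g_genome(self):
        genome = {"chr1": "ACT" * 20_000}
        res = run_density_enrichment(
            [GenomicInterval("chr1", 0, 500)], genome, n_iter=20, n_sample=5, seed=0
        )
        assert res.observed == 0.0 and res.p_higher == 1.0

    def test_enriched_features_detected(self, uniform_genome):
        motif = "GGGTGGGTGGGTGGG"
        genome = dict(uniform_genome)
        seq = list(genome["chr1"])
        features = []
        for k in range(30):
            s = 1500 * k + 200
            seq[s : s + len(motif)] = motif
            features.append(GenomicInterval("chr1", s - 100, s + 400))
        genome["chr1"] = "".join(seq)
        res = run_density_enrichment(features, genome, n_iter=50, seed=1)
        assert res.p_higher <= 0.05
        assert res.n_iter == 50 and len(res.null_values) == 50

    def test_empty_features_error(self, uniform_genome):
        with pytest.raises(ValueError):
            run_density_enrichment([], uniform_genome, n_iter=5, seed=0)


class TestSnpDensityTest:
    def test_zero_snps_all_ties(self, uniform_genome):
        targets = [GenomicInterval("chr1", 100, 1100)]
        (res,) = run_snp_density_test(targets, uniform_genome, [], n_iter=50, seed=0)
        assert res.observed == 0.0
        assert res.p_higher == 1.0 and res.p_lower == 1.0

    def test_per_chrom_grouping(self, uniform_genome, rng):
        targets = [
            GenomicInterval("chr1", 1000, 3000),
            GenomicInterval("chr2", 5000, 9000),
        ]
        snps = [SNPRecord(c, int(p)) for c in ("chr1", "chr2")
                for p in rng.integers(0, 60_000, 500)]
        results = run_snp_density_test(targets, uniform_genome, snps, n_iter=100, seed=3)
        assert [r.scope for r in results] == ["chr1", "chr2"]

    def test_depleted_targets_detected(self, uniform_genome, rng):
        # SNPs everywhere except the target region
        snps = [
            SNPRecord("chr1", int(p))
            for p in rng.integers(0, 60_000, 3000)
            if not 10_000 <= p < 20_000
        ]
        targets = [GenomicInterval("chr1", 10_000 + 200 * k, 10_000 + 200 * k + 150)
                   for k in range(40)]
        (res,) = run_snp_density_test(targets, uniform_genome, snps, n_iter=200, seed=7)
        assert res.observed == 0.0 and res.p_lower <= 0.05

    def test_missing_chromosome_in_snps_ok(self, uniform_genome):
        targets = [GenomicInterval("chr2", 0, 1000)]
        snps = [SNPRecord("chr1", 5)]
        (res,) = run_snp_density_test(targets, uniform_genome, snps, n_iter=20, seed=0)
        assert res.observed == 0.0


class TestGcMatchedSnpTest:
    def _motifs(self, genome, n=30):
        from regg4.g4_scanner import G4Motif

        rng = np.random.default_rng(5)
        motifs = []
        for k in range(n):
            s = 300 * k + int(rng.integers(0, 250))
            motifs.append(
                G4Motif(
                    start=s, end=s + 40, strand="+",
                    g_runs=((s, s + 3), (s + 10, s + 13), (s + 20, s + 23), (s + 37, s + 40)),
                    loop_lengths=(7, 7, 14), n_runs=4,
                    sequence=genome["chr1"][s : s + 40], chrom="chr1",
                )
            )
        return motifs

    def test_calibration_near_half_when_rates_equal(self, uniform_genome, rng):
        snps = [SNPRecord(c, int(p)) for c in ("chr1", "chr2")
                for p in np.unique(rng.integers(0, 60_000, 4000))]
        motifs = self._motifs(uniform_genome, n=150)
        res = run_gc_matched_snp_test(
            motifs, uniform_genome, snps, n_motif_sample=40, n_iter=80, seed=2
        )
        # the motif pool is finite, so only a loose two-sided band is stable
        assert 0.05 <= res.p_random_higher <= 0.95

    def test_insufficient_motifs_error(self, uniform_genome):
        with pytest.raises(ValueError, match="need >="):
            run_gc_matched_snp_test(
                self._motifs(uniform_genome, n=5), uniform_genome, [], n_motif_sample=10
            )

    def test_zero_snps_strict_inequality_gives_zero_p(self, uniform_genome):
        res = run_gc_matched_snp_test(
            self._motifs(uniform_genome), uniform_genome, [],
            n_motif_sample=10, n_iter=20, seed=1,
        )
        assert res.p_random_higher == 0.0


def test_rng_from_is_label_sensitive_and_stable():
    a = rng_from(7, "snps").integers(0, 2**31)
    b = rng_from(7, "snps").integers(0, 2**31)
    c = rng_from(7, "assoc").integers(0, 2**31)
    assert a == b and a != c
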