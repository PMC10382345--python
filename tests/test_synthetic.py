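from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from regg4.disruptive_sites import classify_motif_positions
from regg4.g4_scanner import scan_both_strands, scan_sequence
from regg4.genome_io import GenomicInterval, read_bed, read_fasta, read_genes, read_snps
from regg4.interval_stats import gc_content
from regg4.synthetic_data import (
    ConfigError,
    SyntheticConfig,
    build_motif_sequence,
    generate_dataset,
    generate_genome,
    generate_snps,
    plant_motifs,
    read_truth,
    write_dataset,
)

SMALL = dict(n_chrom=2, chrom_length=60_000, n_genes=20, n_ernas=6, seed=31)


def scan_genome(genome):
    out = []
    for c, s in genome.items():
        out += scan_both_strands(c, s)
    return out


class TestGenome:
    def test_gc_concentration(self):
        cfg = SyntheticConfig(n_chrom=1, chrom_length=100_000, gc=0.5, seed=1)
        genome = generate_genome(cfg)
        assert abs(gc_content(genome["chr1"]) - 0.5) <= 0.01

    def test_seed_reproducibility_byte_identical(self, tmp_path):
        from regg4.genome_io import write_fasta

        cfg = SyntheticConfig(**SMALL)
        a, b = tmp_path / "a.fa", tmp_path / "b.fa"
        write_fasta(generate_genome(cfg), a)
        write_fasta(generate_genome(cfg), b)
        assert a.read_bytes() == b.read_bytes()

    def test_invalid_config_lists_violations(self):
        with pytest.raises(ConfigError) as exc:
            SyntheticConfig(gc=1.2, chrom_length=500, cooccurrence_bias=2.0).validate()
        msg = str(exc.value)
        assert "gc" in msg and "bias" in msg and "10 kb" in msg


class TestPlanting:
    def test_motif_sequences_satisfy_grammar(self, rng):
        cfg = SyntheticConfig(**SMALL)
        for _ in range(200):
            seq, runs, loops = build_motif_sequence(cfg, rng)
            motifs = scan_sequence("A" + seq + "A")
            assert len(motifs) == 1
            m = motifs[0]
            assert (m.start, m.end) == (1, 1 + len(seq))
            assert m.run_lengths == runs

    def test_exact_recovery_with_scrub(self):
        cfg = SyntheticConfig(n_chrom=1, chrom_length=200_000, seed=9, scrub=True)
        genome = generate_genome(cfg)
        regions = [GenomicInterval("chr1", 0, 200_000)]
        genome2, planted = plant_motifs(genome, regions, cfg, n_motifs=50)
        found = scan_genome(genome2)
        assert {m.key() for m in found} == {m.key() for m in planted}
        assert len(planted) == 50

    def test_zero_rate_with_scrub_finds_nothing(self):
        cfg = SyntheticConfig(n_chrom=1, chrom_length=50_000, seed=3, scrub=True)
        genome = generate_genome(cfg)
        genome2, planted = plant_motifs(
            genome, [GenomicInterval("chr1", 0, 50_000)], cfg, n_motifs=0
        )
        assert planted == []
        assert scan_genome(genome2) == []

    def test_planted_run_layout_feeds_disruptive_rule(self):
        cfg = SyntheticConfig(
            n_chrom=1,
            chrom_length=50_000,
            seed=5,
            run_count_dist=((4, 1.0),),
        )
        genome = generate_genome(cfg)
        genome2, planted = plant_motifs(
            genome, [GenomicInterval("chr1", 0, 50_000)], cfg, n_motifs=20
        )
        table = {3: 3, 4: 2, 5: 1}
        for m in planted:
            ann = classify_motif_positions(m)
            expected = sum(table.get(e - s, 0) for s, e in m.g_runs)
            assert len(ann.disruptive_positions) == expected


class TestSnps:
    def test_class_rates_recovered(self):
        cfg = SyntheticConfig(
            n_chrom=1,
            chrom_length=400_000,
            seed=17,
            snp_rate_background=0.03,
            snp_rate_g4_multiplier=1.0,
            snp_rate_disruptive_multiplier=1.0,
            run_count_dist=((4, 1.0),),
        )
        genome = generate_genome(cfg)
        genome2, planted = plant_motifs(
            genome, [GenomicInterval("chr1", 0, 400_000)], cfg, n_motifs=300
        )
        snps, labels = generate_snps(genome2, planted, cfg)
        n_positions = {"background": 400_000, "g4_non_disruptive": 0, "g4_disruptive": 0}
        for m in planted:
            ann = classify_motif_positions(m)
            n_positions["g4_disruptive"] += len(ann.disruptive_positions)
            n_positions["g4_non_disruptive"] += m.length - len(ann.disruptive_positions)
            n_positions["background"] -= m.length
        counts = labels["label"].value_counts()
        for cls, n in n_positions.items():
            rate = counts.get(cls, 0) / n
            assert rate == pytest.approx(0.03, abs=4 * np.sqrt(0.03 / n))

    def test_zero_rate_gives_zero_snps(self):
        cfg = SyntheticConfig(**{**SMALL, "snp_rate_background": 0.0})
        ds = generate_dataset(cfg)
        assert ds.snps == []


class TestDataset:
    def test_truth_matches_scan_and_flags(self):
        cfg = SyntheticConfig(**SMALL)
        ds = generate_dataset(cfg)
        found = scan_genome(ds.genome)
        assert {m.key() for m in found} == {m.key() for m in ds.truth.motifs}
        # per-feature flags consistent with planted motif locations
        for p in ds.promoters:
            planted_here = any(
                m.chrom == p.interval.chrom and m.start >= p.interval.start
                and m.end <= p.interval.end
                for m in ds.truth.motifs
            )
            assert ds.truth.prom_g4[p.gene_id] == planted_here

    def test_emission_roundtrip_reproduces_truth(self, tmp_path):
        cfg = SyntheticConfig(**SMALL)
        ds = generate_dataset(cfg)
        paths = write_dataset(ds, tmp_path)
        genome = read_fasta(paths["fasta"])
        assert genome == ds.genome
        truth = read_truth(paths["truth"])
        assert {m.key() for m in truth.motifs} == {m.key() for m in ds.truth.motifs}
        snps = read_snps(paths["vcf"], "vcf")
        assert [(s.chrom, s.pos) for s in snps] == [(s.chrom, s.pos) for s in ds.snps]
        snps_tsv = read_snps(paths["snps_tsv"], "tsv")
        assert [(s.chrom, s.pos) for s in snps_tsv] == [(s.chrom, s.pos) for s in ds.snps]
        genes = read_genes(paths["genes"])
        assert genes == ds.genes
        proms = read_bed(paths["prom500"])
        assert proms == [p.interval for p in ds.promoters]
        assoc = pd.read_csv(paths["associations"], sep="\t", dtype=str)
        if len(assoc):
            assert assoc.equals(ds.associations)

    def test_dataset_deterministic(self):
        a = generate_dataset(SyntheticConfig(**SMALL))
        b = generate_dataset(SyntheticConfig(**SMALL))
        assert a.genome == b.genome
        assert [m.key() for m in a.truth.motifs] == [m.key() for m in b.truth.motifs]
        assert [(s.chrom, s.pos) for s in a.snps] == [(s.chrom, s.pos) for s in b.snps]
        assert a.associations.equals(b.associations)

    def test_promoter_occupancy_near_configured_rate(self):
        # 1 motif/kb on 500 bp windows -> ~39% of promoters carry a motif
        cfg = SyntheticConfig(
            n_chrom=4, chrom_length=300_000, n_genes=600, n_ernas=0, seed=23
        )
        ds = generate_dataset(cfg)
        frac = np.mean(list(ds.truth.prom_g4.values()))
        assert 0.30 <= frac <= 0.48
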