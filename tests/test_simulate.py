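"""Planted-structure generators: determinism, truth tables, recoverability."""

import numpy as np
import pandas as pd
import pytest

from motifcoloc.clustering import correlation_matrix, dissimilarity, hierarchical_cluster
from motifcoloc.colocalization import density_profile
from motifcoloc.gwas import binomial_enrichment
from motifcoloc.intervals import IntervalSet
from motifcoloc.phasing import partition_pairs
from motifcoloc.pwm import scan_sequence
from motifcoloc.simulate import (
    PHASED_SPACINGS,
    UNPHASED_SPACINGS,
    SimConfig,
    TraitSpec,
    default_motifs,
    make_expression,
    make_genome,
    make_gwas,
    make_mappability,
    make_summits,
    make_tss,
    phasing_recovery_accuracy,
    plant_motif_pairs,
)

SMALL = dict(genome_length=200_000, n_pairs_phased=40, n_pairs_unphased=40, n_tss=50)


class TestGenome:
    def test_deterministic_under_seed(self):
        g1 = make_genome(SimConfig(seed=7, genome_length=50_000))
        g2 = make_genome(SimConfig(seed=7, genome_length=50_000))
        assert g1.seqs == g2.seqs
        g3 = make_genome(SimConfig(seed=8, genome_length=50_000))
        assert g1.seqs != g3.seqs

    def test_gc_one_gives_gc_only(self):
        g = make_genome(SimConfig(seed=0, genome_length=5000, gc=1.0, n_chroms=1))
        assert set(g.seqs["chr1"]) <= {"G", "C"}

    def test_gc_within_three_se(self):
        n = 1_000_000
        gc = 0.41
        g = make_genome(SimConfig(seed=3, genome_length=n, gc=gc, n_chroms=1))
        observed = sum(g.seqs["chr1"].count(b) for b in "GC") / n
        se = np.sqrt(gc * (1 - gc) / n)
        assert abs(observed - gc) < 3 * se


class TestPlantPairs:
    def test_no_pairs_leaves_genome_unchanged(self):
        cfg = SimConfig(seed=1, genome_length=20_000, n_pairs_phased=0, n_pairs_unphased=0)
        g = make_genome(cfg)
        truth, g2 = plant_motif_pairs(g, cfg)
        assert truth.empty
        assert g2.seqs == g.seqs

    def test_truth_table_tallies_requested_histogram(self):
        cfg = SimConfig(seed=2, **SMALL)
        truth, _ = plant_motif_pairs(make_genome(cfg), cfg)
        assert (truth["phase_class"] == "phased").sum() == 40
        assert (truth["phase_class"] == "unphased").sum() == 40
        assert set(truth.loc[truth.phase_class == "phased", "d"]) <= set(PHASED_SPACINGS)
        assert set(truth.loc[truth.phase_class == "unphased", "d"]) <= set(UNPHASED_SPACINGS)
        # zero jitter: realized spacing equals the menu draw
        assert (truth["d"] == truth["d_menu"]).all()

    def test_planted_consensus_written_on_both_strands(self):
        cfg = SimConfig(seed=4, **SMALL)
        motif_a, _ = default_motifs()
        truth, genome = plant_motif_pairs(make_genome(cfg), cfg)
        plus = truth[truth.a_strand == "+"].iloc[0]
        seq = genome.seqs[plus.chrom][plus.a_start : plus.a_start + len(motif_a)]
        assert seq == motif_a.consensus
        minus = truth[truth.a_strand == "-"].iloc[0]
        seq = genome.seqs[minus.chrom][minus.a_start : minus.a_start + len(motif_a)]
        assert seq != motif_a.consensus  # reverse-complement written

    def test_scan_partition_recovers_planted_classes(self):
        cfg = SimConfig(seed=5, **SMALL)
        motif_a, motif_b = default_motifs()
        truth, genome = plant_motif_pairs(make_genome(cfg), cfg)
        hits_a = scan_sequence(genome, motif_a, "high")
        hits_b = scan_sequence(genome, motif_b, "high")
        _, _, pairs = partition_pairs(hits_a, hits_b, max_d=45, tolerance=0)
        assert phasing_recovery_accuracy(truth, pairs) == 1.0

    def test_jittered_recovery_with_tolerance(self):
        cfg = SimConfig(seed=6, pair_jitter=1, **SMALL)
        motif_a, motif_b = default_motifs()
        truth, genome = plant_motif_pairs(make_genome(cfg), cfg)
        hits_a = scan_sequence(genome, motif_a, "high")
        hits_b = scan_sequence(genome, motif_b, "high")
        _, _, pairs = partition_pairs(hits_a, hits_b, max_d=45, tolerance=1)
        assert phasing_recovery_accuracy(truth, pairs) >= 0.99


class TestSummits:
    def test_zero_jitter_profile_peaks_at_planted_sites(self):
        cfg = SimConfig(seed=7, summit_jitter=0.0, **SMALL)
        truth, genome = plant_motif_pairs(make_genome(cfg), cfg)
        summits = make_summits(truth, cfg, genome)
        sites = IntervalSet(
            [s for s in summits], genome.lengths()
        )
        prof = density_profile(summits, sites, 50, 10)
        zero_bin = np.flatnonzero((prof.bin_edges[:-1] <= 0) & (prof.bin_edges[1:] > 0))[0]
        assert prof.raw_counts[zero_bin] == prof.raw_counts.max()

    def test_half_normal_mean_displacement(self):
        cfg = SimConfig(seed=8, summit_jitter=20.0, **SMALL)
        truth, genome = plant_motif_pairs(make_genome(cfg), cfg)
        summits = make_summits(truth, cfg, genome)
        assert len(summits) == len(truth)
        # pairs sit far apart, so the nearest planted center is the source
        centers = truth.groupby("chrom")["a_center"].apply(list).to_dict()
        disp = [
            min(abs(iv.start - c) for c in centers[iv.chrom]) for iv in summits
        ]
        mean = np.mean(disp)
        expected = 20.0 * np.sqrt(2 / np.pi)
        se = 20.0 * np.sqrt(1 - 2 / np.pi) / np.sqrt(len(disp))
        assert abs(mean - expected) < 4 * se

    def test_decoy_only_profile_is_flat(self):
        cfg = SimConfig(
            seed=9,
            genome_length=1_000_000,
            n_pairs_phased=0,
            n_pairs_unphased=0,
            n_decoy_summits=2000,
        )
        genome = make_genome(cfg)
        summits = make_summits(pd.DataFrame(columns=["chrom", "a_center"]), cfg, genome)
        anchors = make_tss(cfg, genome)
        prof = density_profile(anchors, summits, 500, 100)
        se = 1.0 / np.sqrt(prof.global_mean)
        assert np.all(np.abs(prof.density - 1.0) < 4 * se)


class TestTssProximalSites:
    def test_oriented_double_peak_profile(self):
        from motifcoloc.simulate import plant_tss_proximal_sites

        cfg = SimConfig(
            seed=19, genome_length=500_000, n_pairs_phased=0, n_pairs_unphased=0, n_tss=150
        )
        genome = make_genome(cfg)
        tss = make_tss(cfg, genome)
        motif_a, _ = default_motifs()
        truth, genome2 = plant_tss_proximal_sites(
            genome, tss, motif_a, offsets=(30, 200), fraction=1.0, seed=19
        )
        hits = scan_sequence(genome2, motif_a, "high")
        prof = density_profile(tss, hits, half_window=300, bin_width=10, oriented=True)
        top2 = set(np.argsort(prof.raw_counts)[-2:])
        expected_bins = {
            int((30 + 300) // 10),  # just downstream of the start site
            int((200 + 300) // 10),  # +1-nucleosome boundary
        }
        assert top2 == expected_bins


class TestGwasSimulation:
    def _regions(self, genome):
        lengths = genome.lengths()
        from motifcoloc.intervals import GenomicInterval

        return IntervalSet(
            [GenomicInterval("chr1", s, s + 1000) for s in range(0, 50_000, 5000)],
            lengths,
        )

    def test_counts_per_trait_exact(self):
        cfg = SimConfig(
            seed=10,
            **SMALL,
            traits=[TraitSpec("a", 37, 0.0), TraitSpec("b", 11, 1.0)],
        )
        genome = make_genome(cfg)
        track = make_mappability(cfg, genome)
        catalog, _ = make_gwas(cfg, self._regions(genome), track)
        assert catalog.n_snps("a") == 37
        assert catalog.n_snps("b") == 11

    def test_fully_planted_trait_saturates_enrichment(self):
        cfg = SimConfig(
            seed=11, **SMALL, traits=[TraitSpec("planted", 100, 1.0)]
        )
        genome = make_genome(cfg)
        track = make_mappability(cfg, genome)
        regions = self._regions(genome)
        catalog, _ = make_gwas(cfg, regions, track)
        (res,) = binomial_enrichment(regions, catalog, track)
        assert res.x == 100
        assert res.p_value < 1e-100

    def test_planted_fraction_requires_overlap(self):
        cfg = SimConfig(seed=12, **SMALL, traits=[TraitSpec("t", 10, 0.5)])
        genome = make_genome(cfg)
        track = make_mappability(cfg, genome)
        empty = IntervalSet([], genome.lengths())
        with pytest.raises(ValueError):
            make_gwas(cfg, empty, track)

    def test_ld_table_r2_in_range(self):
        cfg = SimConfig(seed=13, **SMALL, traits=[TraitSpec("t", 50, 0.2)])
        genome = make_genome(cfg)
        track = make_mappability(cfg, genome)
        _, ld = make_gwas(cfg, self._regions(genome), track)
        r2s = [r2 for linked in ld.links.values() for _, r2 in linked]
        assert r2s and all(0.0 <= r2 <= 1.0 for r2 in r2s)


class TestMappability:
    def test_striped_fraction(self):
        cfg = SimConfig(seed=14, genome_length=100_000, mappable_fraction_sim=0.6)
        genome = make_genome(cfg)
        track = make_mappability(cfg, genome)
        assert track.total_mappable == pytest.approx(0.6 * 100_000, rel=0.01)


class TestExpression:
    def test_noiseless_blocks_recovered_exactly(self):
        cfg = SimConfig(seed=15, expr_within_r=1.0, expr_n_blocks=3)
        m, blocks = make_expression(cfg)
        labels, _ = hierarchical_cluster(dissimilarity(correlation_matrix(m).r), 3)
        for i in range(len(blocks)):
            for j in range(len(blocks)):
                assert (labels.iloc[i] == labels.iloc[j]) == (
                    blocks.iloc[i] == blocks.iloc[j]
                )

    def test_single_block_single_cluster(self):
        cfg = SimConfig(seed=16, expr_n_blocks=1, expr_within_r=1.0)
        m, _ = make_expression(cfg)
        labels, _ = hierarchical_cluster(dissimilarity(correlation_matrix(m).r), 1)
        assert set(labels) == {1}

    def test_within_block_mean_abs_r_near_target(self):
        cfg = SimConfig(
            seed=17,
            expr_within_r=0.8,
            expr_n_blocks=2,
            expr_rows_per_block=6,
            expr_n_samples=50,
        )
        m, blocks = make_expression(cfg)
        r = correlation_matrix(m).r.to_numpy()
        same = (blocks.to_numpy()[:, None] == blocks.to_numpy()[None, :]) & ~np.eye(
            len(blocks), dtype=bool
        )
        mean_abs = np.abs(r[same]).mean()
        assert abs(mean_abs - 0.8) < 0.05

    def test_deterministic(self):
        m1, _ = make_expression(SimConfig(seed=18))
        m2, _ = make_expression(SimConfig(seed=18))
        pd.testing.assert_frame_equal(m1, m2)
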