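"""Synthetic-data generators: determinism, planted structure, limits."""

import numpy as np
import pytest

import bgcpipe as b
from bgcpipe.codon import SENSE_CODONS, equal_frequencies


class TestGenAnnotation:
    def test_zero_rates_give_zero_clusters(self):
        cfg = b.AnnotationSimConfig(
            chromosome_lengths=(1_000_000,), n_genes=(100,),
            background_cluster_rate=0.0, hotspot=(0, (0, 500_000), 0.0), seed=1,
        )
        _, clusters = b.gen_annotation(cfg)
        assert clusters == []

    def test_deterministic_under_fixed_seed(self):
        cfg = b.AnnotationSimConfig(
            chromosome_lengths=(2_000_000, 1_000_000), n_genes=(200, 100),
            background_cluster_rate=0.01, seed=5,
        )
        assert b.gen_annotation(cfg) == b.gen_annotation(cfg)

    def test_genes_sorted_and_non_overlapping(self):
        cfg = b.AnnotationSimConfig(
            chromosome_lengths=(5_000_000,), n_genes=(500,), seed=2
        )
        genes, _ = b.gen_annotation(cfg)
        for prev, nxt in zip(genes, genes[1:]):
            assert prev.end <= nxt.start

    def test_clusters_span_three_consecutive_genes(self):
        cfg = b.AnnotationSimConfig(
            chromosome_lengths=(5_000_000,), n_genes=(500,),
            background_cluster_rate=0.05, seed=3,
        )
        genes, clusters = b.gen_annotation(cfg)
        by_id = {g.gene_id: g for g in genes}
        assert clusters
        for cl in clusters:
            assert len(cl.member_gene_ids) == 3
            members = [by_id[m] for m in cl.member_gene_ids]
            assert cl.start == members[0].start and cl.end == members[-1].end
            indices = [int(m.split("_g")[1]) for m in cl.member_gene_ids]
            assert indices == list(range(indices[0], indices[0] + 3))

    def test_hotspot_rate_matches_configuration(self):
        # empirical clusters-per-gene inside the hotspot within 3 binomial SDs
        rate = 0.05
        cfg = b.AnnotationSimConfig(
            chromosome_lengths=(50_000_000,), n_genes=(5000,),
            background_cluster_rate=0.0, hotspot=(0, (0, 25_000_000), rate), seed=8,
        )
        genes, clusters = b.gen_annotation(cfg)
        n_in = sum(1 for g in genes if g.midpoint < 25_000_000)
        sd = (rate * (1 - rate) * n_in) ** 0.5
        assert abs(len(clusters) - rate * n_in) <= 3 * sd

    def test_hotspot_outside_chromosome_rejected(self):
        with pytest.raises(ValueError, match="hotspot"):
            b.AnnotationSimConfig(
                chromosome_lengths=(1_000_000,), n_genes=(10,),
                hotspot=(0, (900_000, 2_000_000), 0.1),
            )


class TestGenExpression:
    def test_deterministic_and_integer_nonnegative(self):
        cfg = b.ExpressionSimConfig(n_genes=50, seed=4)
        a = b.gen_expression(cfg)
        c = b.gen_expression(cfg)
        assert a.counts.equals(c.counts)
        assert (a.counts.to_numpy() >= 0).all()
        assert np.issubdtype(a.counts.to_numpy().dtype, np.integer)

    def test_noise_free_limit_approaches_tissue_means(self):
        # at dispersion -> 0 the NB tends to Poisson(mu), so with large
        # means the relative noise ~ 1/sqrt(mu) vanishes and replicate
        # columns of a tissue converge on the shared per-tissue means
        profile = tuple(x * 1e4 for x in (10.0, 100.0, 1.0, 2.0, 3.0, 4.0))
        cfg = b.ExpressionSimConfig(
            n_genes=8, planted_profile=profile, dispersion=1e-8,
            size_factor_range=(1.0, 1.0 + 1e-9), seed=6,
        )
        cm = b.gen_expression(cfg)
        for tissue, _ in cfg.tissues:
            cols = [c for c in cm.sample_ids if c.startswith(tissue)]
            col0, col1 = cm.counts[cols[0]].to_numpy(), cm.counts[cols[1]].to_numpy()
            assert np.abs(col0 / col1 - 1).max() < 0.05

    def test_sample_labels_follow_tissue_rep_convention(self):
        cfg = b.ExpressionSimConfig(n_genes=10, seed=1)
        cm = b.gen_expression(cfg)
        assert cm.sample_ids[0] == "root_1"
        assert len(cm.sample_ids) == sum(reps for _, reps in cfg.tissues)

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValueError, match="replicate"):
            b.ExpressionSimConfig(tissues=(("root", 0),), planted_profile=(1.0,))


class TestGenKmerSpectrum:
    def test_deterministic_under_seed(self):
        cfg = b.SpectrumSimConfig(genome_size=100_000, coverage=20, seed=9)
        assert b.gen_kmer_spectrum(cfg).histogram == b.gen_kmer_spectrum(cfg).histogram

    def test_no_errors_leaves_occurrence_one_nearly_empty(self):
        cfg = b.SpectrumSimConfig(genome_size=500_000, coverage=30, seed=2)
        spec = b.gen_kmer_spectrum(cfg)
        assert spec.histogram.get(1, 0) < 5

    def test_error_fraction_controls_singleton_mass(self):
        cfg = b.SpectrumSimConfig(
            genome_size=200_000, coverage=30, error_kmer_fraction=0.2, seed=2
        )
        spec = b.gen_kmer_spectrum(cfg)
        kn, ku = b.kmer_totals(spec)
        err_instances = ku + 2 * 0  # occurrence-2 errors mix with signal; bound below
        assert ku > 0.1 * kn  # the bulk of the configured 20% sits at occurrence 1

    def test_total_instances_near_genome_times_coverage(self):
        g, cov = 400_000, 25.0
        spec = b.gen_kmer_spectrum(b.SpectrumSimConfig(genome_size=g, coverage=cov, seed=3))
        kn, _ = b.kmer_totals(spec)
        assert kn == pytest.approx(g * cov, rel=0.01)

    def test_peak_detected_near_configured_coverage(self):
        spec = b.gen_kmer_spectrum(
            b.SpectrumSimConfig(genome_size=500_000, coverage=40,
                                error_kmer_fraction=0.1, seed=5)
        )
        assert abs(b.detect_peak(spec) - 40) <= 2

    def test_round_trip_genome_size_recovery(self):
        # non-integer coverage keeps the Poisson mode unique (see docs)
        for seed in (1, 2, 3):
            cfg = b.SpectrumSimConfig(genome_size=2_000_000, coverage=30.5, seed=seed)
            est = b.estimate_genome_size_kmer(b.gen_kmer_spectrum(cfg))
            assert abs(est.genome_size / cfg.genome_size - 1) < 0.02

    def test_low_coverage_rejected(self):
        with pytest.raises(ValueError, match="coverage"):
            b.SpectrumSimConfig(genome_size=1000, coverage=1.5)


class TestSimulateCodonPair:
    def test_zero_branch_length_gives_identical_sequences(self):
        pair = b.simulate_codon_pair(0.0, 2.0, 0.5, 50, seed=1)
        assert pair.seq_a == pair.seq_b

    def test_deterministic_under_seed(self):
        a = b.simulate_codon_pair(0.4, 2.0, 0.3, 100, seed=7)
        c = b.simulate_codon_pair(0.4, 2.0, 0.3, 100, seed=7)
        assert (a.seq_a, a.seq_b) == (c.seq_a, c.seq_b)

    def test_no_stop_codons_in_either_sequence(self):
        pair = b.simulate_codon_pair(1.5, 3.0, 1.0, 200, seed=8)
        for seq in (pair.seq_a, pair.seq_b):
            for k in range(0, len(seq), 3):
                assert seq[k:k + 3] in SENSE_CODONS

    def test_large_t_descendant_matches_stationary_frequencies(self):
        # at t >> 1 the descendant decouples from the ancestor
        pair = b.simulate_codon_pair(40.0, 2.0, 1.0, 3000, seed=10)
        pi = equal_frequencies()
        counts = np.zeros(61)
        for k in range(0, len(pair.seq_b), 3):
            counts[SENSE_CODONS.index(pair.seq_b[k:k + 3])] += 1
        freqs = counts / counts.sum()
        # chi-square-style bound: each frequency within 5 SE of 1/61
        se = np.sqrt(pi * (1 - pi) / 3000)
        assert np.all(np.abs(freqs - pi) < 5 * se)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            b.simulate_codon_pair(-0.1, 2.0, 0.5, 10)
        with pytest.raises(ValueError):
            b.simulate_codon_pair(0.1, 2.0, 0.5, 0)
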