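import dataclasses

import numpy as np
import pytest

from pausekit.quant import define_windows
from pausekit.synthetic import (
    ScenarioEffect,
    SimulationConfig,
    build_truth,
    generate_annotation,
    simulate_dose_matrix,
    simulate_experiment,
    simulate_sample,
)


class TestAnnotation:
    def test_empty_when_no_genes(self):
        cfg = SimulationConfig(n_genes=0, genome_length=1_000_000)
        assert generate_annotation(cfg) == []

    def test_deterministic_given_seed(self, small_config):
        assert generate_annotation(small_config) == generate_annotation(small_config)

    def test_genes_window_disjoint_and_long_enough(self):
        cfg = SimulationConfig(n_genes=200, genome_length=6_000_000, seed=5)
        genes = generate_annotation(cfg)
        assert len(genes) == 200
        assert all(g.length >= cfg.min_gene_length for g in genes)
        # brute-force pairwise check of the +-1000 nt extended intervals
        ext = [(g.start - 1000, g.end + 1000) for g in genes]
        for i in range(len(ext)):
            for j in range(i + 1, len(ext)):
                a, b = ext[i], ext[j]
                assert a[1] <= b[0] or b[1] <= a[0]

    def test_strands_roughly_balanced(self):
        genes = generate_annotation(SimulationConfig(n_genes=400, genome_length=12_000_000, seed=3))
        plus = sum(g.strand == "+" for g in genes)
        assert 120 < plus < 280

    def test_genome_too_small_raises(self):
        with pytest.raises(ValueError, match="genome too small"):
            generate_annotation(SimulationConfig(n_genes=500, genome_length=1_000_000))


class TestTruth:
    def test_true_pi_consistent_with_expected_signals(self, small_config):
        genes = generate_annotation(small_config)
        truth = build_truth(small_config, genes)
        t = truth.table
        # PI must equal promoter density / body density exactly (scale cancels)
        prom_density = t["expected_promoter_count"] / 500.0
        ratio = prom_density / t["expected_body_density"]
        np.testing.assert_allclose(ratio, t["true_pi"], rtol=1e-9)

    def test_vehicle_only_truth_has_unit_fold_changes(self):
        cfg = SimulationConfig(
            n_genes=50, genome_length=2_000_000,
            conditions=(ScenarioEffect("DMSO"),), seed=1,
        )
        truth = build_truth(cfg, generate_annotation(cfg))
        assert (truth.table["body_fc"] == 1.0).all()
        assert not truth.table["affected"].any()

    def test_pause_release_lowers_truth_pi_for_affected(self, small_experiment):
        truth = small_experiment.truth
        veh = truth.per_condition("DMSO")
        rel = truth.per_condition("CDK12i")
        affected = rel["affected"]
        dpi = rel["true_pi"] - veh["true_pi"]
        assert (dpi[affected] < 0).all()
        assert np.allclose(dpi[~affected], 0.0)

    def test_layered_condition_shares_affected_set(self, small_experiment):
        truth = small_experiment.truth
        single = truth.per_condition("CDK12i")["affected"]
        combo = truth.per_condition("CDK12i+PTEFbi")["affected"]
        assert (single == combo).all()


class TestSimulateSample:
    def test_zero_depth_gives_empty_gene_signal(self):
        cfg = SimulationConfig(
            n_genes=20, genome_length=1_000_000, depth_per_sample=0.0,
            background_rate=0.0, seed=2,
        )
        genes = generate_annotation(cfg)
        truth = build_truth(cfg, genes)
        track = simulate_sample(genes, truth, cfg, "DMSO", 1, seed=9)
        assert track.total_signal == 0

    def test_determinism(self, small_config, small_experiment):
        genes = small_experiment.genes
        truth = small_experiment.truth
        a = simulate_sample(genes, truth, small_config, "CDK12i", 1, seed=123)
        b = simulate_sample(genes, truth, small_config, "CDK12i", 1, seed=123)
        for key in a.keys():
            pa, ca = a.arrays(*key)
            pb, cb = b.arrays(*key)
            np.testing.assert_array_equal(pa, pb)
            np.testing.assert_array_equal(ca, cb)

    def test_unknown_condition_rejected(self, small_config, small_experiment):
        with pytest.raises(KeyError):
            simulate_sample(
                small_experiment.genes, small_experiment.truth, small_config,
                "no-such-arm", 1, seed=1,
            )

    def test_signal_on_gene_strand_only(self, small_experiment):
        track = small_experiment.tracks["DMSO_rep1"]
        cfg = dataclasses.replace(small_experiment.config, background_rate=0.0)
        clean = simulate_sample(
            small_experiment.genes, small_experiment.truth, cfg, "DMSO", 1, seed=4
        )
        for g in small_experiment.genes[:50]:
            w = define_windows(g)
            anti = "-" if g.strand == "+" else "+"
            assert clean.count_range(g.chrom, anti, *w.promoter) == 0

    def test_halved_pause_multiplier_halves_promoter_mean(self):
        """Monte-Carlo: promoter-window means track the configured expectation."""
        cfg = SimulationConfig(
            n_genes=500, genome_length=12_000_000, depth_per_sample=1_000_000,
            background_rate=0.0,
            conditions=(ScenarioEffect("DMSO"), ScenarioEffect("half", 1.0, 0.5, 1.0)),
            seed=31,
        )
        genes = generate_annotation(cfg)
        truth = build_truth(cfg, genes)
        track = simulate_sample(genes, truth, cfg, "half", 1, seed=55)
        counts = np.array([
            track.count_range(g.chrom, g.strand, *define_windows(g).promoter) for g in genes
        ])
        expected = truth.per_condition("half")["expected_promoter_count"].to_numpy()
        veh = truth.per_condition("DMSO")["expected_promoter_count"].to_numpy()
        np.testing.assert_allclose(expected, 0.5 * veh)
        # mean over genes within 3 standard errors of the analytic expectation
        var = expected + cfg.dispersion * expected**2
        se = np.sqrt(var.sum()) / len(genes)
        assert abs(counts.mean() - expected.mean()) < 3 * se


class TestSimulateExperiment:
    def test_track_count_matches_design(self, small_experiment):
        # 4 conditions x 2 replicates
        assert len(small_experiment.tracks) == 8
        assert all(("chr1", "+") in t.keys() and ("chr1", "-") in t.keys()
                   for t in small_experiment.tracks.values())

    def test_requires_vehicle_condition(self):
        cfg = SimulationConfig(
            n_genes=10, genome_length=500_000,
            conditions=(ScenarioEffect("drug", 0.5, 0.6, 1.5),), seed=0,
        )
        with pytest.raises(ValueError, match="vehicle"):
            _ = cfg.vehicle

    def test_depth_scaling(self, small_experiment):
        cfg = small_experiment.config
        total = small_experiment.tracks["DMSO_rep1"].total_signal
        background = 2 * cfg.background_rate * cfg.genome_length
        assert abs(total - (cfg.depth_per_sample + background)) / cfg.depth_per_sample < 0.05


class TestDoseMatrix:
    def test_null_matrix_recovers_zero_excess(self):
        matrix, excess = simulate_dose_matrix(
            fa=[0, 0.2, 0.4], fb=[0, 0.3], noise_sd=0.0, n_replicates=2, seed=0
        )
        assert np.all(excess == 0)
        expected = np.array([[0, 0.3], [0.2, 0.44], [0.4, 0.58]])
        np.testing.assert_allclose(matrix.replicate_mean(), expected, atol=1e-12)

    def test_forced_cell_value(self):
        excess = np.zeros((2, 2))
        excess[1, 1] = 0.12
        matrix, _ = simulate_dose_matrix(
            fa=[0, 0.2], fb=[0, 0.5], true_excess=excess, noise_sd=0.0, n_replicates=1
        )
        assert matrix.replicate_mean()[1, 1] == pytest.approx(0.72)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            simulate_dose_matrix(fa=[0, 0.1], fb=[0, 0.1], noise_sd=-0.1)

    def test_mean_recovery_within_noise(self):
        excess = np.zeros((3, 3))
        excess[2, 1] = 0.15
        n_rep = 3
        matrix, _ = simulate_dose_matrix(
            fa=[0, 0.2, 0.35], fb=[0, 0.25, 0.45],
            true_excess=excess, noise_sd=0.02, n_replicates=n_rep, seed=8,
        )
        fa = matrix.replicate_mean()[:, 0]
        fb = matrix.replicate_mean()[0, :]
        bliss = fa[:, None] + fb[None, :] - fa[:, None] * fb[None, :]
        recovered = matrix.replicate_mean() - bliss
        se = 0.02 / np.sqrt(n_rep)
        # single-agent noise propagates, so allow a few combined SEs
        assert abs(recovered[2, 1] - 0.15) < 6 * se
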