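"""Synthetic-data generator: determinism, planted structure, count and
coverage laws, expression coupling."""

import numpy as np
import pandas as pd
import pytest

from ocrdyn.simulate import (
    ConfigError,
    PlacementError,
    SimulationConfig,
    demo_pwms,
    generate_genome,
    plant_peaks_and_motifs,
    run_simulation,
    simulate_counts_and_coverage,
    simulate_expression,
    promoter_openness,
)


def tiny_config(**kw):
    defaults = dict(
        genome_length=1_500_000, n_peaks=200, n_genes=40, seed=1,
        peak_width_range=(300, 500),
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestGenome:
    def test_deterministic_under_fixed_seed(self):
        cfg = tiny_config(seed=9)
        g1, genes1 = generate_genome(cfg)
        g2, genes2 = generate_genome(cfg)
        assert g1 == g2
        assert genes1 == genes2

    def test_gc_content_near_target(self):
        cfg = tiny_config(genome_length=1_000_000, n_peaks=150, gc_content=0.41)
        genome, _ = generate_genome(cfg)
        seq = "".join(genome.values())
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        # binomial CI at n=1e6: half-width well under 0.01
        assert 0.40 <= gc <= 0.42

    def test_tss_spacing_respected(self):
        _, genes = generate_genome(tiny_config(seed=4))
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.interval.chrom, []).append(g.tss)
        for tss in by_chrom.values():
            tss.sort()
            assert np.all(np.diff(tss) >= 2000)

    def test_overfull_gene_placement_fails(self):
        cfg = tiny_config(n_genes=5000)
        with pytest.raises(PlacementError):
            generate_genome(cfg)

    def test_genome_capacity_precondition(self):
        with pytest.raises(ConfigError, match="genome_length"):
            SimulationConfig(genome_length=100_000, n_peaks=600)
        # validation happens at generate time too for mutated configs
        cfg = tiny_config()
        cfg.n_peaks = 10_000
        with pytest.raises(ConfigError):
            generate_genome(cfg)


class TestConfigValidation:
    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ConfigError, match="proportions"):
            tiny_config(dynamic_class_proportions={"up-up": 0.5, "up-flat": 0.4})

    def test_target_r_open_interval(self):
        with pytest.raises(ConfigError, match="open interval"):
            tiny_config(target_pearson_r={"hiPSC": 1.0, "N-d30": 0.4, "N-d41": 0.4})
        with pytest.raises(ConfigError):
            tiny_config(target_pearson_r={"hiPSC": 0.0, "N-d30": 0.4, "N-d41": 0.4})

    def test_yaml_dict_round_trip(self):
        cfg = tiny_config(tf_bound_stages={"TF1": ("N-d41",)})
        assert SimulationConfig.from_dict(cfg.to_dict()) == cfg


class TestPlanting:
    def test_uniform_six_classes_exact_counts(self):
        # 600 peaks, no overrides: deterministic largest-remainder -> 100 each
        cfg = SimulationConfig(
            n_peaks=600, n_genes=60, seed=2, motif_fraction=0.0,
            edges_per_tf=0, autoregulation=False,
        )
        genome, genes = generate_genome(cfg)
        layout = plant_peaks_and_motifs(genome, genes, cfg, demo_pwms(1, seed=3))
        counts = pd.Series(layout.peak_classes).value_counts()
        assert sorted(counts) == [100] * 6

    def test_flat_only_proportions(self):
        cfg = tiny_config(
            dynamic_class_proportions={"flat-flat": 1.0},
            motif_fraction=0.0, edges_per_tf=0, autoregulation=False,
        )
        genome, genes = generate_genome(cfg)
        layout = plant_peaks_and_motifs(genome, genes, cfg, demo_pwms(1, seed=3))
        assert set(layout.peak_classes.values()) == {"flat-flat"}

    def test_empty_pwm_set_rejected(self):
        cfg = tiny_config()
        genome, genes = generate_genome(cfg)
        with pytest.raises(ValueError, match="non-empty"):
            plant_peaks_and_motifs(genome, genes, cfg, [])

    def test_overlong_motif_rejected(self):
        cfg = tiny_config()
        genome, genes = generate_genome(cfg)
        wide = demo_pwms(1, width=200, seed=3)
        with pytest.raises(ValueError, match="too long"):
            plant_peaks_and_motifs(genome, genes, cfg, wide)

    def test_autoregulation_planted_at_minus_213(self):
        cfg = tiny_config()
        genome, genes = generate_genome(cfg)
        layout = plant_peaks_and_motifs(genome, genes, cfg, demo_pwms(2, seed=3))
        tf = layout.truth.autoreg_tf
        assert (tf, tf) in layout.truth.true_edges
        gene = next(g for g in layout.genes if g.gene_id == tf)
        inst = layout.instances[
            (layout.instances.tf == tf)
            & (layout.instances.peak_id == layout.truth.gene_peak[tf])
        ].iloc[-1]
        if gene.strand == "+":
            assert inst.start - gene.tss == -213
        else:
            assert gene.tss - (inst.end - 1) == -213

    def test_truth_refers_to_existing_entities(self, small_sim):
        sim = small_sim
        peak_ids = {p.peak_id for p in sim.peaks}
        gene_ids = {g.gene_id for g in sim.genes}
        assert set(sim.truth.peak_class) == peak_ids
        inst_ids = set(sim.instances.instance_id)
        for (tf, stage), ids in sim.truth.bound_instances.items():
            assert ids <= inst_ids
            assert stage in sim.config.stages
        for tf, gene in sim.truth.true_edges:
            assert gene in gene_ids

    def test_bound_instances_lie_in_open_peaks(self, small_sim):
        sim = small_sim
        inst = sim.instances.set_index("instance_id")
        for (tf, stage), ids in sim.truth.bound_instances.items():
            si = sim.config.stages.index(stage)
            for iid in ids:
                cls = sim.truth.peak_class[inst.loc[iid, "peak_id"]]
                assert sim.config.openness_multipliers[cls][si] > 0


class TestCountsAndCoverage:
    def test_full_determinism(self):
        cfg = tiny_config(seed=17)
        a = run_simulation(cfg)
        b = run_simulation(cfg)
        assert a.genome == b.genome
        pd.testing.assert_frame_equal(a.counts, b.counts)
        pd.testing.assert_frame_equal(a.expression, b.expression)
        for s in cfg.stages:
            for c in a.coverage[s].arrays:
                assert np.array_equal(a.coverage[s].arrays[c], b.coverage[s].arrays[c])

    def test_poisson_limit_variance_over_mean(self):
        # phi=0, fixed width, flat class: all counts i.i.d. Poisson
        cfg = SimulationConfig(
            genome_length=7_000_000, n_chromosomes=2, n_peaks=1700, n_genes=20,
            peak_width_range=(400, 400), nb_dispersion=0.0,
            dynamic_class_proportions={"flat-flat": 1.0},
            motif_fraction=0.0, edges_per_tf=0, autoregulation=False, seed=8,
        )
        sim = run_simulation(cfg, make_coverage=False)
        draws = sim.counts.to_numpy(dtype=float).ravel()  # 1700*6 > 10000 draws
        ratio = draws.var() / draws.mean()
        assert 0.95 <= ratio <= 1.05

    def test_rho_zero_gives_exactly_empty_cores(self):
        cfg = tiny_config(footprint_protection=0.0, motif_fraction=0.5)
        sim = run_simulation(cfg)
        bound = sim.instances[sim.instances.bound]
        assert len(bound) > 10
        for row in bound.itertuples():
            for stage in row.bound_stages.split(","):
                cov = sim.coverage[stage].slice(row.chrom, row.start, row.end)
                assert cov.sum() == 0.0

    def test_zero_multiplier_stage_is_background_only(self):
        mults = dict(SimulationConfig().openness_multipliers)
        mults["flat-up"] = (0.0, 0.0, 4.0)
        cfg = tiny_config(
            openness_multipliers=mults,
            dynamic_class_proportions={"flat-up": 1.0},
            motif_fraction=0.0, edges_per_tf=0, autoregulation=False,
        )
        sim = run_simulation(cfg, make_coverage=False)
        hip = sim.counts[["hiPSC_1", "hiPSC_2"]].to_numpy()
        widths = np.array([len(p.interval) for p in sim.peaks])
        expected_bg = cfg.background_rate * widths.mean()
        assert hip.mean() == pytest.approx(expected_bg, rel=0.25)
        assert sim.counts[["N-d41_1", "N-d41_2"]].to_numpy().mean() > 30 * expected_bg

    def test_coverage_count_conservation_exact(self, small_sim):
        sim = small_sim
        reps = sim.config.replicates_per_stage
        for si, stage in enumerate(sim.config.stages):
            cols = [f"{stage}_{r + 1}" for r in range(reps)]
            stage_totals = sim.counts[cols].sum(axis=1)
            for p in sim.peaks:
                inside = sim.coverage[stage].slice(
                    p.interval.chrom, p.interval.start, p.interval.end
                )
                assert inside.sum() == stage_totals[p.peak_id]


class TestExpression:
    def test_sigma_zero_gives_perfect_correlation(self, small_sim):
        from scipy import stats as sps

        sim = small_sim
        expr = simulate_expression(sim.openness, sim.config, force_sigma=0.0)
        x = np.log2(sim.openness["N-d30"] + 1)
        y = np.log2(expr["N-d30"] + 1)
        assert sps.pearsonr(x, y)[0] == pytest.approx(1.0, abs=1e-12)

    def test_sample_r_tracks_target(self):
        # Fisher-z bound: |atanh(r) - atanh(rho)| < 4/sqrt(n-3) with very
        # high probability at the planted rho
        from scipy import stats as sps

        cfg = SimulationConfig(
            genome_length=3_000_000, n_peaks=600, n_genes=600, seed=21,
            peak_width_range=(300, 500), motif_fraction=0.0,
            edges_per_tf=0, autoregulation=False,
        )
        sim = run_simulation(cfg, make_coverage=False)
        for stage, target in cfg.target_pearson_r.items():
            x = np.log2(sim.openness[stage] + 1)
            y = np.log2(sim.expression[stage] + 1)
            r = sps.pearsonr(x, y)[0]
            n = len(x)
            assert abs(np.arctanh(r) - np.arctanh(target)) < 4 / np.sqrt(n - 3)

    def test_missing_stage_target_rejected(self, small_sim):
        cfg = SimulationConfig(target_pearson_r={"hiPSC": 0.2})
        with pytest.raises(ConfigError, match="target_pearson_r"):
            simulate_expression(small_sim.openness, cfg)

    def test_expression_link_recorded(self, small_sim):
        sim = small_sim
        assert sim.truth.expression_link
        some_gene = next(iter(sim.truth.expression_link))
        b0, b1, sigma = sim.truth.expression_link[some_gene]["N-d30"]
        assert b1 == sim.config.expression_beta1
        assert sigma > 0
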