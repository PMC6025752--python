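"""Stage-specific TF statistics, lag test and network assembly."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from ocrdyn.core import CoverageTrack, GeneModel, GenomicInterval
from ocrdyn.footprints import Footprint, MotifHit
from ocrdyn.networks import (
    Edge,
    assign_targets,
    build_network,
    detect_autoregulation,
    footprint_tss_distance,
    lag_test,
    master_nodes,
    most_connected_component,
    specificity_distribution_test,
    stage_specificity_test,
    upstream_regulators,
)

STAGES = ["hiPSC", "N-d30", "N-d41"]


def counts_frame(rows, n_null=0, null=(10, 10, 10)):
    data = dict(rows)
    for i in range(n_null):
        data[f"null{i}"] = null
    return pd.DataFrame.from_dict(data, orient="index", columns=STAGES)


def fp(tf, chrom, start, end, stage="N-d41", purity=0.95, strand="+"):
    return Footprint(
        hit=MotifHit(tf, GenomicInterval(chrom, start, end, strand), 1.0),
        stage=stage, purity=purity, flank_mean=5.0, core_mean=0.1,
    )


class TestStageSpecificity:
    def test_planted_hipsc_specific(self):
        counts = counts_frame({"TFA": (100, 10, 10)}, n_null=99)
        totals = {s: 10_000 for s in STAGES}
        profiles = stage_specificity_test(counts, totals)
        assert profiles[0].classification == "hiPSC-specific"

    def test_fold_gate_blocks_small_differences(self):
        counts = counts_frame({"TFA": (10, 11, 9)}, n_null=10)
        totals = {s: 10_000 for s in STAGES}
        assert stage_specificity_test(counts, totals)[0].classification == "non-specific"

    def test_shared_neuronal_class(self):
        counts = counts_frame({"TFA": (5, 100, 110)}, n_null=99)
        totals = {s: 10_000 for s in STAGES}
        assert (
            stage_specificity_test(counts, totals)[0].classification
            == "N-d30&N-d41-shared"
        )

    def test_classification_partitions_tf_universe(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(rng.poisson(50, size=(40, 3)), columns=STAGES)
        counts.index = [f"tf{i}" for i in range(40)]
        profiles = stage_specificity_test(counts, {s: 10_000 for s in STAGES})
        labels = {
            "hiPSC-specific", "N-d30-specific", "N-d41-specific",
            "N-d30&N-d41-shared", "non-specific",
        }
        assert len(profiles) == 40
        assert all(p.classification in labels for p in profiles)

    def test_null_simulation_controls_false_positives(self):
        # 200 TFs with equal Poisson means: Bonferroni keeps specific
        # calls essentially at zero
        rng = np.random.default_rng(11)
        counts = pd.DataFrame(rng.poisson(100, size=(200, 3)), columns=STAGES)
        counts.index = [f"tf{i}" for i in range(200)]
        profiles = stage_specificity_test(counts)
        n_specific = sum(p.classification != "non-specific" for p in profiles)
        assert n_specific <= 1

    def test_zero_total_rejected(self):
        counts = counts_frame({"TFA": (1, 2, 3)})
        with pytest.raises(ValueError, match="zero footprint total"):
            stage_specificity_test(counts, {"hiPSC": 0, "N-d30": 10, "N-d41": 10})

    def test_distribution_test_runs(self):
        counts = counts_frame({"TFA": (100, 10, 10)}, n_null=99)
        profiles = stage_specificity_test(counts, {s: 10_000 for s in STAGES})
        p = specificity_distribution_test(profiles)
        assert 0.0 <= p <= 1.0


class TestLag:
    def _frames(self, expr_rows, binding_rows):
        e = pd.DataFrame.from_dict(expr_rows, orient="index", columns=STAGES)
        b = pd.DataFrame.from_dict(binding_rows, orient="index", columns=STAGES)
        return e, b

    def test_seven_of_seven_worked_example(self):
        tfs = [f"tf{i}" for i in range(7)]
        expr, binding = self._frames(
            {t: (1, 50, 10) for t in tfs},  # expression peaks at N-d30
            {t: (0, 5, 40) for t in tfs},  # binding peaks at N-d41
        )
        res = lag_test(expr, binding, tfs, STAGES)
        assert (res.k, res.n) == (7, 7)
        assert res.p_value == pytest.approx(0.015625)
        assert res.p_value < 0.05

    def test_balanced_flags_give_maximal_p(self):
        tfs = [f"tf{i}" for i in range(8)]
        expr_rows = {t: ((1, 50, 10) if i < 4 else (1, 1, 50)) for i, t in enumerate(tfs)}
        expr, binding = self._frames(expr_rows, {t: (0, 5, 40) for t in tfs})
        res = lag_test(expr, binding, tfs, STAGES)
        assert (res.k, res.n) == (4, 8)
        assert res.p_value == pytest.approx(1.0)

    def test_argmax_tie_resolves_to_earliest_stage(self):
        expr, binding = self._frames(
            {"tf0": (50.0, 50.0, 10.0)},  # tie hiPSC/N-d30 -> hiPSC
            {"tf0": (0, 40, 40)},  # tie N-d30/N-d41 -> N-d30
        )
        res = lag_test(expr, binding, ["tf0"], STAGES)
        assert res.flags["tf0"] is True  # hiPSC earlier than N-d30


class TestTargets:
    def setup_method(self):
        self.gene_plus = GeneModel("gA", GenomicInterval("chr1", 50_000, 55_000, "+"))
        self.gene_minus = GeneModel("gB", GenomicInterval("chr2", 40_000, 45_001, "-"))

    def test_upstream_footprint_within_window(self):
        edges = assign_targets([fp("TF1", "chr1", 49_500, 49_510)], [self.gene_plus])
        assert Edge("TF1", "gA") in edges

    def test_far_upstream_excluded_at_default_window(self):
        edges = assign_targets([fp("TF1", "chr1", 30_000, 30_010)], [self.gene_plus])
        assert edges == {}

    def test_minus_strand_window_reflected(self):
        # TSS at 45_000; upstream = larger coordinates
        edges = assign_targets([fp("TF1", "chr2", 49_000, 49_010)], [self.gene_minus])
        assert Edge("TF1", "gB") in edges
        edges = assign_targets([fp("TF1", "chr2", 30_000, 30_010)], [self.gene_minus])
        assert edges == {}

    def test_signed_tss_distance(self):
        f = fp("TF1", "chr1", 49_787, 49_797)
        assert footprint_tss_distance(f, self.gene_plus) == -213
        f2 = fp("TF1", "chr2", 45_204, 45_214)
        assert footprint_tss_distance(f2, self.gene_minus) == -213


def star_edges(hub, n, offset=0, stage="N-d41"):
    edges = {}
    for i in range(n):
        g = f"t{offset + i}"
        edges[Edge(hub, g)] = [fp(hub, "chr1", 1000 * (offset + i), 1000 * (offset + i) + 10, stage=stage)]
    return edges


def profile_for(tf, classification="N-d41-specific"):
    from ocrdyn.networks import TFStageProfile

    return TFStageProfile(
        tf_name=tf, footprint_counts={s: 1 for s in STAGES},
        stage_totals={s: 10 for s in STAGES}, fold_vs_others={},
        fisher_p_bonf={}, classification=classification,
    )


class TestNetwork:
    def test_no_qualifying_tfs_gives_empty_network(self):
        edges = star_edges("TF1", 3)
        expr = pd.DataFrame({s: [1.0] for s in STAGES}, index=["TF1"])
        net = build_network(edges, [profile_for("TF1", "non-specific")], expr,
                            "N-d41", "hiPSC")
        assert net.number_of_nodes() == 0

    def test_below_purity_cutoff_excluded(self):
        edges = {Edge("TF1", "g1"): [fp("TF1", "chr1", 0, 10, purity=0.5)]}
        expr = pd.DataFrame({s: [1.0] for s in STAGES}, index=["TF1"])
        net = build_network(edges, [profile_for("TF1")], expr, "N-d41", "hiPSC")
        assert net.number_of_edges() == 0

    def test_expression_attribute_is_log2_fc(self, small_sim):
        sim = small_sim
        edges = star_edges("TF1", 2)
        net = build_network(edges, [profile_for("TF1")], sim.expression, "N-d41", "hiPSC")
        row = sim.expression.loc["TF1"]
        expected = float(np.log2(row["N-d41"] + 1) - np.log2(row["hiPSC"] + 1))
        assert net.nodes["TF1"]["log2fc"] == pytest.approx(expected)

    def test_star_component_and_hub_master(self):
        edges = {**star_edges("HUB", 10), **star_edges("LONER", 1, offset=50)}
        expr = pd.DataFrame({s: [1.0, 1.0] for s in STAGES}, index=["HUB", "LONER"])
        net = build_network(edges, [profile_for("HUB"), profile_for("LONER")],
                            expr, "N-d41", "hiPSC")
        comp = most_connected_component(net)
        assert comp.number_of_nodes() == 11
        assert master_nodes(comp, k=6) == ["HUB"]

    def test_equal_size_components_tie_broken_by_edges(self):
        g = nx.DiGraph()
        # component A: 3 nodes, 2 edges; component B: 3 nodes, 3 edges
        g.add_edges_from([("a1", "a2"), ("a1", "a3")])
        g.add_edges_from([("b1", "b2"), ("b1", "b3"), ("b2", "b3")])
        for n in g.nodes:
            g.nodes[n]["kind"] = "tf"
        comp = most_connected_component(g)
        assert set(comp.nodes) == {"b1", "b2", "b3"}

    def test_master_tie_break_total_degree_then_name(self):
        g = nx.DiGraph()
        g.add_edges_from([("A", "x"), ("A", "y"), ("B", "y"), ("B", "z"), ("w", "B")])
        for n in "AB":
            g.nodes[n]["kind"] = "tf"
        for n in "xyzw":
            g.nodes[n]["kind"] = "gene"
        # A and B both out-degree 2; B has extra in-edge -> higher degree
        assert master_nodes(g, k=1) == ["B"]


class TestUpstreamAndAutoregulation:
    def test_self_footprint_at_minus_213_reported(self):
        gene = GeneModel("TF1", GenomicInterval("chr1", 50_000, 55_000, "+"))
        f = fp("TF1", "chr1", 49_787, 49_797)
        regs = upstream_regulators(gene, [f])
        assert regs == ["TF1"]

    def test_downstream_footprint_excluded(self):
        gene = GeneModel("TF1", GenomicInterval("chr1", 50_000, 55_000, "+"))
        f = fp("TF1", "chr1", 50_100, 50_110)
        assert upstream_regulators(gene, [f]) == []

    def test_shared_regulators_match_hand_enumeration(self):
        gene_a = GeneModel("A", GenomicInterval("chr1", 500_000, 505_000, "+"))
        gene_b = GeneModel("B", GenomicInterval("chr1", 560_000, 565_000, "+"))
        fps = [
            fp("R1", "chr1", 450_000, 450_010),  # upstream of A only
            fp("R2", "chr1", 499_000, 499_010),  # upstream of A and B (within 100kb of both)
            fp("R3", "chr1", 520_000, 520_010),  # upstream of B only
            fp("R4", "chr1", 559_000, 559_010),  # upstream of B only
            fp("R5", "chr1", 700_000, 700_010),  # downstream of both
            fp("R6", "chr1", 470_000, 470_010),  # upstream of A and B
            fp("R7", "chr2", 450_000, 450_010),  # wrong chromosome
            fp("R8", "chr1", 399_000, 399_010),  # >100 kb upstream of both
            fp("R9", "chr1", 504_000, 504_010),  # inside A, upstream of B
            fp("R10", "chr1", 565_000, 565_010),  # downstream of B
        ]
        regs_a = set(upstream_regulators(gene_a, fps))
        regs_b = set(upstream_regulators(gene_b, fps))
        assert regs_a == {"R1", "R2", "R6"}
        assert regs_b == {"R2", "R3", "R4", "R6", "R9"}
        assert regs_a & regs_b == {"R2", "R6"}

    def test_autoregulation_flag_and_distance(self):
        genes = {"TF1": GeneModel("TF1", GenomicInterval("chr1", 50_000, 55_000, "+"))}
        edges = {Edge("TF1", "TF1"): [fp("TF1", "chr1", 49_787, 49_797)]}
        assert detect_autoregulation("TF1", edges, genes) == (True, -213)

    def test_no_self_edge(self):
        genes = {"TF1": GeneModel("TF1", GenomicInterval("chr1", 50_000, 55_000, "+"))}
        assert detect_autoregulation("TF1", {}, genes) == (False, None)
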