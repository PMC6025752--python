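"""Stage-specific TF classification and TF regulatory-network assembly.

A TF is *stage-specific* when its footprint count in one stage exceeds
every other stage by more than a fold threshold (default 2) and each
pairwise contrast is significant by Fisher's exact test after Bonferroni
correction over all TF x contrast tests. TFs whose two later (neuronal)
stages both beat the first stage by the same rule, with neither beating
the other, are *shared*. Everything else is non-specific.

Networks are directed TF -> target graphs: an edge exists when a called
footprint of the TF lies in a strand-aware window around the target
gene's TSS (default 10 kb upstream / 1 kb downstream). Master nodes are
the highest out-degree TFs of the largest connected component.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import GeneModel
from .footprints import Footprint
from .stats import binomial_test_two_sided, fisher_exact_two_sided

NON_SPECIFIC = "non-specific"


@dataclass
class TFStageProfile:
    tf_name: str
    footprint_counts: Dict[str, int]
    stage_totals: Dict[str, int]
    fold_vs_others: Dict[str, float]
    fisher_p_bonf: Dict[Tuple[str, str], float]
    classification: str


def stage_specificity_test(
    counts: pd.DataFrame,
    totals: Optional[Mapping[str, int]] = None,
    fold_min: float = 2.0,
    alpha: float = 0.05,
) -> List[TFStageProfile]:
    """Classify each TF (rows) by its per-stage footprint counts (columns).

    ``totals`` are the per-stage footprint totals over all TFs (defaults
    to the column sums). For every unordered stage pair a 2x2 Fisher test
    compares (TF count, total - TF count) across the two stages;
    Bonferroni correction spans all TF x pair tests.
    """
    stages = list(counts.columns)
    if len(stages) < 2:
        raise ValueError("need >=2 stages")
    if totals is None:
        totals = counts.sum(axis=0).to_dict()
    for s in stages:
        if totals[s] <= 0:
            raise ValueError(f"zero footprint total for stage {s!r}")
    pairs = [(stages[i], stages[j]) for i in range(len(stages)) for j in range(i + 1, len(stages))]
    m = len(counts) * len(pairs)  # Bonferroni denominator

    profiles: List[TFStageProfile] = []
    for tf, row in counts.iterrows():
        c = {s: int(row[s]) for s in stages}
        p_bonf: Dict[Tuple[str, str], float] = {}
        for sa, sb in pairs:
            p = fisher_exact_two_sided(
                [[c[sa], totals[sa] - c[sa]], [c[sb], totals[sb] - c[sb]]]
            )
            p_bonf[(sa, sb)] = min(1.0, p * m)

        def significant(sa: str, sb: str) -> bool:
            key = (sa, sb) if (sa, sb) in p_bonf else (sb, sa)
            return p_bonf[key] < alpha

        fold_vs_others = {}
        for s in stages:
            others = [c[o] for o in stages if o != s]
            mx = max(others)
            fold_vs_others[s] = float("inf") if mx == 0 else c[s] / mx

        label = NON_SPECIFIC
        for s in stages:
            if all(c[s] > fold_min * c[o] for o in stages if o != s) and all(
                significant(s, o) for o in stages if o != s
            ):
                label = f"{s}-specific"
                break
        if label == NON_SPECIFIC and len(stages) == 3:
            first, n1, n2 = stages
            beats = lambda s: c[s] > fold_min * c[first] and significant(s, first)
            neither_dominates = not (
                c[n1] >= fold_min * c[n2] or c[n2] >= fold_min * c[n1]
            )
            if beats(n1) and beats(n2) and neither_dominates:
                label = f"{n1}&{n2}-shared"
        profiles.append(
            TFStageProfile(
                tf_name=str(tf),
                footprint_counts=c,
                stage_totals=dict(totals),
                fold_vs_others=fold_vs_others,
                fisher_p_bonf=p_bonf,
                classification=label,
            )
        )
    return profiles


def specificity_table(profiles: Sequence[TFStageProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {"tf": p.tf_name, "classification": p.classification}
        row.update({f"n_{s}": c for s, c in p.footprint_counts.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def specificity_distribution_test(profiles: Sequence[TFStageProfile]) -> float:
    """Test whether stage-specific TFs distribute unevenly across stages
    (chi-square on the stage x specific/non-specific count table).

    One interpretation of a global 'not random sampling' check; reported
    as such, without claiming equivalence to any particular published
    construction.
    """
    stages = list(profiles[0].footprint_counts)
    spec = {s: 0 for s in stages}
    nonspec = {s: 0 for s in stages}
    for p in profiles:
        for s in stages:
            if p.classification == f"{s}-specific":
                spec[s] += 1
            else:
                nonspec[s] += 1
    table = np.array([[spec[s] for s in stages], [nonspec[s] for s in stages]])
    if table[0].sum() == 0:
        return 1.0
    _, p, _, _ = sps.chi2_contingency(table)
    return float(p)


# ---------------------------------------------------------------------------
# expression-vs-binding lag


@dataclass
class LagResult:
    flags: Dict[str, bool]
    k: int
    n: int
    p_value: float


def lag_test(
    expression: pd.DataFrame,
    binding: pd.DataFrame,
    tf_set: Sequence[str],
    stage_order: Sequence[str],
) -> LagResult:
    """Does expression peak earlier than footprint occupancy?

    For each TF the binding-peak stage is the argmax of footprint counts
    and the expression-peak stage the argmax of RPKM (ties resolved to
    the earliest stage in ``stage_order``). The lag flag is true when the
    expression peak is strictly earlier; the p-value is the exact
    two-sided binomial test of k lags among n TFs against 0.5.
    """
    order = {s: i for i, s in enumerate(stage_order)}
    flags: Dict[str, bool] = {}
    for tf in tf_set:
        b = binding.loc[tf, list(stage_order)].to_numpy(dtype=float)
        e = expression.loc[tf, list(stage_order)].to_numpy(dtype=float)
        bind_peak = int(np.argmax(b))  # argmax returns first max: earliest
        expr_peak = int(np.argmax(e))
        flags[tf] = expr_peak < bind_peak
    k = sum(flags.values())
    n = len(flags)
    p = binomial_test_two_sided(k, n, 0.5) if n > 0 else float("nan")
    return LagResult(flags=flags, k=k, n=n, p_value=p)


# ---------------------------------------------------------------------------
# network assembly


@dataclass(frozen=True)
class Edge:
    tf: str
    gene: str


def assign_targets(
    footprints: Sequence[Footprint],
    genes: Sequence[GeneModel],
    window: Tuple[int, int] = (10000, 1000),
) -> Dict[Edge, List[Footprint]]:
    """TF -> gene edges supported by footprints in the promoter-proximal
    window (strand-aware; default 10 kb upstream, 1 kb downstream of the
    TSS). A footprint may support several genes when windows overlap.
    """
    upstream, downstream = window
    edges: Dict[Edge, List[Footprint]] = {}
    by_chrom: Dict[str, List[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.interval.chrom, []).append(g)
    for fp in footprints:
        iv = fp.hit.interval
        for g in by_chrom.get(iv.chrom, []):
            win = g.promoter_window(upstream, downstream)
            if iv.start < win.end and win.start < iv.end:
                edges.setdefault(Edge(fp.hit.tf_name, g.gene_id), []).append(fp)
    return edges


def footprint_tss_distance(fp: Footprint, gene: GeneModel) -> int:
    """Strand-aware signed offset of the motif start from the TSS
    (negative = upstream)."""
    iv = fp.hit.interval
    if gene.strand == "+":
        return iv.start - gene.tss
    return gene.tss - (iv.end - 1)


def build_network(
    edges: Mapping[Edge, Sequence[Footprint]],
    profiles: Sequence[TFStageProfile],
    expression: pd.DataFrame,
    stage: str,
    baseline_stage: str,
    purity_cutoff: float = 0.9,
    include_shared: bool = True,
) -> nx.DiGraph:
    """Directed TF -> target network for one stage.

    TF nodes are restricted to TFs classified as specific to ``stage``
    (plus shared classes naming the stage when ``include_shared``) having
    at least one supporting footprint in that stage with purity >= the
    cutoff; target nodes are their assigned genes. Node attribute
    ``log2fc`` is log2(stage RPKM + 1) - log2(baseline RPKM + 1).
    """
    allowed = set()
    for p in profiles:
        cls = p.classification
        if cls == f"{stage}-specific":
            allowed.add(p.tf_name)
        elif include_shared and cls.endswith("-shared") and stage in cls[: -len("-shared")].split("&"):
            allowed.add(p.tf_name)
    g = nx.DiGraph()
    for edge, fps in edges.items():
        if edge.tf not in allowed:
            continue
        support = [
            fp
            for fp in fps
            if fp.stage == stage and fp.purity >= purity_cutoff
        ]
        if not support:
            continue
        for node, kind in ((edge.tf, "tf"), (edge.gene, "gene")):
            if not g.has_node(node):
                g.add_node(node, kind=kind, log2fc=_expr_log2fc(expression, node, stage, baseline_stage))
            elif kind == "tf":
                g.nodes[node]["kind"] = "tf"
        g.add_edge(edge.tf, edge.gene, n_footprints=len(support))
    return g


def _expr_log2fc(expression: pd.DataFrame, gene: str, stage: str, baseline: str) -> float:
    if gene not in expression.index:
        return float("nan")
    row = expression.loc[gene]
    return float(np.log2(row[stage] + 1.0) - np.log2(row[baseline] + 1.0))


def most_connected_component(network: nx.DiGraph) -> nx.DiGraph:
    """Largest weakly connected component (ties: more edges, then the
    lexicographically smallest node set)."""
    if network.number_of_nodes() == 0:
        return network.copy()
    comps = [set(c) for c in nx.weakly_connected_components(network)]
    best = max(
        comps,
        key=lambda c: (
            len(c),
            network.subgraph(c).number_of_edges(),
            [-ord(ch) for ch in "\x00".join(sorted(c))],  # smaller set wins ties
        ),
    )
    return network.subgraph(best).copy()


def master_nodes(subnetwork: nx.DiGraph, k: int = 6) -> List[str]:
    """Top-k TFs of a component by out-degree (ties: total degree, then
    name)."""
    tfs = [n for n, d in subnetwork.nodes(data=True) if d.get("kind") == "tf"]
    ranked = sorted(
        tfs,
        key=lambda n: (-subnetwork.out_degree(n), -subnetwork.degree(n), n),
    )
    return ranked[:k]


def upstream_regulators(
    tf_gene: GeneModel,
    footprints: Sequence[Footprint],
    span: int = 100_000,
) -> List[str]:
    """TFs with >=1 footprint overlapping the strand-aware window
    [TSS - span, TSS) upstream of a focal gene."""
    tss, strand, chrom = tf_gene.tss, tf_gene.strand, tf_gene.interval.chrom
    if strand == "+":
        lo, hi = max(0, tss - span), tss
    else:
        lo, hi = tss + 1, tss + 1 + span
    regulators = set()
    for fp in footprints:
        iv = fp.hit.interval
        if iv.chrom == chrom and iv.start < hi and lo < iv.end:
            regulators.add(fp.hit.tf_name)
    return sorted(regulators)


def detect_autoregulation(
    tf: str,
    edges: Mapping[Edge, Sequence[Footprint]],
    genes: Mapping[str, GeneModel],
) -> Tuple[bool, Optional[int]]:
    """Self-edge check: does the TF target its own gene?

    Returns ``(flag, signed TSS distance of the nearest supporting
    footprint)``; the distance is ``None`` when there is no self-edge.
    The TF's gene is the gene whose id equals the TF name.
    """
    self_edge = Edge(tf, tf)
    if self_edge not in edges or tf not in genes:
        return False, None
    gene = genes[tf]
    dists = [footprint_tss_distance(fp, gene) for fp in edges[self_edge]]
    return True, min(dists, key=abs)
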