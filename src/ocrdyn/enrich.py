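"""Hypergeometric gene-set overrepresentation and nearest-gene mapping.

Peaks are linked to genes by nearest TSS; query gene lists (nearest
genes of stage-specific peaks, TF targets, ...) are tested for
overrepresentation in user-supplied gene sets (GMT) with an upper-tail
hypergeometric test and BH FDR across sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import GeneModel, GenomicInterval
from .stats import bh_fdr


@dataclass
class EnrichmentResult:
    set_name: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    fold_enrichment: float
    p: float
    q: float = float("nan")


def nearest_gene(peak: GenomicInterval, genes: Sequence[GeneModel]) -> str:
    """Gene whose TSS is nearest the peak center; ties go to the smaller
    TSS coordinate. Only same-chromosome genes are considered."""
    center = peak.center
    best = None
    for g in genes:
        if g.interval.chrom != peak.chrom:
            continue
        key = (abs(g.tss - center), g.tss)
        if best is None or key < best[0]:
            best = (key, g.gene_id)
    if best is None:
        raise ValueError(f"no gene on chromosome {peak.chrom}")
    return best[1]


def hypergeometric_enrichment(
    query: Iterable[str],
    gene_sets: Mapping[str, Set[str]],
    universe: Iterable[str],
) -> List[EnrichmentResult]:
    """Upper-tail hypergeometric overrepresentation of ``query`` in each
    gene set, BH-corrected across sets.

    The query must be a subset of the universe; sets are intersected
    with the universe. An empty query returns an empty list.
    """
    uni = set(universe)
    q = set(query)
    if not q:
        return []
    if not q <= uni:
        raise ValueError(f"query genes outside universe: {sorted(q - uni)[:5]}")
    N, n = len(uni), len(q)
    results: List[EnrichmentResult] = []
    for name in sorted(gene_sets):
        members = gene_sets[name] & uni
        K = len(members)
        if K == 0:
            continue
        k = len(members & q)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N)
        results.append(
            EnrichmentResult(
                set_name=name,
                overlap=k,
                set_size=K,
                query_size=n,
                universe_size=N,
                fold_enrichment=fold,
                p=min(1.0, p),
            )
        )
    if results:
        qvals = bh_fdr([r.p for r in results])
        for r, qv in zip(results, qvals):
            r.q = float(qv)
    return results


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set_name": r.set_name,
                "overlap": r.overlap,
                "set_size": r.set_size,
                "query_size": r.query_size,
                "universe_size": r.universe_size,
                "fold_enrichment": r.fold_enrichment,
                "p": r.p,
                "q": r.q,
            }
            for r in results
        ]
    )
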