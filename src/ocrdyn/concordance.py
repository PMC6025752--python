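"""Promoter accessibility vs gene expression concordance.

Each gene is linked to at most one promoter-TSS peak through a
strand-aware window around its TSS (default 1000 bp upstream, 100 bp
downstream). The accessibility-expression relationship is quantified
three ways: per-stage Pearson correlation of log2(x+1)-transformed
promoter openness and RPKM; directional concordance of fold-changes
between stages (2x2 table + two-sided Fisher) restricted to genes with
a >2-fold change in either measure; and selection of the most variable
genes by fold-change and FDR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import GeneModel, Peak
from .stats import bh_fdr, fisher_exact_two_sided
from .dynamics import nb_exact_test


@dataclass
class ContingencyTable2x2:
    """Cells laid out as [[expr-up & ocr-up, expr-up & ocr-down],
    [expr-down & ocr-up, expr-down & ocr-down]]."""

    cells: np.ndarray
    layout: str = "rows: expression up/down vs 1; cols: openness up/down vs 1"

    def __post_init__(self):
        c = np.asarray(self.cells, dtype=np.int64)
        if c.shape != (2, 2) or (c < 0).any():
            raise ValueError("2x2 non-negative integer table required")
        self.cells = c

    @property
    def n(self) -> int:
        return int(self.cells.sum())

    @property
    def concordant(self) -> int:
        return int(self.cells[0, 0] + self.cells[1, 1])


@dataclass
class ConcordanceResult:
    pearson_r: float
    pearson_p: float
    n_genes: int
    table: Optional[ContingencyTable2x2] = None
    fisher_p: Optional[float] = None


def assign_promoter_peak(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    window: Tuple[int, int] = (1000, 100),
) -> Dict[str, str]:
    """Map each gene to the promoter-TSS peak nearest its TSS.

    A candidate peak must overlap the strand-aware promoter window
    (``window = (upstream, downstream)``); among candidates the peak
    whose center is nearest the TSS wins, ties broken by smaller start.
    Genes without a candidate are absent from the result.
    """
    upstream, downstream = window
    by_chrom: Dict[str, list] = {}
    for p in peaks:
        by_chrom.setdefault(p.interval.chrom, []).append(p)
    out: Dict[str, str] = {}
    for gene in genes:
        win = gene.promoter_window(upstream, downstream)
        best = None
        for p in by_chrom.get(win.chrom, []):
            if not p.interval.overlaps(win):
                continue
            dist = abs(p.interval.center - gene.tss)
            key = (dist, p.interval.start)
            if best is None or key < best[0]:
                best = (key, p.peak_id)
        if best is not None:
            out[gene.gene_id] = best[1]
    return out


def stagewise_correlation(
    expr: Mapping[str, float],
    openness: Mapping[str, float],
    log_transform: bool = True,
) -> ConcordanceResult:
    """Pearson correlation of expression vs promoter openness over the
    genes present in both maps.

    Values are log2(x+1)-transformed by default. Raises when fewer than
    3 genes are shared or either vector is constant.
    """
    genes = sorted(set(expr) & set(openness))
    if len(genes) < 3:
        raise ValueError(f"need >=3 shared genes, got {len(genes)}")
    x = np.array([openness[g] for g in genes], dtype=float)
    y = np.array([expr[g] for g in genes], dtype=float)
    if log_transform:
        x = np.log2(x + 1.0)
        y = np.log2(y + 1.0)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = sps.pearsonr(x, y)
    return ConcordanceResult(pearson_r=float(r), pearson_p=float(p), n_genes=len(genes))


def fold_change(a: float, b: float, pseudocount: float = 1.0) -> float:
    """Pseudocounted fold change (a + pc) / (b + pc)."""
    if a < 0 or b < 0:
        raise ValueError("fold change needs non-negative inputs")
    return (a + pseudocount) / (b + pseudocount)


def concordance_test(
    fc_expr: Mapping[str, float],
    fc_ocr: Mapping[str, float],
    fc_threshold: float = 2.0,
) -> Tuple[ContingencyTable2x2, float, int]:
    """Directional concordance of expression and openness fold-changes.

    Keeps genes with FC > threshold or FC < 1/threshold in either
    measure; tabulates up/down (vs 1) in both measures and applies the
    two-sided Fisher test. Genes with FC exactly 1 in either measure
    cannot be oriented and are dropped. An empty selection yields a zero
    table with ``fisher_p = nan`` (a defined no-test result).
    """
    genes = set(fc_expr) & set(fc_ocr)
    table = np.zeros((2, 2), dtype=np.int64)
    n_sel = 0
    for g in genes:
        fe, fo = fc_expr[g], fc_ocr[g]
        if not (
            fe > fc_threshold
            or fe < 1.0 / fc_threshold
            or fo > fc_threshold
            or fo < 1.0 / fc_threshold
        ):
            continue
        if fe == 1.0 or fo == 1.0:
            continue
        n_sel += 1
        row = 0 if fe > 1.0 else 1
        col = 0 if fo > 1.0 else 1
        table[row, col] += 1
    ct = ContingencyTable2x2(table)
    if n_sel == 0:
        return ct, float("nan"), 0
    return ct, fisher_exact_two_sided(table), n_sel


def select_variable_genes(
    expr: pd.DataFrame,
    stage_a: str,
    stage_b: str,
    fold: float = 4.0,
    q_max: float = 0.005,
    q_values: Optional[Mapping[str, float]] = None,
    phi: float = 0.05,
    pseudocount: float = 1.0,
) -> list:
    """Most-variable genes between two stages: |log2 FC| > log2(fold)
    and FDR < q_max.

    When no q-values are supplied, the module's exact NB test is applied
    to the (rounded) expression values of the two stages with BH
    correction across genes.
    """
    if stage_a not in expr.columns or stage_b not in expr.columns:
        raise ValueError("both stages must be expression columns")
    a = expr[stage_a].to_numpy(dtype=float)
    b = expr[stage_b].to_numpy(dtype=float)
    log_fc = np.log2(b + pseudocount) - np.log2(a + pseudocount)
    if q_values is None:
        lib_a = max(a.sum(), 1.0)
        lib_b = max(b.sum(), 1.0)
        p = np.array(
            [
                nb_exact_test([a[i]], [b[i]], [lib_a], [lib_b], phi)
                for i in range(len(expr))
            ]
        )
        q = bh_fdr(p)
    else:
        q = np.array([q_values[g] for g in expr.index])
    keep = (np.abs(log_fc) > math.log2(fold)) & (q < q_max)
    return list(expr.index[keep])
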