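"""Differential openness between consecutive stages and dynamic classes.

Peak read counts are normalized against the total in-peak read count of
each sample (counts per million). Differential accessibility between
consecutive stages uses an exact conditional negative-binomial test with
a method-of-moments common dispersion — a transparent re-implementation
of the qCML-style exact test: replicate counts are depth-equalized to
the geometric-mean library size, summed per condition, and the split of
the grand total is compared with its conditional distribution. With
dispersion 0 the test reduces exactly to the two-sided binomial test.

Each peak is then labeled up/down/flat per transition at FDR alpha
(Benjamini–Hochberg over all transition tests pooled) and assigned the
ordered pair as its dynamic class; six of the nine labels (those without
a sign reversal between transitions plus the single-transition ones) are
the classes expected to be occupied in a monotone differentiation
course, and are flagged in the output.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import GenomicInterval
from .io import stage_groups
from .stats import bh_fdr, conditional_two_sided_p, log_nb_conditional_weights

CANONICAL_CLASSES = ("up-up", "up-flat", "flat-up", "down-down", "down-flat", "flat-down")


@dataclass(frozen=True)
class TransitionResult:
    peak_id: str
    transition: Tuple[str, str]
    log2_fold_change: float
    p_value: float
    q_value: float
    direction: str  # up / down / flat

    def __post_init__(self):
        if self.direction not in ("up", "down", "flat"):
            raise ValueError(f"bad direction {self.direction!r}")


def normalize_counts(raw: pd.DataFrame) -> Tuple[pd.DataFrame, pd.Series]:
    """Counts per million of in-peak reads, plus library sizes.

    value = raw * 1e6 / column_total. Raises on an all-zero column.
    """
    if raw.shape[0] < 1 or raw.shape[1] < 1:
        raise ValueError("count matrix must have >=1 peak and >=1 sample")
    if (raw.to_numpy() < 0).any():
        raise ValueError("negative counts")
    lib_sizes = raw.sum(axis=0)
    if (lib_sizes == 0).any():
        bad = lib_sizes.index[lib_sizes == 0].tolist()
        raise ValueError(f"zero library size for sample(s) {bad}")
    return raw * (1e6 / lib_sizes), lib_sizes


def _equalize_depth(raw: pd.DataFrame, lib_sizes: pd.Series) -> pd.DataFrame:
    """Scale each sample to the geometric-mean library size, rounding to
    the nearest integer."""
    ref = float(np.exp(np.mean(np.log(lib_sizes.astype(float)))))
    return (raw * (ref / lib_sizes)).round().astype(np.int64)


def estimate_common_dispersion(
    raw: pd.DataFrame, groups: Mapping[str, Sequence[str]]
) -> float:
    """Method-of-moments common NB dispersion across peaks.

    On depth-equalized counts, per peak and replicate group with mean m
    and sample variance v the moment estimate is (v - m) / m^2; the
    common value is the median over peaks of the group-averaged estimate,
    clipped at 0.
    """
    _, lib_sizes = normalize_counts(raw)
    eq = _equalize_depth(raw, lib_sizes)
    per_peak: List[float] = []
    for _, row in eq.iterrows():
        ratios = []
        for samples in groups.values():
            if len(samples) < 2:
                continue
            vals = row[list(samples)].to_numpy(dtype=float)
            m = vals.mean()
            if m <= 0:
                continue
            v = vals.var(ddof=1)
            ratios.append((v - m) / m**2)
        if ratios:
            per_peak.append(max(0.0, float(np.mean(ratios))))
    if not per_peak:
        return 0.0
    return float(np.median(per_peak))


def nb_exact_test(
    counts_a: Sequence[float],
    counts_b: Sequence[float],
    lib_sizes_a: Sequence[float],
    lib_sizes_b: Sequence[float],
    phi: float,
) -> float:
    """Exact conditional two-sided NB test for one peak.

    Replicates are depth-equalized to the geometric-mean library size and
    rounded, then summed per condition; the sum of n i.i.d. NB(mu, phi)
    is NB(n*mu, phi/n). Conditional on the grand total the split follows
    a beta-negative-binomial law that depends only on the shape
    parameters; the p-value is the total conditional mass of splits no
    more probable than the observed one. phi=0 gives the exact two-sided
    binomial test with success probability n_a / (n_a + n_b).
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    la = np.asarray(lib_sizes_a, dtype=float)
    lb = np.asarray(lib_sizes_b, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("negative counts")
    if (la <= 0).any() or (lb <= 0).any():
        raise ValueError("library sizes must be positive")
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    libs = np.concatenate([la, lb])
    ref = float(np.exp(np.mean(np.log(libs))))
    sa = int(np.rint(a * (ref / la)).sum())
    sb = int(np.rint(b * (ref / lb)).sum())
    T = sa + sb
    if T == 0:
        return 1.0
    n_a, n_b = a.size, b.size
    if phi == 0:
        lw = sps.binom.logpmf(np.arange(T + 1), T, n_a / (n_a + n_b))
    else:
        lw = log_nb_conditional_weights(T, n_a / phi, n_b / phi)
    return conditional_two_sided_p(lw, sa)


def _direction(log2fc: float, q: float, alpha: float) -> str:
    if q >= alpha or log2fc == 0:
        return "flat"
    return "up" if log2fc > 0 else "down"


def classify_dynamics(
    t1: TransitionResult, t2: TransitionResult, alpha: float = 0.05
) -> str:
    """Ordered pair of per-transition direction labels, e.g. ``up-flat``."""
    d1 = _direction(t1.log2_fold_change, t1.q_value, alpha)
    d2 = _direction(t2.log2_fold_change, t2.q_value, alpha)
    return f"{d1}-{d2}"


def run_dynamics(
    counts: pd.DataFrame,
    stages: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
    phi: Optional[float] = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Full per-peak dynamic classification over consecutive transitions.

    Parameters
    ----------
    counts : raw peak x sample matrix, columns ``<stage>_<replicate>``.
    stages : ordered stage labels; default = order of first appearance.
    phi : common NB dispersion; estimated from the data when ``None``.

    Returns a frame indexed by peak with, per transition i, columns
    ``log2fc_i``, ``p_i``, ``q_i``, ``dir_i``, plus ``dynamic_class`` and
    a ``canonical_class`` flag (classes without a
    sign reversal).
    """
    groups = stage_groups(list(counts.columns))
    if stages is None:
        stages = list(groups)
    missing = [s for s in stages if s not in groups]
    if missing:
        raise ValueError(f"stages {missing} absent from count columns")
    norm, lib_sizes = normalize_counts(counts)
    if phi is None:
        phi = estimate_common_dispersion(counts, {s: groups[s] for s in stages})

    transitions = [(stages[i], stages[i + 1]) for i in range(len(stages) - 1)]
    n_peaks = counts.shape[0]
    res: Dict[str, np.ndarray] = {}
    all_p = []
    for ti, (sa, sb) in enumerate(transitions, start=1):
        cols_a, cols_b = groups[sa], groups[sb]
        p_vals = np.empty(n_peaks)
        fc = np.empty(n_peaks)
        raw_a = counts[cols_a].to_numpy(dtype=float)
        raw_b = counts[cols_b].to_numpy(dtype=float)
        la = lib_sizes[cols_a].to_numpy(dtype=float)
        lb = lib_sizes[cols_b].to_numpy(dtype=float)
        mean_a = norm[cols_a].mean(axis=1).to_numpy()
        mean_b = norm[cols_b].mean(axis=1).to_numpy()
        fc[:] = np.log2(mean_b + pseudocount) - np.log2(mean_a + pseudocount)
        for i in range(n_peaks):
            p_vals[i] = nb_exact_test(raw_a[i], raw_b[i], la, lb, phi)
        res[f"log2fc_{ti}"] = fc
        res[f"p_{ti}"] = p_vals
        all_p.append(p_vals)
    q_all = bh_fdr(np.concatenate(all_p))
    out = pd.DataFrame(index=counts.index)
    classes = None
    for ti in range(1, len(transitions) + 1):
        q = q_all[(ti - 1) * n_peaks : ti * n_peaks]
        out[f"log2fc_{ti}"] = res[f"log2fc_{ti}"]
        out[f"p_{ti}"] = res[f"p_{ti}"]
        out[f"q_{ti}"] = q
        dirs = [
            _direction(fc, qq, alpha) for fc, qq in zip(res[f"log2fc_{ti}"], q)
        ]
        out[f"dir_{ti}"] = dirs
        classes = dirs if classes is None else [f"{c}-{d}" for c, d in zip(classes, dirs)]
    out["dynamic_class"] = classes
    out["canonical_class"] = out["dynamic_class"].isin(CANONICAL_CLASSES)
    out.attrs["phi"] = phi
    out.attrs["stages"] = list(stages)
    return out


# ---------------------------------------------------------------------------
# stage-specific peak sets


class _IntervalIndex:
    """Sorted-start interval index with prefix-max ends for O(log n)
    any-overlap queries."""

    def __init__(self, intervals: Sequence[GenomicInterval]):
        self._by_chrom: Dict[str, Tuple[List[int], List[int]]] = {}
        tmp: Dict[str, List[Tuple[int, int]]] = {}
        for iv in intervals:
            tmp.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for chrom, ivs in tmp.items():
            ivs.sort()
            starts = [s for s, _ in ivs]
            maxend: List[int] = []
            cur = 0
            for _, e in ivs:
                cur = max(cur, e)
                maxend.append(cur)
            self._by_chrom[chrom] = (starts, maxend)

    def overlaps(self, iv: GenomicInterval) -> bool:
        entry = self._by_chrom.get(iv.chrom)
        if entry is None:
            return False
        starts, maxend = entry
        idx = bisect.bisect_left(starts, iv.end)  # intervals with start < end
        return idx > 0 and maxend[idx - 1] > iv.start


@dataclass
class StageSpecificSets:
    specific: Dict[str, List[GenomicInterval]]
    shared: Dict[str, List[GenomicInterval]]  # per stage: calls overlapping another stage

    def sizes(self) -> Dict[str, int]:
        return {s: len(v) for s, v in self.specific.items()}


def stage_specific_peak_sets(
    calls: Mapping[str, Sequence[GenomicInterval]]
) -> StageSpecificSets:
    """Partition each stage's peak calls into stage-specific and shared.

    A peak is stage-specific iff it overlaps (>=1 bp) no peak called in
    any other stage.
    """
    indexes = {s: _IntervalIndex(ivs) for s, ivs in calls.items()}
    specific: Dict[str, List[GenomicInterval]] = {}
    shared: Dict[str, List[GenomicInterval]] = {}
    for stage, ivs in calls.items():
        others = [idx for s, idx in indexes.items() if s != stage]
        spec, shar = [], []
        for iv in ivs:
            if any(idx.overlaps(iv) for idx in others):
                shar.append(iv)
            else:
                spec.append(iv)
        specific[stage] = spec
        shared[stage] = shar
    return StageSpecificSets(specific=specific, shared=shared)
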