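"""PWM scanning, footprint occupancy scoring and motif enrichment.

A TF-binding footprint (TFBF) is a motif occurrence whose core shows
locally depleted Tn5 insertions relative to its immediate flanks. The
occupancy statistic used throughout is the *purity score*

    purity = clip(1 - core_mean / flank_mean, 0, 1)

where ``core_mean`` is the mean insertion rate over the motif interval
and ``flank_mean`` the mean over the two ``flank``-bp windows on either
side. A site with no insertions in the core and accessible flanks scores
1; a flat profile scores 0. Footprints are called at a purity cutoff
(default 0.9), subject to a minimum flank coverage floor that prevents
purity-1 artifacts at uncovered sites.

This score is a deliberately transparent stand-in for generative
footprint posteriors (PIQ-style EM models): the numeric cutoff is reused
but no equivalence between the two scales is claimed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import CoverageTrack, GenomicInterval, Peak
from .stats import fisher_exact_two_sided

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_UNIFORM = np.full(4, 0.25)


@dataclass(frozen=True)
class PWM:
    """A position probability matrix with background and derived log-odds."""

    tf_name: str
    matrix: np.ndarray  # width x 4, rows sum to 1
    background: np.ndarray  # length 4

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError("PWM matrix must be width x 4")
        if m.shape[0] < 4:
            raise ValueError(f"PWM {self.tf_name}: width must be >= 4")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"PWM {self.tf_name}: rows must sum to 1")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0, atol=1e-9):
            raise ValueError("background must be 4 probabilities summing to 1")

    @classmethod
    def from_counts(cls, tf_name, counts, pseudocount: float = 1.0, background=None):
        counts = np.asarray(counts, dtype=float)
        if (counts < 0).any():
            raise ValueError("negative PWM counts")
        probs = counts + pseudocount
        probs = probs / probs.sum(axis=1, keepdims=True)
        bg = _UNIFORM if background is None else np.asarray(background, dtype=float)
        return cls(tf_name=tf_name, matrix=probs, background=bg)

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.matrix / self.background[None, :])

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[j] for j in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(
            tf_name=self.tf_name,
            matrix=self.matrix[::-1, ::-1].copy(),
            background=self.background[::-1].copy(),
        )

    def with_background(self, background) -> "PWM":
        return PWM(self.tf_name, self.matrix, np.asarray(background, dtype=float))


@dataclass(frozen=True)
class MotifHit:
    tf_name: str
    interval: GenomicInterval
    log_odds_score: float


@dataclass(frozen=True)
class Footprint:
    hit: MotifHit
    stage: str
    purity: float
    flank_mean: float
    core_mean: float


@dataclass
class TagDensityProfile:
    """Mean insertion count per offset around motif midpoints."""

    tf_name: str
    stage: str
    window: int
    profile: np.ndarray  # length 2*window + 1
    n_sites: int

    def central_mean(self, half_core: int = 10) -> float:
        c = self.window
        return float(self.profile[c - half_core : c + half_core + 1].mean())

    def flank_mean(self, inner: int = 25) -> float:
        return float(
            np.concatenate(
                [self.profile[: self.window - inner], self.profile[self.window + inner + 1 :]]
            ).mean()
        )


def encode_sequence(seq: str) -> np.ndarray:
    """Bases to indices 0..3; ambiguous bases (N etc.) map to -1."""
    lut = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def genome_background(genome: Mapping[str, str]) -> np.ndarray:
    """Genome-wide mononucleotide frequencies (A,C,G,T), ambiguity ignored."""
    counts = np.zeros(4)
    for seq in genome.values():
        code = encode_sequence(seq)
        counts += np.bincount(code[code >= 0], minlength=4)
    if counts.sum() == 0:
        return _UNIFORM.copy()
    return counts / counts.sum()


def _scan_strand(code: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Log-odds score of every window start; ambiguous bases contribute 0."""
    w = log_odds.shape[0]
    n = code.size - w + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    for j in range(w):
        col = code[j : j + n]
        contrib = np.where(col >= 0, log_odds[j, np.clip(col, 0, 3)], 0.0)
        scores += contrib
    return scores


def scan_sequence(
    genome: Mapping[str, str],
    pwm: PWM,
    threshold_fraction: float = 0.8,
    both_strands: bool = True,
) -> List[MotifHit]:
    """Scan a genome for PWM matches on both strands.

    A window is a hit when its log-odds score is at least
    ``threshold_fraction`` times the maximum attainable score. Reverse-
    strand hits are reported on forward coordinates with strand ``-``.
    """
    if not 0 < threshold_fraction <= 1:
        raise ValueError("threshold_fraction must be in (0, 1]")
    threshold = threshold_fraction * pwm.max_score
    hits: List[MotifHit] = []
    strands = [("+", pwm.log_odds)]
    if both_strands:
        strands.append(("-", pwm.reverse_complement().log_odds))
    for chrom in sorted(genome):
        code = encode_sequence(genome[chrom])
        for strand, lo in strands:
            scores = _scan_strand(code, lo)
            for pos in np.flatnonzero(scores >= threshold - 1e-12):
                hits.append(
                    MotifHit(
                        tf_name=pwm.tf_name,
                        interval=GenomicInterval(chrom, int(pos), int(pos) + pwm.width, strand),
                        log_odds_score=float(scores[pos]),
                    )
                )
    hits.sort(key=lambda h: (h.interval.chrom, h.interval.start, h.interval.strand))
    return hits


def merge_hits(hits: Sequence[MotifHit], min_separation: Optional[int] = None) -> List[MotifHit]:
    """Collapse same-TF hits closer than half a motif width, keeping the
    best-scoring one (ties: earliest position, then + strand)."""
    out: List[MotifHit] = []
    by_key: Dict[str, List[MotifHit]] = {}
    for h in hits:
        by_key.setdefault(h.interval.chrom, []).append(h)
    for chrom in sorted(by_key):
        chrom_hits = sorted(
            by_key[chrom], key=lambda h: (h.interval.start, h.interval.strand)
        )
        cluster: List[MotifHit] = []
        for h in chrom_hits:
            sep = min_separation if min_separation is not None else len(h.interval) // 2
            if cluster and h.interval.start - cluster[-1].interval.start >= max(1, sep):
                out.append(_best_hit(cluster))
                cluster = []
            cluster.append(h)
        if cluster:
            out.append(_best_hit(cluster))
    return out


def _best_hit(cluster: Sequence[MotifHit]) -> MotifHit:
    return max(
        cluster,
        key=lambda h: (h.log_odds_score, -h.interval.start, h.interval.strand == "+"),
    )


def footprint_purity(
    coverage: CoverageTrack,
    hit: MotifHit,
    stage: str,
    flank: int = 50,
    min_flank_coverage: float = 0.2,
) -> Optional[Footprint]:
    """Score one motif hit against one stage's insertion coverage.

    Returns ``None`` (no footprint defined) when the mean flank coverage
    is below ``min_flank_coverage`` insertions/bp. Raises if the flank
    windows do not fit on the chromosome.
    """
    iv = hit.interval
    chrom_len = len(coverage.arrays[iv.chrom])
    if iv.start - flank < 0 or iv.end + flank > chrom_len:
        raise ValueError(
            f"flank windows of {iv.chrom}:{iv.start}-{iv.end} exceed the chromosome"
        )
    core = coverage.slice(iv.chrom, iv.start, iv.end)
    left = coverage.slice(iv.chrom, iv.start - flank, iv.start)
    right = coverage.slice(iv.chrom, iv.end, iv.end + flank)
    core_mean = float(core.mean())
    flank_mean = float(np.concatenate([left, right]).mean())
    if flank_mean < min_flank_coverage:
        return None
    purity = float(np.clip(1.0 - core_mean / flank_mean, 0.0, 1.0))
    return Footprint(hit=hit, stage=stage, purity=purity, flank_mean=flank_mean, core_mean=core_mean)


def call_footprints(
    genome: Mapping[str, str],
    coverage_by_stage: Mapping[str, CoverageTrack],
    pwms: Sequence[PWM],
    purity_cutoff: float = 0.9,
    threshold_fraction: float = 0.8,
    flank: int = 50,
    min_flank_coverage: float = 0.2,
    background: Optional[np.ndarray] = None,
) -> Dict[Tuple[str, str], List[Footprint]]:
    """Scan once, score every (hit, stage) pair, keep footprints passing
    the purity cutoff and the coverage floor.

    Returns a dict keyed by ``(tf_name, stage)``. Each motif instance is
    counted at most once per stage (nearby same-TF hits are merged).
    """
    bg = genome_background(genome) if background is None else background
    result: Dict[Tuple[str, str], List[Footprint]] = {
        (pwm.tf_name, stage): [] for pwm in pwms for stage in coverage_by_stage
    }
    for pwm in pwms:
        hits = merge_hits(scan_sequence(genome, pwm.with_background(bg), threshold_fraction))
        for stage, coverage in coverage_by_stage.items():
            for hit in hits:
                iv = hit.interval
                if iv.start - flank < 0 or iv.end + flank > len(coverage.arrays[iv.chrom]):
                    continue
                fp = footprint_purity(coverage, hit, stage, flank, min_flank_coverage)
                if fp is not None and fp.purity >= purity_cutoff:
                    result[(pwm.tf_name, stage)].append(fp)
    return result


def aggregate_tag_density(
    hits: Sequence[MotifHit],
    coverage: CoverageTrack,
    stage: str,
    window: int = 100,
) -> TagDensityProfile:
    """Mean insertion count per offset around motif midpoints.

    Minus-strand hits are flipped before averaging so that the profile is
    oriented 5'->3' along the motif. Hits whose window does not fit are
    skipped.
    """
    if not hits:
        raise ValueError("no hits to aggregate")
    acc = np.zeros(2 * window + 1)
    n = 0
    tf = hits[0].tf_name
    for h in hits:
        mid = (h.interval.start + h.interval.end) // 2
        lo, hi = mid - window, mid + window + 1
        arr = coverage.arrays[h.interval.chrom]
        if lo < 0 or hi > arr.size:
            continue
        slice_ = arr[lo:hi]
        if h.interval.strand == "-":
            slice_ = slice_[::-1]
        acc += slice_
        n += 1
    if n == 0:
        raise ValueError("no hit fits within the coverage track")
    return TagDensityProfile(tf_name=tf, stage=stage, window=window, profile=acc / n, n_sites=n)


def motif_enrichment_in_peaks(
    hits: Sequence[MotifHit],
    target_peaks: Sequence[Peak],
    background_peaks: Sequence[Peak],
) -> pd.DataFrame:
    """Per-TF enrichment of motif occurrences in target vs background peaks.

    Builds a 2x2 table of (peaks with >=1 hit / without) x (target /
    background); fold = ratio of hit fractions; p = two-sided Fisher.
    """
    by_tf: Dict[str, List[MotifHit]] = {}
    for h in hits:
        by_tf.setdefault(h.tf_name, []).append(h)
    rows = []
    for tf in sorted(by_tf):
        tf_hits = by_tf[tf]
        t_with = _n_peaks_with_hit(target_peaks, tf_hits)
        b_with = _n_peaks_with_hit(background_peaks, tf_hits)
        n_t, n_b = len(target_peaks), len(background_peaks)
        table = [[t_with, n_t - t_with], [b_with, n_b - b_with]]
        frac_t = t_with / n_t if n_t else np.nan
        frac_b = b_with / n_b if n_b else np.nan
        if frac_b == 0:
            fold = np.inf if frac_t > 0 else np.nan
        else:
            fold = frac_t / frac_b
        rows.append(
            {
                "tf": tf,
                "target_with_hit": t_with,
                "target_total": n_t,
                "background_with_hit": b_with,
                "background_total": n_b,
                "fold_enrichment": fold,
                "p": fisher_exact_two_sided(table),
            }
        )
    return pd.DataFrame(rows)


def _n_peaks_with_hit(peaks: Sequence[Peak], hits: Sequence[MotifHit]) -> int:
    # sweep over sorted starts per chromosome
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for h in hits:
        by_chrom.setdefault(h.interval.chrom, []).append((h.interval.start, h.interval.end))
    for v in by_chrom.values():
        v.sort()
    n = 0
    for p in peaks:
        ivs = by_chrom.get(p.interval.chrom, [])
        if any(s < p.interval.end and p.interval.start < e for s, e in ivs):
            n += 1
    return n
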