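"""Synthetic ATAC-seq differentiation experiment with planted ground truth.

Emulates a three-stage differentiation time course (default
hiPSC -> N-d30 -> N-d41, two replicates per stage): a random genome with
strand-aware genes, promoter and distal peaks assigned to dynamic
classes, negative-binomial replicate read counts, base-resolution Tn5
insertion coverage with footprint-protected motif instances, and gene
expression coupled to promoter openness at a controlled Pearson
correlation.

Footprint model: at a bound motif instance, in the stages where it is
bound, the insertion rate over the motif core is multiplied by the
protection factor rho (default 0.1) while the +-flank region is
multiplied by ``flank_boost`` (default 2.0). The elevated flanks
reproduce the characteristic dip-between-two-peaks profile of real TF
footprints and is what makes a protected site separable from shot noise
at a purity cutoff of 1 - rho.

Every random draw flows from ``SimulationConfig.seed`` through fixed
per-step child seeds, so identical configs give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .core import CoverageTrack, GeneModel, GenomicInterval, Peak
from .footprints import PWM
from . import io as gio

DEFAULT_STAGES = ("hiPSC", "N-d30", "N-d41")

#: stage openness multipliers per dynamic class: 4-fold effects per
#: changing transition, with class base levels chosen so the per-stage
#: totals are equal under a uniform class mix (42 per stage). Total
#: accessibility is then stage-constant, so normalization against the
#: per-sample total read count introduces no composition bias.
DEFAULT_MULTIPLIERS: Dict[str, Tuple[float, float, float]] = {
    "up-up": (1.0, 4.0, 16.0),
    "up-flat": (4.0, 16.0, 16.0),
    "flat-up": (1.0, 1.0, 4.0),
    "down-down": (16.0, 4.0, 1.0),
    "down-flat": (4.0, 1.0, 1.0),
    "flat-down": (16.0, 16.0, 4.0),
    "flat-flat": (1.0, 1.0, 1.0),
}

SIX_CLASSES = ("up-up", "up-flat", "flat-up", "down-down", "down-flat", "flat-down")


class PlacementError(RuntimeError):
    """Requested genes/peaks cannot be placed on the configured genome."""


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    genome_length: int = 4_000_000
    n_chromosomes: int = 2
    gc_content: float = 0.41
    n_genes: int = 120
    n_peaks: int = 600
    peak_width_range: Tuple[int, int] = (300, 600)
    stages: Tuple[str, ...] = DEFAULT_STAGES
    replicates_per_stage: int = 2
    mean_depth: float = 200.0
    nb_dispersion: float = 0.05
    dynamic_class_proportions: Dict[str, float] = field(
        default_factory=lambda: {c: 1.0 / 6.0 for c in SIX_CLASSES}
    )
    openness_multipliers: Dict[str, Tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_MULTIPLIERS)
    )
    footprint_protection: float = 0.1  # rho: core insertion rate multiplier
    flank_boost: float = 2.0  # flank insertion rate multiplier at bound sites
    target_pearson_r: Dict[str, float] = field(
        default_factory=lambda: {"hiPSC": 0.21, "N-d30": 0.42, "N-d41": 0.41}
    )
    expression_beta0: float = 0.0
    expression_beta1: float = 0.5
    background_rate: float = 0.05  # insertions/bp/replicate outside signal
    motif_fraction: float = 0.25  # fraction of distal peaks receiving a motif
    bound_fraction: float = 0.5  # fraction of motif-carrying peaks that are bound
    bound_stages: Tuple[str, ...] = ("N-d41",)
    tf_bound_stages: Optional[Dict[str, Tuple[str, ...]]] = None  # per-TF override
    # class forced onto bound-instance peaks; None = pick the class with
    # the largest minimum multiplier over the instance's bound stages, so
    # protected sites sit in strongly open chromatin there
    bound_peak_class: Optional[str] = None
    edges_per_tf: int = 8
    hub_shared_targets: int = 2  # targets shared between consecutive same-stage TFs
    target_window: Tuple[int, int] = (10000, 1000)  # promoter-proximal exclusion for distal peaks
    autoregulation: bool = True
    autoreg_offset: int = -213  # planted self-edge motif offset from the TSS
    replicate_depth_factors: Optional[Tuple[float, ...]] = None
    min_tss_spacing: int = 2000
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not 0 < self.gc_content < 1:
            raise ConfigError("gc_content must be in (0,1)")
        total = sum(self.dynamic_class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"class proportions sum to {total}, expected 1")
        for cls in self.dynamic_class_proportions:
            if cls not in self.openness_multipliers:
                raise ConfigError(f"no openness multipliers for class {cls!r}")
        for cls, mults in self.openness_multipliers.items():
            if len(mults) != len(self.stages):
                raise ConfigError(f"class {cls!r}: need one multiplier per stage")
            if any(m < 0 for m in mults):
                raise ConfigError(f"class {cls!r}: negative multiplier")
        for stage, r in self.target_pearson_r.items():
            if not 0 < r < 1:
                raise ConfigError(
                    f"target_pearson_r[{stage!r}]={r} must lie in the open interval (0,1)"
                )
        if not 0 <= self.footprint_protection <= 1:
            raise ConfigError("footprint_protection must be in [0,1]")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be >= 0")
        if self.peak_width_range[0] > self.peak_width_range[1]:
            raise ConfigError("peak_width_range must be (min, max)")
        if any(s not in self.stages for s in self.bound_stages):
            raise ConfigError("bound_stages must be a subset of stages")
        if self.tf_bound_stages:
            for tf, sts in self.tf_bound_stages.items():
                if any(s not in self.stages for s in sts):
                    raise ConfigError(f"tf_bound_stages[{tf!r}] outside stages")
        if self.replicate_depth_factors is not None and len(
            self.replicate_depth_factors
        ) != self.replicates_per_stage:
            raise ConfigError("need one depth factor per replicate")
        if self.genome_length < 10 * self.n_peaks * self.peak_width_range[1]:
            raise ConfigError(
                "genome_length must be >= 10 * n_peaks * max peak width"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["peak_width_range"] = list(self.peak_width_range)
        d["stages"] = list(self.stages)
        d["bound_stages"] = list(self.bound_stages)
        d["openness_multipliers"] = {k: list(v) for k, v in self.openness_multipliers.items()}
        if self.tf_bound_stages is not None:
            d["tf_bound_stages"] = {k: list(v) for k, v in self.tf_bound_stages.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        for key in ("peak_width_range", "stages", "bound_stages", "target_window", "replicate_depth_factors"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if "openness_multipliers" in d:
            d["openness_multipliers"] = {
                k: tuple(v) for k, v in d["openness_multipliers"].items()
            }
        if d.get("tf_bound_stages") is not None:
            d["tf_bound_stages"] = {k: tuple(v) for k, v in d["tf_bound_stages"].items()}
        return cls(**d)

    @property
    def sample_names(self) -> List[str]:
        return [
            f"{s}_{r + 1}" for s in self.stages for r in range(self.replicates_per_stage)
        ]


@dataclass
class TruthTables:
    peak_class: Dict[str, str] = field(default_factory=dict)
    bound_instances: Dict[Tuple[str, str], Set[str]] = field(default_factory=dict)
    true_edges: Set[Tuple[str, str]] = field(default_factory=set)
    expression_link: Dict[str, Dict[str, Tuple[float, float, float]]] = field(
        default_factory=dict
    )
    gene_peak: Dict[str, str] = field(default_factory=dict)
    autoreg_tf: Optional[str] = None


# ---------------------------------------------------------------------------
# genome + genes


def _chrom_lengths(config: SimulationConfig) -> Dict[str, int]:
    base = config.genome_length // config.n_chromosomes
    return {f"chr{i + 1}": base for i in range(config.n_chromosomes)}


def generate_genome(
    config: SimulationConfig,
) -> Tuple[Dict[str, str], List[GeneModel]]:
    """Random genome (i.i.d. bases at the configured GC) and gene table.

    Genes are placed with strand-aware TSS, no two TSS within
    ``min_tss_spacing`` bp. Raises :class:`PlacementError` when the
    genome cannot hold the requested genes.
    """
    if config.genome_length < 10 * config.n_peaks * config.peak_width_range[1]:
        raise ConfigError(
            "genome_length must be >= 10 * n_peaks * max peak width"
        )
    rng = np.random.default_rng(config.seed)
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome: Dict[str, str] = {}
    for chrom, length in _chrom_lengths(config).items():
        codes = rng.choice(4, size=length, p=probs)
        genome[chrom] = alphabet[codes].tobytes().decode("ascii")

    chroms = list(genome)
    margin = 6000
    gap = config.min_tss_spacing
    per_chrom = _split_evenly(config.n_genes, len(chroms))
    genes: List[GeneModel] = []
    idx = 0
    for chrom, n in zip(chroms, per_chrom):
        length = len(genome[chrom])
        usable = length - 2 * margin - (n - 1) * gap if n > 0 else 0
        if n > 0 and usable <= 0:
            raise PlacementError(
                f"cannot place {n} genes with {gap} bp TSS spacing on {chrom} "
                f"(length {length})"
            )
        if n == 0:
            continue
        offsets = np.sort(rng.integers(0, usable, size=n))
        tss_positions = margin + offsets + gap * np.arange(n)
        for tss in tss_positions:
            idx += 1
            strand = "+" if rng.random() < 0.5 else "-"
            glen = int(rng.integers(2000, 5001))
            if strand == "+":
                start, end = int(tss), min(int(tss) + glen, length)
            else:
                start, end = max(0, int(tss) - glen + 1), int(tss) + 1
            genes.append(
                GeneModel(
                    gene_id=f"gene{idx:04d}",
                    interval=GenomicInterval(chrom, start, end, strand),
                )
            )
    return genome, genes


def _split_evenly(n: int, k: int) -> List[int]:
    base, rem = divmod(n, k)
    return [base + (1 if i < rem else 0) for i in range(k)]


# ---------------------------------------------------------------------------
# peaks + motifs


@dataclass
class PlantedLayout:
    genome: Dict[str, str]
    genes: List[GeneModel]
    peaks: List[Peak]
    peak_classes: Dict[str, str]
    instances: pd.DataFrame
    truth: TruthTables


def _bound_class(config: SimulationConfig, bound_in: Sequence[str]) -> str:
    """Dynamic class for a peak carrying a bound instance: the class
    whose smallest multiplier over the bound stages is largest (ties ->
    lexicographically first)."""
    if config.bound_peak_class is not None:
        return config.bound_peak_class
    idx = [config.stages.index(s) for s in bound_in]
    return max(
        sorted(config.openness_multipliers),
        key=lambda cls: min(config.openness_multipliers[cls][i] for i in idx),
    )


def _allocate_classes(config: SimulationConfig, n: int, rng) -> List[str]:
    """Largest-remainder allocation of dynamic classes (exact counts when
    proportions divide n), shuffled across peaks."""
    classes = sorted(config.dynamic_class_proportions)
    quotas = {c: config.dynamic_class_proportions[c] * n for c in classes}
    counts = {c: int(math.floor(quotas[c])) for c in classes}
    short = n - sum(counts.values())
    for c in sorted(classes, key=lambda c: quotas[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    labels = [c for c in classes for _ in range(counts[c])]
    return list(rng.permutation(labels))


def plant_peaks_and_motifs(
    genome: Mapping[str, str],
    genes: Sequence[GeneModel],
    config: SimulationConfig,
    pwm_set: Sequence[PWM],
) -> PlantedLayout:
    """Place promoter + distal peaks, assign dynamic classes, write motif
    instances into the sequence and record the planted truth.

    The first ``len(pwm_set)`` genes become TF genes (renamed to the TF
    names). Each TF receives ``edges_per_tf`` planted target genes whose
    promoter peaks carry the TF's consensus, bound in ``bound_stages``;
    one TF additionally gets a self-promoter instance at
    ``autoreg_offset`` from its own TSS. A fraction of distal peaks carry
    decoy or bound instances.
    """
    if not pwm_set:
        raise ValueError("pwm_set must be non-empty")
    for pwm in pwm_set:
        if pwm.width > config.peak_width_range[0] // 2:
            raise ValueError(
                f"motif {pwm.tf_name} (width {pwm.width}) too long for peaks "
                f"of width >= {config.peak_width_range[0]}"
            )
    rng = np.random.default_rng(config.seed + 1)
    genome = dict(genome)  # sequences are edited through mutable buffers
    seq_lists = {c: bytearray(s, "ascii") for c, s in genome.items()}
    n_tfs = min(len(pwm_set), len(genes))

    # rename TF genes to the TF names so that expression / network node
    # identities line up
    genes = list(genes)
    tf_gene_ids: Dict[str, str] = {}
    for i in range(n_tfs):
        tf = pwm_set[i].tf_name
        genes[i] = GeneModel(gene_id=tf, interval=genes[i].interval)
        tf_gene_ids[tf] = tf

    widths = rng.integers(
        config.peak_width_range[0], config.peak_width_range[1] + 1, size=config.n_peaks
    )
    truth = TruthTables()
    peaks: List[Peak] = []
    n_prom = min(len(genes), config.n_peaks)
    autoreg_tf = pwm_set[0].tf_name if (config.autoregulation and n_tfs > 0) else None

    flank = 50  # must match the default purity flank so planted sites are scoreable
    for i in range(n_prom):
        g = genes[i]
        w = int(widths[i])
        if autoreg_tf is not None and g.gene_id == autoreg_tf:
            need = 2 * (abs(config.autoreg_offset) + pwm_set[0].width + flank + 10)
            w = max(w, need, config.peak_width_range[1])
        chrom_len = len(genome[g.interval.chrom])
        start = int(np.clip(g.tss - w // 2, 0, chrom_len - w))
        peaks.append(
            Peak(
                peak_id=f"peak{i + 1:06d}",
                interval=GenomicInterval(g.interval.chrom, start, start + w),
            )
        )
        truth.gene_peak[g.gene_id] = peaks[-1].peak_id

    # distal peaks by rejection sampling against an occupancy map; gene
    # promoter-proximal windows are excluded so that distal instances
    # never create TF->gene edges outside the planted truth
    occupied: Dict[str, List[Tuple[int, int]]] = {}
    for p in peaks:
        occupied.setdefault(p.interval.chrom, []).append((p.interval.start, p.interval.end))
    up_w, down_w = config.target_window
    for g in genes:
        win = g.promoter_window(up_w + 500, down_w + 500)
        occupied.setdefault(win.chrom, []).append((win.start, win.end))
    chroms = sorted(genome)
    n_distal = config.n_peaks - n_prom
    placed = 0
    attempts = 0
    max_attempts = 200 * max(1, n_distal)
    pad = 200
    while placed < n_distal:
        attempts += 1
        if attempts > max_attempts:
            raise PlacementError(
                f"could not place {n_distal} distal peaks after {attempts} attempts"
            )
        w = int(widths[n_prom + placed])
        chrom = chroms[int(rng.integers(len(chroms)))]
        chrom_len = len(genome[chrom])
        start = int(rng.integers(0, chrom_len - w))
        ivs = occupied.setdefault(chrom, [])
        if any(start - pad < e and s < start + w + pad for s, e in ivs):
            continue
        ivs.append((start, start + w))
        placed += 1
        peaks.append(
            Peak(
                peak_id=f"peak{n_prom + placed:06d}",
                interval=GenomicInterval(chrom, start, start + w),
            )
        )

    class_labels = _allocate_classes(config, config.n_peaks, rng)
    peak_classes = {p.peak_id: c for p, c in zip(peaks, class_labels)}
    peak_by_id = {p.peak_id: p for p in peaks}

    # --- motif instances ------------------------------------------------
    inst_rows: List[dict] = []

    def add_instance(pwm: PWM, peak: Peak, core_start: int, bound: bool) -> None:
        iid = f"inst{len(inst_rows) + 1:06d}"
        chrom = peak.interval.chrom
        seq_lists[chrom][core_start : core_start + pwm.width] = pwm.consensus.encode("ascii")
        bound_in = tuple(config.bound_stages)
        if config.tf_bound_stages and pwm.tf_name in config.tf_bound_stages:
            bound_in = tuple(config.tf_bound_stages[pwm.tf_name])
        inst_rows.append(
            {
                "instance_id": iid,
                "tf": pwm.tf_name,
                "chrom": chrom,
                "start": core_start,
                "end": core_start + pwm.width,
                "strand": "+",
                "peak_id": peak.peak_id,
                "bound": bound,
                "bound_stages": ",".join(bound_in) if bound else "",
            }
        )
        if bound:
            peak_classes[peak.peak_id] = _bound_class(config, bound_in)
            for stage in bound_in:
                truth.bound_instances.setdefault((pwm.tf_name, stage), set()).add(iid)

    def center_offset_slot(peak: Peak, width: int) -> int:
        """A core start near the peak center with full flank clearance."""
        lo = peak.interval.start + flank + 5
        hi = peak.interval.end - flank - width - 5
        mid = (peak.interval.start + peak.interval.end) // 2 - width // 2
        return int(np.clip(mid, lo, hi))

    # network edges: TF -> disjoint target genes, planted in promoters
    non_tf_genes = [g for g in genes[n_tfs:n_prom]]
    cursor = 0
    lead_targets: Dict[str, List[str]] = {}
    for i in range(n_tfs):
        pwm = pwm_set[i]
        for j in range(config.edges_per_tf):
            if cursor >= len(non_tf_genes):
                break
            target = non_tf_genes[cursor]
            cursor += 1
            peak = peak_by_id[truth.gene_peak[target.gene_id]]
            add_instance(pwm, peak, center_offset_slot(peak, pwm.width), bound=True)
            truth.true_edges.add((pwm.tf_name, target.gene_id))
            if j < config.hub_shared_targets:
                lead_targets.setdefault(pwm.tf_name, []).append(target.gene_id)

    # consecutive TFs bound in the same stages share targets, connecting
    # the planted hub-and-spoke stars into one component per stage
    def _bound_in(tf: str) -> Tuple[str, ...]:
        if config.tf_bound_stages and tf in config.tf_bound_stages:
            return tuple(config.tf_bound_stages[tf])
        return tuple(config.bound_stages)

    if config.hub_shared_targets > 0 and config.edges_per_tf > 0:
        for i in range(n_tfs - 1):
            tf_a, tf_b = pwm_set[i].tf_name, pwm_set[i + 1].tf_name
            if _bound_in(tf_a) != _bound_in(tf_b):
                continue
            for gene_id in lead_targets.get(tf_a, []):
                if (tf_b, gene_id) in truth.true_edges:
                    continue
                peak = peak_by_id[truth.gene_peak[gene_id]]
                pwm_b = pwm_set[i + 1]
                slot = center_offset_slot(peak, pwm_b.width) + 3 * pwm_b.width
                slot = min(slot, peak.interval.end - flank - pwm_b.width - 5)
                add_instance(pwm_b, peak, slot, bound=True)
                truth.true_edges.add((tf_b, gene_id))

    if autoreg_tf is not None:
        g = next(g for g in genes if g.gene_id == autoreg_tf)
        pwm = pwm_set[0]
        if g.strand == "+":
            core_start = g.tss + config.autoreg_offset
        else:
            core_start = g.tss - config.autoreg_offset - (pwm.width - 1)
        peak = peak_by_id[truth.gene_peak[autoreg_tf]]
        add_instance(pwm, peak, core_start, bound=True)
        truth.true_edges.add((autoreg_tf, autoreg_tf))
        truth.autoreg_tf = autoreg_tf

    # distal decoy / bound instances, round-robin over PWMs
    distal = peaks[n_prom:]
    n_with_motif = int(round(config.motif_fraction * len(distal)))
    chosen = rng.permutation(len(distal))[:n_with_motif]
    for j, pi in enumerate(sorted(chosen)):
        peak = distal[pi]
        pwm = pwm_set[j % n_tfs] if n_tfs else pwm_set[0]
        bound = rng.random() < config.bound_fraction
        add_instance(pwm, peak, center_offset_slot(peak, pwm.width), bound=bound)

    truth.peak_class = dict(peak_classes)
    genome_out = {c: s.decode("ascii") for c, s in seq_lists.items()}
    instances = pd.DataFrame(
        inst_rows,
        columns=[
            "instance_id",
            "tf",
            "chrom",
            "start",
            "end",
            "strand",
            "peak_id",
            "bound",
            "bound_stages",
        ],
    )
    return PlantedLayout(
        genome=genome_out,
        genes=genes,
        peaks=peaks,
        peak_classes=peak_classes,
        instances=instances,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# counts + coverage


def _nb_draw(rng, mean: float, phi: float) -> int:
    if mean <= 0:
        return 0
    if phi == 0:
        return int(rng.poisson(mean))
    r = 1.0 / phi
    return int(rng.negative_binomial(r, r / (r + mean)))


def simulate_counts_and_coverage(
    layout: PlantedLayout,
    config: SimulationConfig,
    make_coverage: bool = True,
) -> Tuple[pd.DataFrame, Dict[str, CoverageTrack], pd.DataFrame]:
    """Replicate peak counts and per-stage insertion coverage.

    Per replicate, a peak's count is NB(mean_depth * stage multiplier *
    relative width, nb_dispersion) signal plus Poisson background. The
    stage coverage distributes the stage's summed count over the peak's
    bases (raised-cosine bump plus uniform background component) with a
    multinomial draw, so base-level insertions inside a peak sum exactly
    to the reported counts. Bound motif instances reweight their core by
    rho and their flanks by ``flank_boost`` in the bound stages.

    Returns ``(counts, coverage_by_stage, calls)`` where ``calls`` is a
    per-peak per-stage boolean open/closed table (multiplier >= 1).
    """
    rng = np.random.default_rng(config.seed + 2)
    stages = list(config.stages)
    reps = config.replicates_per_stage
    depth_factors = (
        list(config.replicate_depth_factors)
        if config.replicate_depth_factors is not None
        else [1.0] * reps
    )
    mean_width = float(np.mean(config.peak_width_range))
    chrom_sizes = {c: len(s) for c, s in layout.genome.items()}

    inst_by_peak: Dict[str, List[Tuple[int, int, Set[str]]]] = {}
    for row in layout.instances.itertuples():
        stages_bound = set(row.bound_stages.split(",")) if row.bound else set()
        inst_by_peak.setdefault(row.peak_id, []).append((row.start, row.end, stages_bound))

    counts = np.zeros((len(layout.peaks), len(stages) * reps), dtype=np.int64)
    coverage: Dict[str, np.ndarray] = {}
    if make_coverage:
        coverage = {
            s: {c: rng.poisson(config.background_rate * reps, size=n).astype(float)
                for c, n in chrom_sizes.items()}
            for s in stages
        }

    flank = 50
    calls = np.zeros((len(layout.peaks), len(stages)), dtype=bool)
    for pi, peak in enumerate(layout.peaks):
        cls = layout.peak_classes[peak.peak_id]
        mults = config.openness_multipliers[cls]
        w = len(peak.interval)
        rel_w = w / mean_width
        offs = np.arange(w)
        cosine = 1.0 + np.cos(2.0 * np.pi * (offs - (w - 1) / 2.0) / w)
        for si, stage in enumerate(stages):
            mu = config.mean_depth * mults[si] * rel_w
            calls[pi, si] = mults[si] >= 1.0
            sig_total = 0
            bg_total = 0
            for ri in range(reps):
                sig = _nb_draw(rng, mu * depth_factors[ri], config.nb_dispersion)
                bg = int(rng.poisson(config.background_rate * w * depth_factors[ri]))
                counts[pi, si * reps + ri] = sig + bg
                sig_total += sig
                bg_total += bg
            if not make_coverage:
                continue
            total = sig_total + bg_total
            arr = coverage[stage][peak.interval.chrom]
            # replace the background already drawn genome-wide
            arr[peak.interval.start : peak.interval.end] = 0.0
            if total == 0:
                continue
            mu_stage = mu * sum(depth_factors)
            weights = cosine / cosine.sum() * mu_stage + config.background_rate * reps
            for core_start, core_end, stages_bound in inst_by_peak.get(peak.peak_id, []):
                if stage not in stages_bound:
                    continue
                lo, hi = core_start - peak.interval.start, core_end - peak.interval.start
                weights[max(0, lo - flank) : max(0, lo)] *= config.flank_boost
                weights[min(w, hi) : min(w, hi + flank)] *= config.flank_boost
                weights[max(0, lo) : min(w, hi)] *= config.footprint_protection
            wsum = weights.sum()
            if wsum == 0:
                continue
            arr[peak.interval.start : peak.interval.end] += rng.multinomial(
                total, weights / wsum
            )

    sample_names = [f"{s}_{r + 1}" for s in stages for r in range(reps)]
    counts_df = pd.DataFrame(
        counts, index=[p.peak_id for p in layout.peaks], columns=sample_names
    )
    calls_df = pd.DataFrame(
        calls, index=[p.peak_id for p in layout.peaks], columns=stages
    )
    tracks = (
        {s: CoverageTrack(arrs) for s, arrs in coverage.items()} if make_coverage else {}
    )
    return counts_df, tracks, calls_df


# ---------------------------------------------------------------------------
# expression


def promoter_openness(
    counts: pd.DataFrame, gene_peak: Mapping[str, str], stages: Sequence[str]
) -> pd.DataFrame:
    """Per-gene per-stage normalized promoter accessibility (CPM averaged
    over a stage's replicates)."""
    from .dynamics import normalize_counts

    norm, _ = normalize_counts(counts)
    groups = gio.stage_groups(list(counts.columns))
    pairs = [(g, p) for g, p in gene_peak.items() if p in norm.index]
    if not pairs:
        return pd.DataFrame(columns=list(stages))
    sub = norm.loc[[p for _, p in pairs]]
    out = pd.DataFrame(
        {s: sub[groups[s]].mean(axis=1).to_numpy() for s in stages},
        index=[g for g, _ in pairs],
    )
    return out.loc[:, list(stages)]


def simulate_expression(
    openness: pd.DataFrame,
    config: SimulationConfig,
    truth: Optional[TruthTables] = None,
    force_sigma: Optional[float] = None,
) -> pd.DataFrame:
    """Expression (RPKM) linked to promoter openness at a target Pearson R.

    Per stage, log2(RPKM+1) = b0 + b1 * log2(openness+1) + eps with
    sigma_eps chosen in closed form from the population identity
    R = b1*sx / sqrt(b1^2 sx^2 + sigma^2), sx estimated from the
    generated openness. ``force_sigma`` overrides the closed form (0
    gives an exactly deterministic link).
    """
    rng = np.random.default_rng(config.seed + 3)
    b0, b1 = config.expression_beta0, config.expression_beta1
    out = {}
    for stage in config.stages:
        r_target = config.target_pearson_r.get(stage)
        if r_target is None:
            raise ConfigError(f"no target_pearson_r for stage {stage!r}")
        x = np.log2(openness[stage].to_numpy(dtype=float) + 1.0)
        sx = float(x.std())
        if sx == 0:
            raise ConfigError(f"constant promoter openness in stage {stage!r}")
        if force_sigma is not None:
            sigma = float(force_sigma)
        else:
            sigma = abs(b1) * sx * math.sqrt(1.0 / r_target**2 - 1.0)
        y = b0 + b1 * x + rng.normal(0.0, sigma, size=x.size)
        out[stage] = np.maximum(0.0, np.exp2(y) - 1.0)
        if truth is not None:
            for gene in openness.index:
                truth.expression_link.setdefault(gene, {})[stage] = (b0, b1, sigma)
    return pd.DataFrame(out, index=openness.index).loc[:, list(config.stages)]


# ---------------------------------------------------------------------------
# TF footprint-count simulation (specificity recovery substrate)


def simulate_tf_footprint_counts(
    n_tfs: int,
    n_specific: int,
    stages: Sequence[str] = DEFAULT_STAGES,
    baseline: float = 100.0,
    fold: float = 5.0,
    seed: int = 0,
) -> Tuple[pd.DataFrame, Dict[str, str]]:
    """Poisson per-TF per-stage footprint counts with ``n_specific`` TFs
    planted at a ``fold`` excess in one stage (round-robin).

    Returns the count table and the planted truth (tf -> specific stage,
    absent for null TFs).
    """
    rng = np.random.default_rng(seed)
    stages = list(stages)
    counts = np.empty((n_tfs, len(stages)), dtype=np.int64)
    truth: Dict[str, str] = {}
    names = [f"TF{i + 1:03d}" for i in range(n_tfs)]
    for i in range(n_tfs):
        means = np.full(len(stages), baseline)
        if i < n_specific:
            stage = stages[i % len(stages)]
            means[stages.index(stage)] *= fold
            truth[names[i]] = stage
        counts[i] = rng.poisson(means)
    return pd.DataFrame(counts, index=names, columns=stages), truth


# ---------------------------------------------------------------------------
# one-shot simulation + serialization


@dataclass
class SimulationResult:
    config: SimulationConfig
    genome: Dict[str, str]
    genes: List[GeneModel]
    peaks: List[Peak]
    instances: pd.DataFrame
    truth: TruthTables
    counts: pd.DataFrame
    coverage: Dict[str, CoverageTrack]
    calls: pd.DataFrame
    openness: pd.DataFrame
    expression: pd.DataFrame
    pwms: List[PWM]


def demo_pwms(n: int = 3, width: int = 10, seed: int = 7, names: Optional[Sequence[str]] = None) -> List[PWM]:
    """Sharp synthetic PWMs with distinct random consensus sequences."""
    rng = np.random.default_rng(seed)
    pwms = []
    seen = set()
    names = list(names) if names is not None else [f"TF{i + 1}" for i in range(n)]
    while len(pwms) < n:
        consensus = tuple(rng.integers(0, 4, size=width))
        if consensus in seen:
            continue
        seen.add(consensus)
        counts = np.full((width, 4), 1.0)
        for j, b in enumerate(consensus):
            counts[j, b] = 100.0
        pwms.append(PWM.from_counts(names[len(pwms)], counts, pseudocount=1.0))
    return pwms


def run_simulation(
    config: SimulationConfig,
    pwms: Optional[Sequence[PWM]] = None,
    make_coverage: bool = True,
) -> SimulationResult:
    """Generate the complete synthetic experiment in memory."""
    if pwms is None:
        pwms = demo_pwms(3, seed=config.seed + 7)
    genome, genes = generate_genome(config)
    layout = plant_peaks_and_motifs(genome, genes, config, pwms)
    counts, coverage, calls = simulate_counts_and_coverage(
        layout, config, make_coverage=make_coverage
    )
    openness = promoter_openness(counts, layout.truth.gene_peak, config.stages)
    expression = simulate_expression(openness, config, truth=layout.truth)
    return SimulationResult(
        config=config,
        genome=layout.genome,
        genes=layout.genes,
        peaks=layout.peaks,
        instances=layout.instances,
        truth=layout.truth,
        counts=counts,
        coverage=coverage,
        calls=calls,
        openness=openness,
        expression=expression,
        pwms=list(pwms),
    )


def write_simulation(result: SimulationResult, outdir) -> Dict[str, str]:
    """Write every artifact of a simulation to ``outdir``; returns the
    path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, str] = {}

    def _p(name: str) -> str:
        paths[name] = str(outdir / name)
        return paths[name]

    gio.write_fasta(_p("genome.fa"), result.genome)
    gio.write_genes_bed(_p("genes.bed"), result.genes)
    gio.write_bed(
        _p("peaks.bed"), [(p.interval, p.peak_id, 0.0) for p in result.peaks]
    )
    result.calls.to_csv(_p("calls.tsv"), sep="\t", index_label="peak_id")
    gio.write_counts(_p("counts.tsv"), result.counts)
    for stage, track in result.coverage.items():
        gio.write_bedgraph(_p(f"coverage_{stage}.bedGraph"), track)
    gio.write_expression(_p("expression.tsv"), result.expression)
    gio.write_jaspar(_p("pwms.jaspar"), result.pwms)
    gio.write_yaml(_p("config.yaml"), result.config.to_dict())
    result.instances.to_csv(_p("instances.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [(k, v) for k, v in result.truth.peak_class.items()],
        columns=["peak_id", "dynamic_class"],
    ).to_csv(_p("truth_peak_class.tsv"), sep="\t", index=False)
    pd.DataFrame(
        sorted(result.truth.true_edges), columns=["tf", "target"]
    ).to_csv(_p("truth_edges.tsv"), sep="\t", index=False)
    return paths
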