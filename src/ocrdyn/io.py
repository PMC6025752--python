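"""Readers and writers for every on-disk format the pipeline touches.

Formats: FASTA (genome), BED (peaks / genes / footprints), bedGraph
(per-stage insertion coverage), TSV matrices (counts, expression, truth
tables), JASPAR-style PWM text, GMT gene sets, YAML configs, GraphML +
edge-TSV network exports.

Dialect rules enforced everywhere: tab separation, 0-based half-open
coordinates, ``track``/``browser``/``#`` lines skipped in BED. Count
matrix columns follow the ``<stage>_<replicate>`` convention; the stage
factor of a sample is the part before the last underscore.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import CoverageTrack, GeneModel, GenomicInterval

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """A per-line parse failure; carries file and line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> Dict[str, str]:
    """Genome sequences as a dict chrom -> uppercase string."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# BED


def _is_skippable(line: str) -> bool:
    s = line.strip()
    return (
        not s
        or s.startswith("#")
        or s.startswith("track")
        or s.startswith("browser")
    )


def read_bed(path) -> List[Tuple[GenomicInterval, str, float]]:
    """Parse a BED file into ``(interval, name, score)`` triples.

    Name defaults to ``""`` and score to ``0.0`` when columns 4-5 are
    absent; strand is taken from column 6 when present.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_skippable(line):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(path, lineno, f"need >=3 BED columns, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(path, lineno, f"non-integer coordinates: {exc}")
            if start < 0 or start >= end:
                raise ParseError(
                    path, lineno, f"invalid interval [{start}, {end}) on {chrom}"
                )
            name = fields[3] if len(fields) > 3 else ""
            score = float(fields[4]) if len(fields) > 4 and fields[4] not in (".", "") else 0.0
            strand = fields[5] if len(fields) > 5 else "."
            out.append((GenomicInterval(chrom, start, end, strand), name, score))
    return out


def write_bed(path, records: Iterable[Tuple[GenomicInterval, str, float]]) -> None:
    """Write ``(interval, name, score)`` triples as BED6."""
    with open(path, "w") as fh:
        for iv, name, score in records:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name or '.'}\t{score:g}\t{iv.strand}\n"
            )


def read_genes_bed(path) -> List[GeneModel]:
    """Gene models from BED6 (name = gene_id, strand required)."""
    genes = []
    for iv, name, _score in read_bed(path):
        if iv.strand not in ("+", "-"):
            raise ValueError(f"gene {name!r} in {path} lacks a +/- strand")
        genes.append(GeneModel(gene_id=name, interval=iv))
    return genes


def write_genes_bed(path, genes: Sequence[GeneModel]) -> None:
    write_bed(path, [(g.interval, g.gene_id, 0.0) for g in genes])


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(path, chrom_sizes: Mapping[str, int]) -> CoverageTrack:
    """A bedGraph as a dense per-base CoverageTrack.

    Intervals must be non-overlapping and lie within ``chrom_sizes``;
    uncovered positions are 0.
    """
    arrays = {c: np.zeros(n, dtype=float) for c, n in chrom_sizes.items()}
    seen = {c: np.zeros(n, dtype=bool) for c, n in chrom_sizes.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_skippable(line):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(path, lineno, "need 4 bedGraph columns")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if chrom not in arrays:
                raise ParseError(path, lineno, f"unknown chromosome {chrom!r}")
            if start < 0 or start >= end or end > len(arrays[chrom]):
                raise ParseError(path, lineno, f"interval [{start},{end}) outside {chrom}")
            if seen[chrom][start:end].any():
                raise ParseError(path, lineno, f"overlapping interval [{start},{end}) on {chrom}")
            arrays[chrom][start:end] = value
            seen[chrom][start:end] = True
    return CoverageTrack(arrays)


def write_bedgraph(path, track: CoverageTrack) -> None:
    """Run-length encode a CoverageTrack; zero runs are omitted."""
    with open(path, "w") as fh:
        for chrom in sorted(track.arrays):
            arr = track.arrays[chrom]
            if arr.size == 0:
                continue
            # boundaries of constant runs
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


# ---------------------------------------------------------------------------
# TSV matrices


def read_counts(path) -> pd.DataFrame:
    """Peak x sample integer count matrix; rows indexed by peak_id,
    columns named ``<stage>_<replicate>``."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate peak ids in {path}: {dups[:5]}")
    if df.columns.duplicated().any():
        raise ValueError(f"duplicate sample columns in {path}")
    return df


def write_counts(path, counts: pd.DataFrame) -> None:
    counts.to_csv(path, sep="\t", index_label="peak_id")


def sample_stage(sample: str) -> str:
    """Stage factor of a ``<stage>_<replicate>`` sample name."""
    stage, _, rep = sample.rpartition("_")
    if not stage or not rep:
        raise ValueError(f"sample {sample!r} does not follow <stage>_<replicate>")
    return stage


def stage_groups(samples: Sequence[str]) -> Dict[str, List[str]]:
    """Group sample names by their stage prefix, preserving order."""
    groups: Dict[str, List[str]] = {}
    for s in samples:
        groups.setdefault(sample_stage(s), []).append(s)
    return groups


def read_expression(path) -> pd.DataFrame:
    """Gene x stage RPKM table."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError(f"duplicate gene ids in {path}")
    if (df.to_numpy() < 0).any():
        raise ValueError(f"negative RPKM values in {path}")
    return df


def write_expression(path, expr: pd.DataFrame) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# JASPAR-style PWMs


def read_jaspar(path, pseudocount: float = 1.0, background=None):
    """Parse JASPAR-style count matrices into :class:`~ocrdyn.footprints.PWM`.

    Accepts both the bracketed 4-row layout::

        >MA0000.1 TF1
        A [ 8  0  0 ]
        C [ 0  8  0 ]
        ...

    and bare whitespace-separated rows in A,C,G,T order.
    """
    from .footprints import PWM  # local import to avoid a cycle

    pwms = []
    name = None
    rows: Dict[str, List[float]] = {}
    order = "ACGT"

    def flush():
        if name is None:
            return
        if set(rows) != set(order):
            raise ValueError(f"PWM {name!r}: need exactly A,C,G,T rows, got {sorted(rows)}")
        counts = np.array([rows[b] for b in order], dtype=float).T  # width x 4
        pwms.append(PWM.from_counts(name, counts, pseudocount=pseudocount, background=background))

    with open(path) as fh:
        row_cursor = 0
        for line in fh:
            s = line.strip()
            if not s:
                continue
            if s.startswith(">"):
                flush()
                parts = s[1:].split()
                # prefer the TF name over the matrix accession when both given
                name = parts[1] if len(parts) > 1 else parts[0]
                rows = {}
                row_cursor = 0
                continue
            body = s.replace("[", " ").replace("]", " ")
            fields = body.split()
            if fields and fields[0].upper() in order and not _is_number(fields[0]):
                base = fields[0].upper()
                values = [float(x) for x in fields[1:]]
            else:
                base = order[row_cursor]
                row_cursor += 1
                values = [float(x) for x in fields]
            rows[base] = values
    flush()
    return pwms


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def write_jaspar(path, pwms) -> None:
    """Write PWMs back out as bracketed JASPAR count-style matrices
    (probabilities scaled by 100)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.tf_name} {pwm.tf_name}\n")
            for j, base in enumerate("ACGT"):
                vals = " ".join(f"{100 * v:.4f}" for v in pwm.matrix[:, j])
                fh.write(f"{base} [ {vals} ]\n")


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path) -> Dict[str, set]:
    """GMT: tab-separated set name, description, member genes."""
    sets: Dict[str, set] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.rstrip("\n")
            if not s.strip():
                continue
            fields = s.split("\t")
            if len(fields) < 3:
                logger.warning("%s:%d: skipping short GMT line", path, lineno)
                continue
            name = fields[0]
            members = {g for g in fields[2:] if g}
            if not members:
                logger.warning("%s:%d: skipping empty gene set %r", path, lineno, name)
                continue
            sets[name] = members
    return sets


def write_gmt(path, sets: Mapping[str, Iterable[str]]) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write(name + "\tna\t" + "\t".join(sorted(members)) + "\n")


# ---------------------------------------------------------------------------
# YAML config / generic tables


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_yaml(path, obj: Mapping) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(obj), fh, sort_keys=True)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(path, df: pd.DataFrame, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


# ---------------------------------------------------------------------------
# Networks


def write_graphml(path, graph) -> None:
    import networkx as nx

    nx.write_graphml(graph, str(path))


def read_graphml(path):
    import networkx as nx

    return nx.read_graphml(str(path))


def write_edge_tsv(path, graph) -> None:
    """Flat TF -> target edge export with supporting-footprint count."""
    rows = []
    for u, v, data in graph.edges(data=True):
        rows.append(
            {
                "tf": u,
                "target": v,
                "n_footprints": data.get("n_footprints", 1),
            }
        )
    write_table(path, pd.DataFrame(rows, columns=["tf", "target", "n_footprints"]))
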