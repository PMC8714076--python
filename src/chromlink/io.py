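"""Readers and writers for the plain-text genomics formats the pipeline touches.

Formats: BED3/BED6, 10-column narrowPeak, TAD BED, bedGraph score
tracks, GTF-lite gene rows, TSV gene tables, and a minimal MEME-like
count-matrix format for motifs. Floats are serialized with 6
significant digits.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import (
    GenomicInterval,
    GeneModel,
    Peak,
    ScoreTrack,
    TAD,
    ValidationError,
    validate_nonoverlapping_tads,
)
from .motifs import PWM

__all__ = [
    "ParseError",
    "read_bed",
    "write_bed",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_tads",
    "read_gene_models",
    "write_gene_models",
    "read_bedgraph",
    "write_bedgraph",
    "read_pwms",
    "write_pwms",
]

FLOAT_FMT = "%.6g"


class ParseError(ValueError):
    """Raised for a malformed line; names the file and line number."""

    def __init__(self, path: str, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = path
        self.lineno = lineno


def _fields(path: str, min_cols: int):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < min_cols:
                raise ParseError(path, lineno, f"expected >= {min_cols} columns, got {len(cols)}")
            yield lineno, cols


def _interval(path: str, lineno: int, chrom: str, start: str, end: str) -> GenomicInterval:
    try:
        s, e = int(start), int(end)
    except ValueError as exc:
        raise ParseError(path, lineno, f"non-integer coordinate: {exc}")
    try:
        return GenomicInterval(chrom, s, e)
    except ValidationError as exc:
        raise ParseError(path, lineno, str(exc))


def read_bed(path: str) -> List[GenomicInterval]:
    """Read BED3+ as plain intervals (extra columns ignored)."""
    return [_interval(path, ln, c[0], c[1], c[2]) for ln, c in _fields(path, 3)]


def write_bed(intervals: Sequence[GenomicInterval], path: str, names: Optional[Sequence[str]] = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            row = [iv.chrom, str(iv.start), str(iv.end)]
            if names is not None:
                row.append(names[i])
            fh.write("\t".join(row) + "\n")


def read_narrowpeak(path: str, replicate_id: str = "") -> List[Peak]:
    """Read 10-column narrowPeak.

    Column 8 is -log10(p) and is converted to a linear p-value. Column
    10 is the summit offset from ``start``; ``-1`` means no summit was
    called, in which case the interval midpoint is used.
    """
    peaks: List[Peak] = []
    for lineno, c in _fields(path, 10):
        iv = _interval(path, lineno, c[0], c[1], c[2])
        try:
            neglog_p = float(c[7])
            offset = int(c[9])
        except ValueError as exc:
            raise ParseError(path, lineno, f"bad narrowPeak numeric field: {exc}")
        summit = iv.start + offset if offset >= 0 else iv.start + len(iv) // 2
        try:
            peaks.append(
                Peak(
                    interval=iv,
                    summit=summit,
                    pvalue=10.0 ** (-neglog_p),
                    replicate_id=replicate_id,
                    name=None if c[3] in (".", "") else c[3],
                )
            )
        except ValidationError as exc:
            raise ParseError(path, lineno, str(exc))
    return peaks


def write_narrowpeak(peaks: Sequence[Peak], path: str) -> None:
    """Write 10-column narrowPeak; -log10(p) in column 8, summit offset in column 10."""
    with open(path, "w") as fh:
        for p in peaks:
            neglog_p = -math.log10(p.pvalue)
            fh.write(
                "\t".join(
                    [
                        p.interval.chrom,
                        str(p.interval.start),
                        str(p.interval.end),
                        p.name or ".",
                        "0",
                        ".",
                        "0",
                        FLOAT_FMT % neglog_p,
                        "-1",
                        str(p.summit - p.interval.start),
                    ]
                )
                + "\n"
            )


def read_tads(path: str) -> List[TAD]:
    """Read TADs from BED; validates that TADs do not overlap per chromosome."""
    tads = []
    for lineno, c in _fields(path, 3):
        iv = _interval(path, lineno, c[0], c[1], c[2])
        tad_id = c[3] if len(c) > 3 and c[3] not in (".", "") else f"tad_{lineno}"
        tads.append(TAD(interval=iv, tad_id=tad_id))
    validate_nonoverlapping_tads(tads)
    return tads


def read_gene_models(path: str, format: str = "tsv") -> List[GeneModel]:
    """Read gene models.

    ``tsv``: columns gene_id, chrom, start, end, strand with 0-based
    half-open coordinates and a header line.
    ``gtf``: GTF-lite rows (feature == "gene", 1-based inclusive
    coordinates, ``gene_id "X"`` attribute) converted to 0-based
    half-open on read.
    """
    genes: List[GeneModel] = []
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        for i, row in df.iterrows():
            genes.append(
                GeneModel(
                    gene_id=str(row["gene_id"]),
                    interval=GenomicInterval(row["chrom"], int(row["start"]), int(row["end"])),
                    strand=str(row["strand"]),
                )
            )
    elif format == "gtf":
        for lineno, c in _fields(path, 9):
            if c[2] != "gene":
                continue
            attr = c[8]
            gene_id = ""
            for part in attr.split(";"):
                part = part.strip()
                if part.startswith("gene_id"):
                    gene_id = part.split(None, 1)[1].strip().strip('"')
            if not gene_id:
                raise ParseError(path, lineno, "missing gene_id attribute")
            iv = _interval(path, lineno, c[0], str(int(c[3]) - 1), c[4])
            if c[6] not in ("+", "-"):
                raise ParseError(path, lineno, f"unknown strand {c[6]!r}")
            genes.append(GeneModel(gene_id=gene_id, interval=iv, strand=c[6]))
    else:
        raise ValueError(f"unknown gene model format {format!r}")
    seen = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValidationError(f"duplicate gene_id {g.gene_id!r}")
        seen.add(g.gene_id)
    return genes


def write_gene_models(genes: Sequence[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\tstrand\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.interval.start}\t{g.interval.end}\t{g.strand}\n")


def read_bedgraph(path: str, chrom_sizes: Optional[Dict[str, int]] = None) -> ScoreTrack:
    """Read a bedGraph into a dense per-base :class:`ScoreTrack`.

    Uncovered positions are NaN. When ``chrom_sizes`` is omitted,
    vector lengths are the maximum covered coordinate per chromosome.
    """
    spans: Dict[str, List[Tuple[int, int, float]]] = {}
    for lineno, c in _fields(path, 4):
        iv = _interval(path, lineno, c[0], c[1], c[2])
        try:
            val = float(c[3])
        except ValueError as exc:
            raise ParseError(path, lineno, f"bad score: {exc}")
        spans.setdefault(iv.chrom, []).append((iv.start, iv.end, val))
    sizes = dict(chrom_sizes) if chrom_sizes else {c: max(e for _, e, _ in v) for c, v in spans.items()}
    scores = {c: np.full(n, np.nan, dtype=np.float32) for c, n in sizes.items()}
    for chrom, group in spans.items():
        vec = scores.setdefault(chrom, np.full(max(e for _, e, _ in group), np.nan, dtype=np.float32))
        for s, e, val in group:
            vec[s:e] = val
    return ScoreTrack(scores)


def write_bedgraph(track: ScoreTrack, path: str) -> None:
    """Write a ScoreTrack as run-length-compressed bedGraph (NaN runs omitted)."""
    with open(path, "w") as fh:
        for chrom in sorted(track.scores):
            vec = track.scores[chrom]
            if len(vec) == 0:
                continue
            # run boundaries where the value changes (NaN-aware)
            same = (vec[1:] == vec[:-1]) | (np.isnan(vec[1:]) & np.isnan(vec[:-1]))
            breaks = np.flatnonzero(~same) + 1
            starts = np.concatenate([[0], breaks])
            ends = np.concatenate([breaks, [len(vec)]])
            for s, e in zip(starts, ends):
                v = vec[s]
                if not np.isnan(v):
                    fh.write(f"{chrom}\t{s}\t{e}\t{FLOAT_FMT % v}\n")


def read_pwms(path: str) -> List[PWM]:
    """Read the minimal count-matrix motif format.

    Each record: a header line ``>motif_id k`` followed by ``k``
    whitespace-separated rows of 4 counts (A, C, G, T order).
    """
    pwms: List[PWM] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.startswith(">"):
            raise ParseError(path, i + 1, f"expected motif header, got {line!r}")
        parts = line[1:].split()
        if len(parts) != 2:
            raise ParseError(path, i + 1, "header must be '>motif_id k'")
        motif_id, k = parts[0], int(parts[1])
        rows = []
        for j in range(k):
            try:
                vals = [float(x) for x in lines[i + 1 + j].split()]
            except (IndexError, ValueError):
                raise ParseError(path, i + 2 + j, "expected 4 numeric counts")
            if len(vals) != 4:
                raise ParseError(path, i + 2 + j, f"expected 4 counts, got {len(vals)}")
            rows.append(vals)
        pwms.append(PWM(motif_id=motif_id, counts=np.array(rows, dtype=float)))
        i += 1 + k
    return pwms


def write_pwms(pwms: Sequence[PWM], path: str) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id} {pwm.length}\n")
            for row in pwm.counts:
                fh.write("\t".join(FLOAT_FMT % v for v in row) + "\n")
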