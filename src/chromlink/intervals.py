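"""Genomic interval data model and interval algebra.

All coordinates are 0-based, half-open ``[start, end)`` — the BED
convention. Inputs in other conventions (1-based inclusive GTF) are
converted on read by :mod:`chromlink.io` and never stored internally.
Chromosome names are compared by exact string equality; no ``chr``
prefix aliasing is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "GenomicInterval",
    "Peak",
    "GeneModel",
    "TAD",
    "ScoreTrack",
    "overlaps",
    "nearest_point",
]


class ValidationError(ValueError):
    """Raised when a record violates its type invariants."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class Peak:
    """A called peak: an interval with a summit and a significance p-value.

    ``summit`` is the single base of maximal enrichment and must lie
    inside the interval. ``pvalue`` is the MACS-style peak significance
    in ``(0, 1]``.
    """

    interval: GenomicInterval
    summit: int
    pvalue: float
    replicate_id: str = ""
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValidationError(
                f"summit {self.summit} outside interval "
                f"[{self.interval.start}, {self.interval.end})"
            )
        if not (0.0 < self.pvalue <= 1.0):
            raise ValidationError(f"pvalue must be in (0, 1], got {self.pvalue}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True)
class GeneModel:
    """A gene body with strand and the derived transcription start site.

    The TSS is the strand-aware 5' end of the body: ``start`` on the
    plus strand, ``end - 1`` on the minus strand.
    """

    gene_id: str
    interval: GenomicInterval
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"unknown strand {self.strand!r}")
        if not self.gene_id:
            raise ValidationError("gene_id must be non-empty")

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True)
class TAD:
    """A topologically associating domain interval."""

    interval: GenomicInterval
    tad_id: str

    @property
    def chrom(self) -> str:
        return self.interval.chrom


def validate_nonoverlapping_tads(tads: Sequence[TAD]) -> None:
    """Raise :class:`ValidationError` if any two TADs on one chromosome overlap."""
    by_chrom: Dict[str, List[TAD]] = {}
    for t in tads:
        by_chrom.setdefault(t.chrom, []).append(t)
    for chrom, group in by_chrom.items():
        group = sorted(group, key=lambda t: t.interval.start)
        for a, b in zip(group, group[1:]):
            if a.interval.end > b.interval.start:
                raise ValidationError(
                    f"overlapping TADs on {chrom}: {a.tad_id} and {b.tad_id}"
                )


class ScoreTrack:
    """Per-base numeric scores keyed by chromosome.

    Missing positions carry ``NaN``. Positions outside the stored
    vector are treated as missing.
    """

    def __init__(self, scores: Dict[str, np.ndarray]):
        self.scores = {c: np.asarray(v, dtype=np.float32) for c, v in scores.items()}

    @classmethod
    def constant(cls, chrom_sizes: Dict[str, int], value: float) -> "ScoreTrack":
        return cls({c: np.full(n, value, dtype=np.float32) for c, n in chrom_sizes.items()})

    def window(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Scores for ``[start, end)``; out-of-bounds positions are NaN."""
        out = np.full(end - start, np.nan, dtype=np.float32)
        vec = self.scores.get(chrom)
        if vec is None:
            return out
        lo = max(start, 0)
        hi = min(end, len(vec))
        if hi > lo:
            out[lo - start : hi - start] = vec[lo:hi]
        return out


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two intervals share at least one base."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def nearest_point(
    query: int,
    points: Iterable[Tuple[int, str]],
    max_dist: Optional[float] = None,
) -> Optional[Tuple[str, int]]:
    """Nearest labelled point to ``query`` on the same chromosome.

    Returns ``(label, signed_distance)`` where the signed distance is
    ``query - point`` (genome orientation, not gene strand). Ties in
    absolute distance are broken by the lexicographically smallest
    label. Returns ``None`` when no point lies within ``max_dist`` or
    the point set is empty.
    """
    best: Optional[Tuple[int, str, int]] = None  # (|d|, label, signed d)
    for pos, label in points:
        d = query - pos
        key = (abs(d), label)
        if best is None or key < (best[0], best[1]):
            best = (abs(d), label, d)
    if best is None:
        return None
    if max_dist is not None and best[0] > max_dist:
        return None
    return best[1], best[2]
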