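"""Replicate peak confirmation by threshold classes and Fisher combination.

Per-replicate peak calls made at a permissive threshold are combined
into a confirmed set: a candidate peak (p <= weak threshold) is
confirmed when peaks from enough other replicates overlap it and the
Fisher-combined evidence over the overlapping group reaches the
stringent threshold. Overlapping confirmed candidates are merged into
one confirmed peak that spans their union and carries the best
(minimum) p-value, as in MSPC's "biological" replicate mode.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import stats

from .intervals import GenomicInterval, Peak, ValidationError, overlaps

__all__ = [
    "ReplicationConfig",
    "ConfirmedPeak",
    "classify_peak",
    "fisher_combine",
    "confirm_replicated",
]


@dataclass(frozen=True)
class ReplicationConfig:
    """Thresholds of the confirmation procedure.

    ``stringent`` and ``weak`` are p-value thresholds with
    stringent < weak; ``min_supporting_replicates`` is the number of
    *other* replicates that must contribute an overlapping peak.
    """

    stringent: float = 1e-5
    weak: float = 1e-2
    min_supporting_replicates: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.stringent < 1 and 0 < self.weak < 1):
            raise ValidationError("thresholds must lie in (0, 1)")
        if self.stringent >= self.weak:
            raise ValidationError("stringent threshold must be < weak threshold")
        if self.min_supporting_replicates < 1:
            raise ValidationError("min_supporting_replicates must be >= 1")


@dataclass(frozen=True)
class ConfirmedPeak:
    """A replicated peak: union interval, best p-value, best summit, support."""

    interval: GenomicInterval
    summit: int
    pvalue: float
    support: int
    name: str = ""

    @property
    def chrom(self) -> str:
        return self.interval.chrom


def classify_peak(p: float, cfg: ReplicationConfig) -> str:
    """Classify a p-value as ``stringent``, ``weak`` or ``discarded``."""
    if not (0 < p <= 1):
        raise ValidationError(f"p-value must be in (0, 1], got {p}")
    if p <= cfg.stringent:
        return "stringent"
    if p <= cfg.weak:
        return "weak"
    return "discarded"


def fisher_combine(pvalues: Sequence[float]) -> float:
    """Fisher's method: chi-square upper tail of -2 sum(ln p) with 2k df."""
    ps = np.asarray(pvalues, dtype=float)
    if ps.size == 0:
        raise ValidationError("need at least one p-value")
    if (ps <= 0).any() or (ps > 1).any():
        raise ValidationError("p-values must be in (0, 1]")
    return float(stats.combine_pvalues(ps, method="fisher").pvalue)


def _overlap_components(peaks: List[Peak]) -> List[List[Peak]]:
    """Transitive closure of pairwise overlap (per chromosome, sorted sweep)."""
    by_chrom: Dict[str, List[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    components: List[List[Peak]] = []
    for chrom in sorted(by_chrom):
        group = sorted(by_chrom[chrom], key=lambda p: (p.interval.start, p.interval.end))
        current: List[Peak] = []
        reach = -1
        for p in group:
            if current and p.interval.start < reach:
                current.append(p)
                reach = max(reach, p.interval.end)
            else:
                if current:
                    components.append(current)
                current = [p]
                reach = p.interval.end
        if current:
            components.append(current)
    return components


def confirm_replicated(
    replicates: Sequence[Sequence[Peak]],
    cfg: ReplicationConfig = ReplicationConfig(),
) -> List[ConfirmedPeak]:
    """Confirm peaks supported across replicates.

    A candidate (p <= weak) is confirmed when candidates from at least
    ``min_supporting_replicates`` other replicates overlap it and
    Fisher's combined p over {own p} and the overlapping peaks' p-values
    reaches the stringent threshold. Confirmed candidates overlapping
    across replicates are merged: union interval, minimum p, summit of
    the minimum-p peak (ties to the smaller start). The result is
    invariant to the order of the replicate lists.
    """
    if len(replicates) < 2:
        raise ValidationError("need at least 2 replicates")
    candidates: List[Peak] = []
    for i, rep in enumerate(replicates):
        for p in rep:
            rid = p.replicate_id or f"rep{i}"
            if classify_peak(p.pvalue, cfg) != "discarded":
                candidates.append(
                    Peak(p.interval, p.summit, p.pvalue, replicate_id=rid, name=p.name)
                )
    confirmed: List[Peak] = []
    supporters: Dict[int, set] = {}  # id(peak) -> replicate ids contributing evidence
    for comp in _overlap_components(candidates):
        for p in comp:
            others = [q for q in comp if q.replicate_id != p.replicate_id and overlaps(p.interval, q.interval)]
            support_reps = {q.replicate_id for q in others}
            if len(support_reps) < cfg.min_supporting_replicates:
                continue
            combined = fisher_combine([p.pvalue] + [q.pvalue for q in others])
            if combined <= cfg.stringent:
                confirmed.append(p)
                supporters[id(p)] = support_reps | {p.replicate_id}
    merged: List[ConfirmedPeak] = []
    for comp in _overlap_components(confirmed):
        start = min(p.interval.start for p in comp)
        end = max(p.interval.end for p in comp)
        best = min(comp, key=lambda p: (p.pvalue, p.interval.start))
        reps = set().union(*(supporters[id(p)] for p in comp))
        merged.append(
            ConfirmedPeak(
                interval=GenomicInterval(comp[0].chrom, start, end),
                summit=best.summit,
                pvalue=best.pvalue,
                support=len(reps),
            )
        )
    merged.sort(key=lambda c: (c.chrom, c.interval.start, c.interval.end))
    return merged
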