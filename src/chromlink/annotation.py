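"""Peak annotation relative to gene models and summit-centered conservation.

Each confirmed peak is anchored at its summit, assigned to the nearest
TSS, and categorised as promoter (within the promoter half-width of a
TSS), intragenic (peak interval overlaps a gene body) or intergenic.
The three categories partition the peak set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .intervals import GeneModel, ScoreTrack, nearest_point, overlaps
from .replication import ConfirmedPeak

__all__ = [
    "PeakAnnotation",
    "ConservationProfile",
    "annotate_peaks",
    "distance_histogram",
    "conservation_profile",
    "DEFAULT_BIN_EDGES",
]

# absolute TSS-distance bin edges: [0,5k), [5k,50k), [50k,100k), [100k,inf)
DEFAULT_BIN_EDGES = (5_000, 50_000, 100_000)


@dataclass(frozen=True)
class PeakAnnotation:
    peak: ConfirmedPeak
    nearest_gene: Optional[str]
    tss_distance: Optional[int]  # signed: summit - TSS
    category: str  # promoter | intragenic | intergenic


@dataclass
class ConservationProfile:
    """Mean per-offset score around summits; offsets run -flank..flank-1."""

    offsets: np.ndarray
    mean_score: np.ndarray
    n_peaks: np.ndarray


def annotate_peaks(
    peaks: Sequence[ConfirmedPeak],
    genes: Sequence[GeneModel],
    promoter_halfwidth: int = 2_500,
    anchor: str = "summit",
) -> List[PeakAnnotation]:
    """Assign each peak its nearest gene (by TSS), signed distance and category.

    ``anchor`` selects the reference point for TSS distance: the peak
    summit (default) or the interval midpoint.
    """
    if not genes:
        raise ValueError("gene set must be non-empty")
    if anchor not in ("summit", "midpoint"):
        raise ValueError(f"unknown anchor {anchor!r}")
    tss_by_chrom: Dict[str, List[Tuple[int, str]]] = {}
    bodies_by_chrom: Dict[str, List[GeneModel]] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, []).append((g.tss, g.gene_id))
        bodies_by_chrom.setdefault(g.chrom, []).append(g)
    out: List[PeakAnnotation] = []
    for peak in peaks:
        pos = peak.summit if anchor == "summit" else peak.interval.start + len(peak.interval) // 2
        hit = nearest_point(pos, tss_by_chrom.get(peak.chrom, []))
        if hit is None:
            out.append(PeakAnnotation(peak, None, None, "intergenic"))
            continue
        gene_id, dist = hit
        if abs(dist) <= promoter_halfwidth:
            category = "promoter"
        elif any(overlaps(peak.interval, g.interval) for g in bodies_by_chrom[peak.chrom]):
            category = "intragenic"
        else:
            category = "intergenic"
        out.append(PeakAnnotation(peak, gene_id, dist, category))
    return out


def distance_histogram(
    annotations: Sequence[PeakAnnotation],
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
) -> np.ndarray:
    """Fractions of peaks per absolute TSS-distance bin.

    With the default edges the bins are [0, 5 kb), [5, 50 kb),
    [50, 100 kb) and [100 kb, inf); the fractions sum to 1. Peaks
    without a nearest gene on their chromosome are excluded.
    """
    dists = [abs(a.tss_distance) for a in annotations if a.tss_distance is not None]
    if not dists:
        raise ValueError("need at least one annotated peak")
    edges = [0.0, *bin_edges, np.inf]
    counts, _ = np.histogram(dists, bins=edges)
    return counts / counts.sum()


def conservation_profile(
    peaks: Sequence[ConfirmedPeak],
    track: ScoreTrack,
    flank: int = 150,
) -> ConservationProfile:
    """Mean score per offset over the ``2*flank`` window centered on summits.

    Missing (NaN) bases and out-of-bounds positions are excluded per
    offset; ``n_peaks`` records how many peaks contributed at each
    offset.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    width = 2 * flank
    total = np.zeros(width)
    count = np.zeros(width, dtype=int)
    for peak in peaks:
        win = track.window(peak.chrom, peak.summit - flank, peak.summit + flank)
        ok = ~np.isnan(win)
        total[ok] += win[ok]
        count += ok
    mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return ConservationProfile(
        offsets=np.arange(-flank, flank),
        mean_score=mean,
        n_peaks=count,
    )
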