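"""PWM scanning with exact best-site p-values and motif-hit matrix assembly.

A position weight matrix is scored as a log2 likelihood ratio against a
0-order background. Site p-values are exact for the quantised score
matrix: per-position scores are discretised onto an integer grid and
the null distribution of the window score under the background is
obtained by convolution across positions, exactly as FIMO computes its
site p-values. Scanning uses the same quantised scores, so the p-value
of any site equals the true upper-tail mass of its quantised score.

Both strands are always scanned; the better (smaller) p-value wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "PWM",
    "ScoreDistribution",
    "site_pvalue_table",
    "best_site",
    "build_matrix",
    "hierarchical_cluster",
    "consensus",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = np.array([3, 2, 1, 0])  # A<->T, C<->G in ACGT index space

DEFAULT_RESOLUTION = 10_000


@dataclass(frozen=True)
class PWM:
    """Position count matrix with pseudocount and background model.

    ``counts`` has shape (k, 4) in A, C, G, T column order. The
    log-odds score of base j at position i is
    ``log2(((counts[i,j] + pc) / (rowsum[i] + 4 pc)) / background[j])``.
    """

    motif_id: str
    counts: np.ndarray
    pseudocount: float = 0.1
    background: Tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValueError("counts must have shape (k, 4)")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        bg = np.asarray(self.background, dtype=float)
        if not np.isclose(bg.sum(), 1.0) or (bg <= 0).any():
            raise ValueError("background frequencies must be positive and sum to 1")
        totals = counts.sum(axis=1) + 4 * self.pseudocount
        if (totals <= 0).any():
            raise ValueError("each position needs positive total count after pseudocount")

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    def log_odds(self) -> np.ndarray:
        """(k, 4) log2 likelihood-ratio score matrix."""
        bg = np.asarray(self.background, dtype=float)
        probs = (self.counts + self.pseudocount) / (
            self.counts.sum(axis=1, keepdims=True) + 4 * self.pseudocount
        )
        return np.log2(probs / bg)

    def reverse_complement(self) -> "PWM":
        return PWM(
            motif_id=self.motif_id,
            counts=self.counts[::-1, ::-1].copy(),
            pseudocount=self.pseudocount,
            background=self.background,
        )


def consensus(pwm: PWM) -> str:
    """Highest-count base at each position."""
    return "".join(BASES[j] for j in pwm.counts.argmax(axis=1))


@dataclass
class ScoreDistribution:
    """Quantised log-odds scores and the exact null tail of their sum.

    ``int_scores[i, j]`` is the grid score of base j at position i;
    ``tail[t]`` is P(window score >= t) under the background model.
    """

    pwm: PWM
    int_scores: np.ndarray
    tail: np.ndarray
    resolution: int

    def score_word(self, indices: Sequence[int]) -> int:
        return int(sum(self.int_scores[i, j] for i, j in enumerate(indices)))

    def pvalue(self, int_score: int) -> float:
        return float(self.tail[int_score])

    @property
    def max_score(self) -> int:
        return len(self.tail) - 1


def site_pvalue_table(pwm: PWM, resolution: int = DEFAULT_RESOLUTION) -> ScoreDistribution:
    """Exact null distribution of the quantised window score.

    The per-position log-odds scores are shifted to non-negative
    integers on a grid whose step divides the total score range into
    ``resolution`` bins. The probability mass function of the window
    score under the 0-order background is the convolution of the
    per-position distributions; ``tail`` is its inclusive suffix sum,
    so p-values are non-increasing in the score and p at the minimum
    achievable score is exactly 1.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    lom = pwm.log_odds()
    per_pos_min = lom.min(axis=1)
    per_pos_max = lom.max(axis=1)
    span = float((per_pos_max - per_pos_min).sum())
    step = span / resolution if span > 0 else 1.0
    int_scores = np.rint((lom - per_pos_min[:, None]) / step).astype(np.int64)
    bg = np.asarray(pwm.background, dtype=float)
    pmf = np.ones(1)
    for i in range(pwm.length):
        pos_max = int(int_scores[i].max())
        pos_pmf = np.zeros(pos_max + 1)
        for j in range(4):
            pos_pmf[int_scores[i, j]] += bg[j]
        pmf = np.convolve(pmf, pos_pmf)
    tail = np.cumsum(pmf[::-1])[::-1]
    np.minimum(tail, 1.0, out=tail)
    return ScoreDistribution(pwm=pwm, int_scores=int_scores, tail=tail, resolution=resolution)


def _encode(sequence: str) -> np.ndarray:
    """Map ACGT to 0..3; any other symbol (N etc.) to -1."""
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(len(arr), -1, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def _best_int_score(encoded: np.ndarray, int_scores: np.ndarray) -> Optional[int]:
    """Best quantised window score over one strand; None if no valid window."""
    k = int_scores.shape[0]
    n = len(encoded)
    if n < k:
        return None
    valid = encoded >= 0
    best: Optional[int] = None
    for start in range(n - k + 1):
        window = encoded[start : start + k]
        if not valid[start : start + k].all():
            continue
        s = int(int_scores[np.arange(k), window].sum())
        if best is None or s > best:
            best = s
    return best


def best_site(
    region_sequence: str,
    pwm: PWM,
    threshold: float = 1e-4,
    dist: Optional[ScoreDistribution] = None,
) -> Optional[float]:
    """Minimum site p-value over all positions on both strands.

    Windows containing non-ACGT symbols are skipped. Returns ``None``
    when no site reaches the p-value threshold or the sequence is
    shorter than the motif.
    """
    if dist is None:
        dist = site_pvalue_table(pwm)
    encoded = _encode(region_sequence)
    fwd = _best_int_score(encoded, dist.int_scores)
    # reverse strand: scan the reverse complement of the sequence with
    # the same matrix (equivalent to scanning the sequence with the
    # reverse-complement matrix)
    rc = _COMPLEMENT[encoded[::-1]] if len(encoded) else encoded
    rc[encoded[::-1] < 0] = -1
    rev = _best_int_score(rc, dist.int_scores)
    candidates = [s for s in (fwd, rev) if s is not None]
    if not candidates:
        return None
    p = dist.pvalue(max(candidates))
    return p if p <= threshold else None


def build_matrix(
    regions: Dict[str, str],
    pwms: Sequence[PWM],
    threshold: float = 1e-4,
    resolution: int = DEFAULT_RESOLUTION,
) -> pd.DataFrame:
    """Region x motif matrix of -log10 best-site p-values.

    Entries are 0 when no site passes the threshold (p-value treated as
    1), so every entry is either 0 or >= -log10(threshold).
    """
    dists = {pwm.motif_id: site_pvalue_table(pwm, resolution) for pwm in pwms}
    data = {}
    for motif_id, dist in dists.items():
        col = []
        for label, seq in regions.items():
            if seq is None:
                raise ValueError(f"missing sequence for region {label!r}")
            p = best_site(seq, dist.pwm, threshold=threshold, dist=dist)
            col.append(0.0 if p is None else -np.log10(p))
        data[motif_id] = col
    return pd.DataFrame(data, index=list(regions.keys()))


def hierarchical_cluster(matrix: pd.DataFrame) -> Tuple[np.ndarray, List[int]]:
    """Agglomerative complete-linkage clustering of matrix rows.

    Euclidean distance, complete linkage. Ties in the minimum linkage
    distance are broken by the smallest (row-index) cluster pair, so
    the merge sequence is deterministic and invariant to row input
    order up to relabelling. Returns a scipy-style linkage matrix ``Z``
    (n-1 rows: id_a, id_b, height, size) and the dendrogram leaf order.
    """
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("clustering requires at least 2 rows")
    # pairwise complete-linkage distance, updated as clusters merge
    dist = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
    active: Dict[int, List[int]] = {i: [i] for i in range(n)}  # cluster id -> members
    cluster_dist: Dict[Tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            cluster_dist[(i, j)] = float(dist[i, j])
    Z = np.zeros((n - 1, 4))
    children: Dict[int, Tuple[int, int]] = {}
    next_id = n
    for step in range(n - 1):
        (a, b), height = min(cluster_dist.items(), key=lambda kv: (kv[1], kv[0]))
        Z[step] = [a, b, height, len(active[a]) + len(active[b])]
        children[next_id] = (a, b)
        members = active.pop(a) + active.pop(b)
        remaining = sorted(active)
        for c in remaining:
            key_a = (min(a, c), max(a, c))
            key_b = (min(b, c), max(b, c))
            d = max(cluster_dist.pop(key_a), cluster_dist.pop(key_b))
            cluster_dist[(c, next_id)] = d
        cluster_dist.pop((a, b))
        active[next_id] = members
        next_id += 1
    # leaf order: left-to-right depth-first traversal, scipy convention
    def leaves(node: int) -> List[int]:
        if node < n:
            return [node]
        a, b = children[node]
        return leaves(a) + leaves(b)

    return Z, leaves(next_id - 1)
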