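"""Differential-expression filtering and direction calls.

The differential statistic itself (count normalisation, dispersion,
exact tests) is an upstream input: tables arrive with a linear fold
change and a raw p-value per gene. This module applies the expression
floor, chromosome exclusion, Benjamini-Hochberg correction on the
filtered universe, and the fold-change/FDR direction call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, List, Sequence, Set

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .intervals import ValidationError

__all__ = ["DEGThresholds", "bh_adjust", "filter_expressed", "call_degs"]


@dataclass(frozen=True)
class DEGThresholds:
    """Expression and significance thresholds for DEG calling.

    A gene is retained when its expression (fragments per million) is
    at least ``min_expression`` in at least ``min_samples`` samples and
    it does not lie on an excluded chromosome. A retained gene is a DEG
    when its BH q-value is at most ``fdr_max`` and its linear fold
    change is >= ``fc_min`` (up) or <= 1/``fc_min`` (down).
    """

    min_expression: float = 1.0
    min_samples: int = 3
    fdr_max: float = 0.1
    fc_min: float = 1.2
    excluded_chroms: FrozenSet[str] = frozenset({"X", "Y", "M", "chrX", "chrY", "chrM"})

    def __post_init__(self) -> None:
        if self.fc_min <= 1:
            raise ValidationError("fc_min must exceed 1")
        if not (0 < self.fdr_max < 1):
            raise ValidationError("fdr_max must lie in (0, 1)")


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValidationError("p-values must be in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def filter_expressed(expression: pd.DataFrame, chrom: pd.Series, thresholds: DEGThresholds) -> Set[str]:
    """Genes expressed above the floor in enough samples, off excluded chromosomes.

    ``expression`` is a gene x sample matrix (index: gene_id); ``chrom``
    maps each gene to its chromosome. The sample count is taken over
    all columns jointly (both genotypes pooled).
    """
    missing = expression.index.difference(chrom.index)
    if len(missing):
        raise ValidationError(f"genes missing chromosome annotation: {list(missing)[:5]}")
    if (expression.to_numpy() < 0).any():
        raise ValidationError("expression values must be non-negative")
    n_ok = (expression >= thresholds.min_expression).sum(axis=1)
    keep = (n_ok >= thresholds.min_samples) & ~chrom.loc[expression.index].isin(thresholds.excluded_chroms)
    return set(expression.index[keep])


def call_degs(
    table: pd.DataFrame,
    retained: Iterable[str],
    thresholds: DEGThresholds = DEGThresholds(),
) -> pd.DataFrame:
    """Direction-labelled DEG records over the retained gene universe.

    ``table`` needs columns ``gene_id``, ``linear_fc`` (> 0, mutant /
    wild type) and ``raw_p``. BH correction is computed on the retained
    universe only. Returns one row per retained gene with columns
    gene_id, linear_fc, log2_fc, raw_p, q, direction
    (up / down / unchanged).
    """
    retained = set(retained)
    sub = table[table["gene_id"].isin(retained)].copy()
    if sub["gene_id"].duplicated().any():
        raise ValidationError("duplicate gene_id in DE table")
    if (sub["linear_fc"] <= 0).any():
        raise ValidationError("linear fold changes must be positive")
    sub["q"] = bh_adjust(sub["raw_p"].to_numpy())
    sub["log2_fc"] = np.log2(sub["linear_fc"])
    up = (sub["q"] <= thresholds.fdr_max) & (sub["linear_fc"] >= thresholds.fc_min)
    down = (sub["q"] <= thresholds.fdr_max) & (sub["linear_fc"] <= 1.0 / thresholds.fc_min)
    sub["direction"] = np.where(up, "up", np.where(down, "down", "unchanged"))
    cols = ["gene_id", "linear_fc", "log2_fc", "raw_p", "q", "direction"]
    return sub[cols].reset_index(drop=True)
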