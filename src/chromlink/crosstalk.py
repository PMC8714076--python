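"""Two-pathway DEG comparison and regulatory-network construction.

Genes differentially expressed in both of two mutant contrasts are
classified as concordant (same fold-change direction) or discordant
(opposite directions), overlaid with target-gene membership, and turned
into a signed regulatory edge table grouped by curated spatial-bias
categories. The sign convention: a pathway activates a gene when the
gene is downregulated in that pathway's loss-of-function mutant, and
inhibits it when the gene is upregulated.
"""

from __future__ import annotations

from typing import Iterable, Sequence, Set

import pandas as pd

from .intervals import ValidationError

__all__ = ["SPATIAL_CATEGORIES", "shared_degs", "overlay_targets", "build_grn", "grn_to_dot"]

SPATIAL_CATEGORIES = ("anterior", "posterior", "proximal", "distal", "core", "AER", "unannotated")


def shared_degs(degs_a: pd.DataFrame, degs_b: pd.DataFrame) -> pd.DataFrame:
    """Intersect two direction-labelled DEG tables by gene.

    Only genes called up or down in *both* contrasts are shared.
    Returns columns gene_id, fc_a, fc_b, direction_a, direction_b,
    concordance (concordant iff the directions agree).
    """
    frames = []
    for label, df in (("a", degs_a), ("b", degs_b)):
        if df["gene_id"].duplicated().any():
            raise ValidationError(f"duplicate gene_id in DEG set {label}")
        sub = df[df["direction"].isin(["up", "down"])]
        frames.append(
            sub[["gene_id", "linear_fc", "direction"]].rename(
                columns={"linear_fc": f"fc_{label}", "direction": f"direction_{label}"}
            )
        )
    merged = frames[0].merge(frames[1], on="gene_id", how="inner")
    merged["concordance"] = (merged["direction_a"] == merged["direction_b"]).map(
        {True: "concordant", False: "discordant"}
    )
    return merged.sort_values("gene_id").reset_index(drop=True)


def overlay_targets(shared: pd.DataFrame, target_genes: Iterable[str]) -> pd.DataFrame:
    """Flag shared DEGs that are called targets of pathway A."""
    targets: Set[str] = set(target_genes)
    out = shared.copy()
    out["is_target_a"] = out["gene_id"].isin(targets)
    return out


def build_grn(
    shared: pd.DataFrame,
    bias: pd.Series,
    pathway_a: str = "A",
    pathway_b: str = "B",
) -> pd.DataFrame:
    """Signed regulatory edges, two per shared gene, grouped by spatial bias.

    ``bias`` maps gene_id to one of the spatial categories; genes
    absent from the table are labelled ``unannotated``. Edge sign is
    ``activation`` when the gene is downregulated in that pathway's
    mutant and ``inhibition`` when upregulated. Rows are sorted by
    (spatial_bias, gene_id, source).
    """
    bad = set(bias.unique()) - set(SPATIAL_CATEGORIES)
    if bad:
        raise ValidationError(f"unknown spatial-bias categories: {sorted(bad)}")
    rows = []
    for _, rec in shared.iterrows():
        category = bias.get(rec["gene_id"], "unannotated")
        for source, direction in (
            (pathway_a, rec["direction_a"]),
            (pathway_b, rec["direction_b"]),
        ):
            rows.append(
                {
                    "source": source,
                    "target": rec["gene_id"],
                    "sign": "activation" if direction == "down" else "inhibition",
                    "spatial_bias": category,
                }
            )
    edges = pd.DataFrame(rows, columns=["source", "target", "sign", "spatial_bias"])
    order = {c: i for i, c in enumerate(SPATIAL_CATEGORIES)}
    edges["_k"] = edges["spatial_bias"].map(order)
    edges = edges.sort_values(["_k", "target", "source"]).drop(columns="_k")
    return edges.reset_index(drop=True)


def grn_to_dot(edges: pd.DataFrame) -> str:
    """Render the edge table as a DOT graph (arrowheads encode sign)."""
    lines = ["digraph grn {"]
    for _, e in edges.iterrows():
        arrow = "normal" if e["sign"] == "activation" else "tee"
        lines.append(
            f'  "{e["source"]}" -> "{e["target"]}" '
            f'[arrowhead={arrow}, label="{e["spatial_bias"]}"];'
        )
    lines.append("}")
    return "\n".join(lines)
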