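"""Clock-gene ranking: root-to-tip variance, bipartition concordance, length.

Genes are ranked SortaDate-style to pick fixed-size clock datasets (the 8-
and 16-gene concatenations): lexicographically by bipartition concordance
with the species tree (descending), then root-to-tip variance (ascending,
more clock-like), then total tree length (descending, more signal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tree import RootedTree, TreeError

__all__ = [
    "GeneTreeStats",
    "root_to_tip_variance",
    "bipartition_concordance",
    "tree_length",
    "rank_and_select",
    "gene_stats",
]


@dataclass
class GeneTreeStats:
    gene: str
    concordance: float
    rtt_variance: float
    length: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.concordance <= 1.0:
            raise ValueError("concordance must be in [0, 1]")
        if self.rtt_variance < 0 or self.length < 0:
            raise ValueError("variance and length must be non-negative")


def root_to_tip_variance(tree: RootedTree) -> float:
    """Population variance of root-to-tip path lengths (squared subst/site).

    Zero exactly when the tree is clock-like in substitutions.
    """
    if tree.n_tips < 2:
        raise TreeError("need at least 2 tips")
    depths = np.array(list(tree.root_to_tip_lengths().values()))
    return float(depths.var())  # population variance


def _nontrivial_splits(tree: RootedTree, restrict: set[str] | None = None) -> set[frozenset]:
    """Unrooted non-trivial bipartitions as canonical frozensets of labels.

    Each split is stored as the side not containing the reference tip
    (smallest label), restricted to ``restrict`` when given.
    """
    tips = set(tree.tip_labels) if restrict is None else (set(tree.tip_labels) & restrict)
    if len(tips) < 4:
        return set()
    ref = min(tips)
    splits = set()
    for v in range(tree.n_nodes):
        if tree.is_tip(v) or v == tree.root:
            continue
        side = {tree.labels[t] for t in tree.subtree_tips(v)} & tips
        if ref in side:
            side = tips - side
        if 2 <= len(side) <= len(tips) - 2:
            splits.add(frozenset(side))
    return splits


def bipartition_concordance(gene_tree: RootedTree, species_tree: RootedTree) -> float:
    """Fraction of the species tree's non-trivial splits present in the gene tree.

    Both trees are restricted to their shared tip set; the denominator is
    the species tree's split count after restriction (flip
    ``denominator="gene"`` conventions via :func:`gene_stats` if needed).
    """
    shared = set(gene_tree.tip_labels) & set(species_tree.tip_labels)
    if len(shared) < 4:
        raise TreeError("fewer than 4 shared tips")
    ref_splits = _nontrivial_splits(species_tree, shared)
    if not ref_splits:
        return 0.0
    gene_splits = _nontrivial_splits(gene_tree, shared)
    return len(ref_splits & gene_splits) / len(ref_splits)


def tree_length(tree: RootedTree) -> float:
    """Sum of branch lengths (subst/site)."""
    return float(np.nansum(tree.lengths))


def gene_stats(
    gene_trees: dict[str, RootedTree],
    species_tree: RootedTree,
    denominator: str = "species",
) -> list[GeneTreeStats]:
    out = []
    for name, gt in sorted(gene_trees.items()):
        if denominator == "species":
            conc = bipartition_concordance(gt, species_tree)
        else:  # denominator = gene tree's splits
            conc = bipartition_concordance(species_tree, gt)
        out.append(
            GeneTreeStats(
                gene=name,
                concordance=conc,
                rtt_variance=root_to_tip_variance(gt),
                length=tree_length(gt),
            )
        )
    return out


def rank_and_select(
    stats: list[GeneTreeStats], k: int
) -> tuple[list[str], pd.DataFrame]:
    """Top-k genes under the lexicographic SortaDate-style order.

    Sort key: concordance descending, then root-to-tip variance ascending,
    then tree length descending; gene name breaks exact ties, so the
    ranking is deterministic and stable.
    """
    if k > len(stats):
        raise ValueError(f"k={k} exceeds number of genes {len(stats)}")
    table = pd.DataFrame(
        [
            {
                "gene": s.gene,
                "concordance": s.concordance,
                "rtt_variance": s.rtt_variance,
                "length": s.length,
            }
            for s in stats
        ]
    )
    table = table.sort_values(
        by=["concordance", "rtt_variance", "length", "gene"],
        ascending=[False, True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    table["selected"] = table["rank"] <= k
    return list(table["gene"].head(k)), table
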