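"""Rooted tree container shared by every stage of the pipeline.

A :class:`RootedTree` stores a rooted, node-indexed topology together with
per-branch lengths and, optionally, per-node ages.  Branch lengths carry a
*kind* flag distinguishing substitutions/site (the unit of gene trees and
alignment-derived branch data) from millions of years (the unit of
chronograms).  Node ages are measured in My before present with extant tips
at age 0, so a branch's duration is ``age[parent] - age[child]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = ["RootedTree", "TreeError"]

SUBST = "subst"
MY = "my"


class TreeError(ValueError):
    pass


@dataclass
class RootedTree:
    """Node-indexed rooted tree.

    Nodes are integers ``0..n_nodes-1``.  ``parent[i]`` is ``-1`` exactly for
    the root.  ``lengths[i]`` is the length of the branch above node ``i``
    (0.0 for the root).  ``labels[i]`` is the tip label for leaves and
    ``None`` for internal nodes.
    """

    parent: list[int]
    children: list[list[int]]
    labels: list[str | None]
    lengths: np.ndarray
    length_kind: str = SUBST
    ages: np.ndarray | None = None
    _tip_index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        roots = [i for i, p in enumerate(self.parent) if p == -1]
        if len(roots) != 1:
            raise TreeError(f"tree must have exactly one root, found {len(roots)}")
        self._root = roots[0]
        if np.any(self.lengths < -1e-12):
            raise TreeError("negative branch length")
        labels = [l for l in self.labels if l is not None]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate tip labels: {dupes}")
        self._tip_index = {l: i for i, l in enumerate(self.labels) if l is not None}
        if self.ages is not None:
            self.ages = np.asarray(self.ages, dtype=float)
            self._check_ages()

    def _check_ages(self) -> None:
        ages = self.ages
        if np.any(ages < -1e-9):
            raise TreeError("negative node age")
        for v in range(self.n_nodes):
            p = self.parent[v]
            if p >= 0 and not ages[p] > ages[v]:
                raise TreeError(
                    f"parent age {ages[p]} not greater than child age {ages[v]}"
                )

    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return self._root

    @property
    def tips(self) -> list[int]:
        return [i for i, l in enumerate(self.labels) if l is not None]

    @property
    def n_tips(self) -> int:
        return len(self._tip_index)

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tips]

    def is_tip(self, v: int) -> bool:
        return not self.children[v]

    def tip_id(self, label: str) -> int:
        try:
            return self._tip_index[label]
        except KeyError:
            raise TreeError(f"tip {label!r} not found") from None

    def is_binary(self) -> bool:
        return all(len(c) in (0, 2) for c in self.children)

    def has_polytomy(self) -> bool:
        return any(len(c) > 2 for c in self.children)

    # ------------------------------------------------------------------
    def postorder(self) -> Iterator[int]:
        """Children before parents."""
        stack, out = [self._root], []
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(self.children[v])
        return iter(reversed(out))

    def preorder(self) -> Iterator[int]:
        stack = [self._root]
        while stack:
            v = stack.pop()
            yield v
            stack.extend(reversed(self.children[v]))

    def ancestors(self, v: int) -> list[int]:
        """Path of ancestors of ``v`` up to and including the root."""
        out = []
        p = self.parent[v]
        while p != -1:
            out.append(p)
            p = self.parent[p]
        return out

    def mrca(self, label_a: str, label_b: str) -> int:
        """Most recent common ancestor of two tips."""
        a, b = self.tip_id(label_a), self.tip_id(label_b)
        seen = {a} | set(self.ancestors(a))
        while b not in seen:
            b = self.parent[b]
        return b

    def subtree_tips(self, v: int) -> list[int]:
        out, stack = [], [v]
        while stack:
            u = stack.pop()
            if self.is_tip(u):
                out.append(u)
            stack.extend(self.children[u])
        return out

    # ------------------------------------------------------------------
    def durations(self) -> np.ndarray:
        """Per-branch durations in My (indexed by child node; root = 0)."""
        if self.ages is not None:
            out = np.zeros(self.n_nodes)
            for v in range(self.n_nodes):
                p = self.parent[v]
                if p >= 0:
                    out[v] = self.ages[p] - self.ages[v]
            return out
        if self.length_kind == MY:
            return self.lengths.copy()
        raise TreeError("tree has neither ages nor My branch lengths")

    def with_ages(self, ages: Sequence[float]) -> "RootedTree":
        """Copy with node ages set and branch lengths refreshed in My."""
        ages = np.asarray(ages, dtype=float)
        lengths = np.zeros(self.n_nodes)
        for v in range(self.n_nodes):
            p = self.parent[v]
            if p >= 0:
                lengths[v] = ages[p] - ages[v]
        return RootedTree(
            parent=list(self.parent),
            children=[list(c) for c in self.children],
            labels=list(self.labels),
            lengths=lengths,
            length_kind=MY,
            ages=ages,
        )

    def copy(self) -> "RootedTree":
        return RootedTree(
            parent=list(self.parent),
            children=[list(c) for c in self.children],
            labels=list(self.labels),
            lengths=self.lengths.copy(),
            length_kind=self.length_kind,
            ages=None if self.ages is None else self.ages.copy(),
        )

    # ------------------------------------------------------------------
    def ages_from_lengths(self) -> np.ndarray:
        """Infer node ages from My branch lengths (tree must be ultrametric)."""
        if self.length_kind != MY:
            raise TreeError("branch lengths are not in My")
        depth = np.zeros(self.n_nodes)
        for v in self.preorder():
            p = self.parent[v]
            if p >= 0:
                depth[v] = depth[p] + self.lengths[v]
        height = max(depth[t] for t in self.tips)
        ages = height - depth
        ages[np.abs(ages) < 1e-9] = 0.0
        return ages

    def root_to_tip_lengths(self) -> dict[str, float]:
        depth = np.zeros(self.n_nodes)
        for v in self.preorder():
            p = self.parent[v]
            if p >= 0:
                depth[v] = depth[p] + self.lengths[v]
        return {self.labels[t]: float(depth[t]) for t in self.tips}


def build_tree(
    edges: Iterable[tuple[int, int]],
    labels: dict[int, str],
    lengths: dict[int, float] | None = None,
    length_kind: str = SUBST,
    ages: dict[int, float] | None = None,
) -> RootedTree:
    """Convenience constructor from an edge list (parent, child)."""
    edges = list(edges)
    n = max(max(p, c) for p, c in edges) + 1
    parent = [-1] * n
    children: list[list[int]] = [[] for _ in range(n)]
    for p, c in edges:
        parent[c] = p
        children[p].append(c)
    length_arr = np.zeros(n)
    if lengths:
        for v, l in lengths.items():
            length_arr[v] = l
    age_arr = None
    if ages is not None:
        age_arr = np.zeros(n)
        for v, a in ages.items():
            age_arr[v] = a
    return RootedTree(
        parent=parent,
        children=children,
        labels=[labels.get(i) for i in range(n)],
        lengths=length_arr,
        length_kind=length_kind,
        ages=age_arr,
    )
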