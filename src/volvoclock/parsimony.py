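"""Parsimony oracles: Fitch counting, Sankoff DP, and origin counting.

These deterministic counts serve two roles: they are the classical
minimum-change estimates of trait origins/losses reported for the volvocine
characters, and they bound the stochastic-mapping change counts from below
(every sampled history must contain at least the Fitch minimum number of
changes).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .tables import MISSING
from .tree import RootedTree

__all__ = ["fitch_count", "sankoff_cost", "count_origins", "SankoffResult"]


def _states_from(tip_states: Mapping[str, str], states: Sequence[str] | None):
    if states is None:
        states = sorted({s for s in tip_states.values() if s != MISSING})
    if not states:
        raise ValueError("all tips missing: no observed states")
    return list(states)


def _tip_state_map(tree: RootedTree, tip_states: Mapping[str, str], states):
    index = {s: i for i, s in enumerate(states)}
    out = {}
    for t in tree.tips:
        sym = tip_states.get(tree.labels[t], MISSING)
        if sym == MISSING:
            out[t] = None
        else:
            if sym not in index:
                raise ValueError(f"state {sym!r} not in state space {states}")
            out[t] = index[sym]
    return out


def _binary_resolved(tree: RootedTree) -> RootedTree:
    """Resolve polytomies into arbitrary zero-length caterpillars."""
    if tree.is_binary() or not tree.has_polytomy():
        return tree
    warnings.warn("polytomies resolved arbitrarily for Fitch counting")
    parent = list(tree.parent)
    children = [list(c) for c in tree.children]
    labels = list(tree.labels)
    lengths = list(tree.lengths)
    v = 0
    while v < len(parent):
        while len(children[v]) > 2:
            # collapse the last two children under a new zero-length node
            a = children[v].pop()
            b = children[v].pop()
            new = len(parent)
            parent.append(v)
            children.append([b, a])
            labels.append(None)
            lengths.append(0.0)
            parent[a] = parent[b] = new
            children[v].append(new)
        v += 1
    return RootedTree(parent, children, labels, np.array(lengths), tree.length_kind)


def fitch_count(
    tree: RootedTree,
    tip_states: Mapping[str, str],
    states: Sequence[str] | None = None,
) -> tuple[int, dict[int, frozenset[str]]]:
    """Fitch bottom-up pass: minimum changes under equal costs.

    Returns the minimum number of state changes and the per-node Fitch state
    sets.  Missing tips ("?") carry the full state set.  The count is
    invariant to state order; the sets are reported as frozensets of symbols.
    """
    states = _states_from(tip_states, states)
    tree = _binary_resolved(tree)
    tip_idx = _tip_state_map(tree, tip_states, states)
    full = frozenset(range(len(states)))
    sets: dict[int, frozenset[int]] = {}
    changes = 0
    for v in tree.postorder():
        if tree.is_tip(v):
            si = tip_idx[v]
            sets[v] = full if si is None else frozenset([si])
        else:
            a, b = (sets[c] for c in tree.children[v])
            inter = a & b
            if inter:
                sets[v] = inter
            else:
                sets[v] = a | b
                changes += 1
    named = {v: frozenset(states[i] for i in s) for v, s in sets.items()}
    return changes, named


@dataclass
class SankoffResult:
    min_cost: float
    labeling: dict[int, str]
    transition_counts: dict[tuple[str, str], int]
    min_gains: int | None = None  # over all optima, when derived states given


def sankoff_cost(
    tree: RootedTree,
    tip_states: Mapping[str, str],
    cost_matrix: np.ndarray,
    states: Sequence[str],
    derived_states: Iterable[str] | None = None,
    root_state: str | None = None,
) -> SankoffResult:
    """Sankoff dynamic programming under an arbitrary cost matrix.

    ``cost_matrix[i, j]`` is the cost of an i -> j change (np.inf forbids the
    transition, encoding irreversibility).  The backtrace reports one optimal
    labeling, tie-broken deterministically by state order, together with its
    per-transition-type counts.  When ``derived_states`` is given, a second
    additive objective is minimised lexicographically *within* the set of
    minimum-cost labelings: the number of transitions from a non-derived
    into a derived state, i.e. the minimum gain count across optima.
    """
    states = list(states)
    k = len(states)
    C = np.asarray(cost_matrix, dtype=float)
    if C.shape != (k, k):
        raise ValueError("cost matrix shape does not match state space")
    if np.any(np.diag(C) != 0) or np.any(C < 0):
        raise ValueError("cost matrix must be non-negative with zero diagonal")
    derived = set()
    if derived_states is not None:
        derived = {states.index(s) for s in derived_states}
    gain = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            if i != j and i not in derived and j in derived:
                gain[i, j] = 1.0

    tip_idx = _tip_state_map(tree, tip_states, states)
    INF = math.inf
    S: dict[int, np.ndarray] = {}
    G: dict[int, np.ndarray] = {}
    for v in tree.postorder():
        if tree.is_tip(v):
            s = np.full(k, INF)
            si = tip_idx[v]
            if si is None:
                s[:] = 0.0
            else:
                s[si] = 0.0
            S[v] = s
            G[v] = np.zeros(k)
        else:
            s = np.zeros(k)
            g = np.zeros(k)
            for c in tree.children[v]:
                # trans[i, j] = cost of assigning child state j given parent state i
                trans = C + S[c][None, :]
                best = trans.min(axis=1)
                s += best
                with np.errstate(invalid="ignore"):
                    is_best = trans <= best[:, None] + 1e-9
                gtrans = np.where(is_best, gain + G[c][None, :], INF)
                g += gtrans.min(axis=1)
            S[v] = s
            G[v] = g

    root = tree.root
    if root_state is not None:
        # constrain the root (e.g. to a known ancestral condition established
        # by outgroups not present on this tree)
        ri = states.index(root_state)
        mask = np.full(k, math.inf)
        mask[ri] = 0.0
        S[root] = S[root] + mask
    min_cost = float(S[root].min())
    if not math.isfinite(min_cost):
        raise ValueError("no finite-cost labeling exists under this cost matrix")

    # min gains across all optima
    opt_states = [i for i in range(k) if S[root][i] <= min_cost + 1e-9]
    min_gains = int(min(G[root][i] for i in opt_states)) if derived else None

    # one optimal labeling, tie-broken by state order
    labeling: dict[int, int] = {root: opt_states[0]}
    for v in tree.preorder():
        if v == root:
            continue
        p_state = labeling[tree.parent[v]]
        scores = C[p_state] + S[v]
        labeling[v] = int(np.argmin(scores))  # argmin takes first (state order)
    counts: dict[tuple[str, str], int] = {}
    for v in range(tree.n_nodes):
        p = tree.parent[v]
        if p < 0:
            continue
        i, j = labeling[p], labeling[v]
        if i != j:
            key = (states[i], states[j])
            counts[key] = counts.get(key, 0) + 1
    named = {v: states[i] for v, i in labeling.items()}
    return SankoffResult(min_cost, named, counts, min_gains)


def count_origins(
    tree: RootedTree,
    tip_states: Mapping[str, str],
    derived_state: str | Iterable[str],
    states: Sequence[str] | None = None,
    root_state: str | None = None,
) -> int:
    """Minimum number of independent gains of a derived state under parsimony.

    The count is the minimum, over all minimum-change (equal-cost)
    reconstructions, of the number of transitions from a non-derived state
    into the derived state (or state set, for e.g. "any non-isogamous
    gamete system").  ``root_state`` optionally pins the root to a known
    ancestral condition (established by outgroups outside the tree), which
    resolves root-adjacent gain/loss ties.  A derived state absent from the
    tips yields 0 with a warning.
    """
    derived = [derived_state] if isinstance(derived_state, str) else list(derived_state)
    states = _states_from(tip_states, states)
    observed = {s for s in tip_states.values() if s != MISSING}
    if not observed & set(derived):
        warnings.warn(f"derived state(s) {derived} absent from tips; 0 origins")
        return 0
    k = len(states)
    equal_cost = np.ones((k, k)) - np.eye(k)
    res = sankoff_cost(
        tree, tip_states, equal_cost, states,
        derived_states=derived, root_state=root_state,
    )
    return int(res.min_gains)
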