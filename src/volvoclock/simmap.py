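"""Stochastic character mapping: sampling full trait histories on a tree.

Given a fitted Mk model and tip data, histories (state changes with times on
every branch) are drawn from the posterior over character histories: node
states are sampled from their joint conditionals top-down, then each branch
path is sampled conditioned on its endpoints by uniformization (jump-number
sampling against the uniformized chain, then bridge sampling of the jump
states).  The resulting history sets feed origin/loss counting.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .mk import MkModel, _pruning
from .tree import RootedTree

__all__ = ["SimmapSet", "stochastic_map", "count_transitions", "TransitionCounts"]

# One history: {child node id: [(state symbol, dwell time), ...]} ordered from
# the parent end of the branch to the child end.
History = dict[int, list[tuple[str, float]]]


@dataclass
class SimmapSet:
    tree: RootedTree
    model: MkModel
    histories: list[History]
    node_states: list[dict[int, str]]
    seed: int

    @property
    def n_maps(self) -> int:
        return len(self.histories)

    def change_count(self, h: int) -> int:
        return sum(len(segs) - 1 for segs in self.histories[h].values())

    def to_simmap_newick(self, h: int) -> str:
        """Serialize one history in the simmap-annotated Newick dialect."""
        tree = self.tree

        def body(v: int) -> str:
            if tree.is_tip(v):
                core = tree.labels[v]
            else:
                core = "(" + ",".join(body(c) for c in tree.children[v]) + ")"
            if tree.parent[v] == -1:
                return core
            # simmap convention: segments listed from the child end upward
            segs = list(reversed(self.histories[h][v]))
            chain = ":".join(f"{s},{t:.6g}" for s, t in segs)
            return f"{core}:{{{chain}}}"

        return body(tree.root) + ";"


def _sample_path(
    rng: np.random.Generator,
    Q: np.ndarray,
    R: np.ndarray,
    R_powers: list[np.ndarray],
    P_t: np.ndarray,
    a: int,
    b: int,
    t: float,
    omega: float,
    max_jumps: int,
) -> list[tuple[int, float]]:
    """Endpoint-conditioned CTMC path on one branch by uniformization.

    Returns [(state index, dwell time), ...] from the parent end; dwell
    times sum to t and consecutive segment states differ.
    """
    if omega <= 0.0 or t <= 0.0:
        return [(a, t)]
    p_ab = P_t[a, b]
    # sample the number of uniformized jumps n ~ Pois(omega t) * R^n[a,b] / p_ab
    u = rng.random() * p_ab
    log_pois = -omega * t
    cum = 0.0
    n = 0
    while True:
        while len(R_powers) <= n:
            R_powers.append(R_powers[-1] @ R)
        cum += math.exp(log_pois) * R_powers[n][a, b]
        if u <= cum or n >= max_jumps:
            break
        n += 1
        log_pois += math.log(omega * t) - math.log(n)
    if n == 0:
        return [(a, t)]
    # bridge-sample the uniformized jump chain states
    states = [a]
    for j in range(1, n):
        prev = states[-1]
        w = R[prev, :] * R_powers[n - j][:, b]
        w_sum = w.sum()
        probs = w / w_sum if w_sum > 0 else np.full(len(w), 1 / len(w))
        states.append(int(rng.choice(len(w), p=probs)))
    states.append(b)
    times = np.sort(rng.random(n)) * t
    # collapse virtual (self) jumps into dwell segments
    segs: list[tuple[int, float]] = []
    boundaries = np.concatenate([[0.0], times, [t]])
    cur_state = states[0]
    seg_start = 0.0
    for j in range(1, n + 1):
        if states[j] != cur_state:
            segs.append((cur_state, boundaries[j] - seg_start))
            cur_state = states[j]
            seg_start = boundaries[j]
    segs.append((cur_state, t - seg_start))
    return segs


def stochastic_map(
    tree: RootedTree,
    tip_states: Mapping[str, str],
    model: MkModel,
    n_maps: int,
    seed: int = 0,
    max_jump_factor: float = 1.05,
) -> SimmapSet:
    """Draw ``n_maps`` character histories from the posterior (simmap).

    The uniformization rate bound is ``max|q_ii| * max_jump_factor``.
    Reproducible under a fixed seed.
    """
    if n_maps < 1:
        raise ValueError("n_maps must be >= 1")
    rng = np.random.default_rng(seed)
    below, log_scale, P = _pruning(tree, tip_states, model)
    if not math.isfinite(log_scale):
        raise ValueError("tip data have zero likelihood under this model")
    Q = model.rate_matrix()
    omega = float(max(-np.diag(Q).min(), 0.0)) * max_jump_factor
    k = model.k
    R = np.eye(k) + (Q / omega if omega > 0 else np.zeros_like(Q))
    durations = tree.durations()
    root = tree.root
    root_w = model.root_weights(below[root]) * below[root]
    root_w = root_w / root_w.sum()
    # cap on uniformized jumps per branch: generous Poisson upper tail
    max_mu = omega * float(durations.max(initial=0.0))
    max_jumps = int(max_mu + 20.0 * math.sqrt(max_mu + 5.0) + 50)
    R_powers = [np.eye(k)]

    histories: list[History] = []
    node_states_all: list[dict[int, str]] = []
    order = [v for v in tree.preorder()]
    for _ in range(n_maps):
        node_state: dict[int, int] = {}
        node_state[root] = int(rng.choice(k, p=root_w))
        hist: History = {}
        for v in order:
            if v == root:
                continue
            p = tree.parent[v]
            w = P[v][node_state[p], :] * below[v]
            w_sum = w.sum()
            if w_sum <= 0:
                raise RuntimeError(
                    f"endpoint sampling failed on branch above node {v}"
                )
            node_state[v] = int(rng.choice(k, p=w / w_sum))
            segs = _sample_path(
                rng, Q, R, R_powers, P[v], node_state[p], node_state[v],
                float(durations[v]), omega, max_jumps,
            )
            hist[v] = [(model.states[s], d) for s, d in segs]
        histories.append(hist)
        node_states_all.append({v: model.states[s] for v, s in node_state.items()})
    return SimmapSet(tree, model, histories, node_states_all, seed)


@dataclass
class TransitionCounts:
    """Per-history transition counts with mean/mode/distribution summaries."""

    per_history: list[Counter]  # Counter[(from, to)] per history
    states: list[str]

    def counts(self, from_state: str, to_state: str) -> np.ndarray:
        return np.array([c[(from_state, to_state)] for c in self.per_history])

    def mean(self, from_state: str, to_state: str) -> float:
        return float(self.counts(from_state, to_state).mean())

    def mode(self, from_state: str, to_state: str) -> int:
        return _mode(self.counts(from_state, to_state))

    def distribution(self, from_state: str, to_state: str) -> dict[int, float]:
        c = self.counts(from_state, to_state)
        vals, freq = np.unique(c, return_counts=True)
        return {int(v): float(f) / len(c) for v, f in zip(vals, freq)}

    def total_changes(self) -> np.ndarray:
        return np.array([sum(c.values()) for c in self.per_history])


def _mode(values: np.ndarray) -> int:
    vals, freq = np.unique(values, return_counts=True)
    return int(vals[np.argmax(freq)])  # smallest value on frequency ties


def count_transitions(maps: SimmapSet) -> TransitionCounts:
    """Count every i -> j change event in every sampled history."""
    per_history = []
    for hist in maps.histories:
        c: Counter = Counter()
        for segs in hist.values():
            for (s1, _), (s2, _) in zip(segs, segs[1:]):
                c[(s1, s2)] += 1
        per_history.append(c)
    return TransitionCounts(per_history, list(maps.model.states))


def simmap_origin_counts(
    maps: SimmapSet, derived_states: str | Iterable[str]
) -> np.ndarray:
    """Per-history number of transitions from non-derived into derived states."""
    derived = {derived_states} if isinstance(derived_states, str) else set(derived_states)
    tc = count_transitions(maps)
    out = np.zeros(maps.n_maps, dtype=int)
    for i, c in enumerate(tc.per_history):
        out[i] = sum(
            n for (s1, s2), n in c.items() if s1 not in derived and s2 in derived
        )
    return out


def simmap_modal_origins(maps: SimmapSet, derived_states) -> int:
    return _mode(simmap_origin_counts(maps, derived_states))
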