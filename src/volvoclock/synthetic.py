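"""Seeded generators for trees, rates, branch data, traits, calibrations,
and sequence pairs — every observable comes with its ground truth.

Each generator takes an explicit seed and draws from its own
``numpy.random.Generator`` stream (no global state), so regenerating with
the same seed reproduces identical output.  Default scales (20 tips, 1000
sites, 3 calibrations) size the recovery suites to run in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mk import MkModel
from .rate_models import RateProcessParams
from .tables import Calibration, CalibrationTable
from .tree import MY, RootedTree

__all__ = [
    "sim_bd_tree",
    "sim_rates",
    "sim_branch_data",
    "sim_traits",
    "sim_calibrations",
    "sim_seq_pair",
    "BranchData",
]


# ----------------------------------------------------------------------
@dataclass
class BranchData:
    """Per-branch substitution observations, indexed by child node id.

    Poisson mode: integer ``counts`` over ``sites`` alignment columns, so the
    observed length is count/sites.  Normal mode: observed ``lengths``
    (subst/site) with standard errors.
    """

    lengths: np.ndarray
    mode: str = "poisson"  # "poisson" | "normal"
    counts: np.ndarray | None = None
    sites: int | None = None
    ses: np.ndarray | None = None

    @classmethod
    def from_lengths(cls, lengths: np.ndarray, sites: int, se_floor: float = 1e-6):
        """Normal-approximation mode for real input trees: SE = sqrt(len/sites)."""
        lengths = np.asarray(lengths, dtype=float)
        ses = np.maximum(np.sqrt(np.maximum(lengths, 0.0) / sites), se_floor)
        return cls(lengths=lengths, mode="normal", ses=ses, sites=sites)


def sim_bd_tree(
    n_tips: int, birth: float, death: float, seed: int = 0
) -> RootedTree:
    """Birth–death tree conditioned on its tip count, ages in My.

    Forward simulation from two lineages at the root; extinct lineages are
    pruned and the simulation restarts if fewer than ``n_tips`` survivors
    remain when the target is reached; the present is placed between the
    n-th birth and the next event.  Under pure birth (death = 0) the root
    age then has mean sum_{k=2}^{n} 1/(k * birth).
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if not birth > death or death < 0:
        raise ValueError("require birth > death >= 0")
    rng = np.random.default_rng(seed)
    for _attempt in range(1000):
        result = _sim_bd_once(rng, n_tips, birth, death)
        if result is not None:
            return result
    raise RuntimeError("birth-death simulation failed to reach target tip count")


def _sim_bd_once(rng, n_tips, birth, death):
    """One forward pass; returns None when extinction forces a restart."""
    # node 0 is the root split at time 0; nodes are appended after their
    # parents, so parent index < child index throughout
    parent = [-1, 0, 0]
    children: list[list[int]] = [[1, 2], [], []]
    split_time: list[float | None] = [0.0, None, None]
    alive = [1, 2]
    t = 0.0
    while len(alive) < n_tips:
        total = len(alive) * (birth + death)
        t += rng.exponential(1.0 / total)
        i = int(rng.integers(len(alive)))
        v = alive[i]
        if rng.random() < birth / (birth + death):
            split_time[v] = t
            c1, c2 = len(parent), len(parent) + 1
            parent.extend([v, v])
            children[v] = [c1, c2]
            children.extend([[], []])
            split_time.extend([None, None])
            alive[i] = c1
            alive.append(c2)
        else:  # death
            split_time[v] = t
            alive.pop(i)
            if len(alive) < 2:
                return None
    # present lies between the n-th birth and the next event (exclusive),
    # so the youngest internal node keeps a positive age
    t += rng.exponential(1.0 / (len(alive) * (birth + death)))
    T = t
    alive_set = set(alive)
    N = len(parent)
    # surviving-descendant counts (reverse creation order: children first)
    counts = [1 if v in alive_set else 0 for v in range(N)]
    for v in range(N - 1, 0, -1):
        counts[parent[v]] += counts[v]
    retained = [
        v in alive_set or sum(1 for c in children[v] if counts[c] > 0) >= 2
        for v in range(N)
    ]
    if not retained[0]:
        return None  # one side of the root split died out: recondition
    # nearest retained ancestor (parents precede children in index order)
    anc = [-1] * N
    for v in range(1, N):
        p = parent[v]
        anc[v] = p if retained[p] else anc[p]
    ids = {}
    P: list[int] = []
    C: list[list[int]] = []
    labels: list[str | None] = []
    ages: list[float] = []
    tip_no = 0
    for v in range(N):
        if not retained[v] or counts[v] == 0:
            continue
        i = len(P)
        ids[v] = i
        P.append(-1 if v == 0 else ids[anc[v]])
        C.append([])
        if v != 0:
            C[P[i]].append(i)
        if v in alive_set:
            tip_no += 1
            labels.append(f"t{tip_no}")
            ages.append(0.0)
        else:
            labels.append(None)
            ages.append(T - split_time[v])
    n = len(P)
    ages_arr = np.array(ages)
    lengths = np.zeros(n)
    for i in range(n):
        if P[i] >= 0:
            lengths[i] = ages_arr[P[i]] - ages_arr[i]
    return RootedTree(P, C, labels, lengths, length_kind=MY, ages=ages_arr)


def sim_rates(
    tree: RootedTree, params: RateProcessParams, seed: int = 0
) -> np.ndarray:
    """Per-branch substitution rates drawn from the chosen clock process.

    LN and CIR evolve sequentially down lineages (a branch's rate depends on
    its parent branch's rate over the branch duration); UGAM and WN are
    independent draws.  With variance scale 0 every rate equals the base
    rate (strict clock limit).
    """
    params.validate()
    rng = np.random.default_rng(seed)
    durations = tree.durations()
    rates = np.zeros(tree.n_nodes)
    nu, s2 = params.base_rate, params.variance
    if params.model == "UGAM":
        if s2 == 0:
            rates[:] = nu
        else:
            shape = nu**2 / s2
            rates[:] = rng.gamma(shape, s2 / nu, size=tree.n_nodes)
    elif params.model == "WN":
        for v in range(tree.n_nodes):
            dt = durations[v]
            if dt <= 0 or s2 == 0:
                rates[v] = nu
            else:
                var = s2 / dt
                rates[v] = rng.gamma(nu**2 / var, var / nu)
    elif params.model == "LN":
        for v in tree.preorder():
            p = tree.parent[v]
            if p == -1:
                rates[v] = nu
                continue
            # branches hanging off the root evolve from the base rate
            base = nu if p == tree.root else rates[p]
            dt = durations[v]
            if s2 == 0 or dt <= 0:
                rates[v] = base
            else:
                rates[v] = base * np.exp(rng.normal(0.0, np.sqrt(s2 * dt)))
    elif params.model == "CIR":
        theta = params.reversion
        for v in tree.preorder():
            p = tree.parent[v]
            if p == -1:
                rates[v] = nu
                continue
            base = nu if p == tree.root else rates[p]
            dt = durations[v]
            if s2 == 0 or dt <= 0:
                rates[v] = base
            else:
                # exact CIR transition: scaled noncentral chi-square
                c = 2 * theta / (s2 * (1 - np.exp(-theta * dt)))
                df = 4 * theta * nu / s2
                nc = 2 * c * base * np.exp(-theta * dt)
                rates[v] = rng.noncentral_chisquare(df, nc) / (2 * c)
    else:
        raise ValueError(f"unknown clock model {params.model!r}")
    rates[tree.root] = 0.0  # no branch above the root
    return rates


def sim_branch_data(
    tree: RootedTree, rates: np.ndarray, sites: int, seed: int = 0
) -> BranchData:
    """Poisson substitution counts: count_b ~ Pois(rate_b * duration_b * sites)."""
    if sites < 1:
        raise ValueError("sites must be >= 1")
    rng = np.random.default_rng(seed)
    durations = tree.durations()
    mean = rates * durations * sites
    counts = rng.poisson(mean)
    counts[tree.root] = 0
    return BranchData(
        lengths=counts / sites, mode="poisson", counts=counts, sites=sites
    )


def sim_traits(
    tree: RootedTree, model: MkModel, root_state: str, seed: int = 0
) -> tuple[dict[str, str], "SimmapSetLike"]:
    """Simulate a discrete character down the tree (CTMC forward simulation).

    Returns (tip states for inference, full true history for scoring).  The
    history uses the same segment layout as stochastic mapping so origin
    counts on truth and on sampled maps are directly comparable.
    """
    from .simmap import SimmapSet

    if root_state not in model.states:
        raise ValueError(f"root state {root_state!r} not in state space")
    rng = np.random.default_rng(seed)
    Q = model.rate_matrix()
    durations = tree.durations()
    idx = {s: i for i, s in enumerate(model.states)}
    node_state = {tree.root: idx[root_state]}
    history: dict[int, list[tuple[str, float]]] = {}
    for v in tree.preorder():
        if v == tree.root:
            continue
        s = node_state[tree.parent[v]]
        t_left = float(durations[v])
        segs: list[tuple[str, float]] = []
        seg_start = t_left
        while True:
            out_rate = -Q[s, s]
            wait = rng.exponential(1.0 / out_rate) if out_rate > 0 else np.inf
            if wait >= t_left:
                segs.append((model.states[s], t_left))
                break
            segs.append((model.states[s], wait))
            t_left -= wait
            probs = Q[s].clip(0.0)
            probs[s] = 0.0
            probs = probs / probs.sum()
            s = int(rng.choice(model.k, p=probs))
        node_state[v] = s
        history[v] = segs
    tips = {tree.labels[t]: model.states[node_state[t]] for t in tree.tips}
    truth = SimmapSet(
        tree, model, [history],
        [{v: model.states[s] for v, s in node_state.items()}], seed,
    )
    return tips, truth


SimmapSetLike = object  # forward alias for documentation


def sim_calibrations(
    tree: RootedTree,
    nodes: list[int],
    width: float,
    seed: int = 0,
    tail_low: float = 0.025,
    tail_high: float = 0.025,
    min_only: bool = False,
    outlier_node: int | None = None,
    outlier_offset: float = 0.0,
) -> CalibrationTable:
    """Two-sided calibrations bracketing the true node ages.

    min = truth - width*u1, max = truth + width*u2 with u ~ U(0.5, 1), so the
    truth always lies inside [min, max] by construction.  ``outlier_node``
    optionally shifts one calibration by ``outlier_offset`` My (planted
    conflict for fossil cross-validation tests).
    """
    if tree.ages is None:
        raise ValueError("tree must carry node ages")
    rng = np.random.default_rng(seed)
    rows = []
    for i, v in enumerate(nodes):
        if tree.is_tip(v):
            raise ValueError("calibrated nodes must be internal")
        truth = float(tree.ages[v])
        shift = outlier_offset if v == outlier_node else 0.0
        tips = tree.subtree_tips(v)
        left = tree.children[v][0]
        right = tree.children[v][1 if len(tree.children[v]) > 1 else 0]
        tip_a = tree.labels[tree.subtree_tips(left)[0]]
        tip_b = tree.labels[tree.subtree_tips(right)[0]]
        if width == 0.0:
            lo, hi = truth + shift, None if min_only else truth + shift + 1e-6
        else:
            lo = truth + shift - width * rng.uniform(0.5, 1.0)
            hi = None if min_only else truth + shift + width * rng.uniform(0.5, 1.0)
        rows.append(
            Calibration(
                name=f"cal_{i+1}", tip_a=tip_a, tip_b=tip_b,
                min_age=max(lo, 1e-9), max_age=hi,
                tail_low=0.05 if min_only else tail_low,
                tail_high=0.0 if min_only else tail_high,
            )
        )
    return CalibrationTable(rows)


def sim_seq_pair(
    length: int, target_identity: float, seed: int = 0, alphabet: str = "ACGT"
) -> tuple[str, str]:
    """A gap-free sequence pair with the requested percent identity.

    The number of mismatched positions is round(length * (1 - target/100));
    measured identity therefore equals the target to within 1/length.
    """
    if not 0 < target_identity <= 100:
        raise ValueError("target identity must be in (0, 100]")
    rng = np.random.default_rng(seed)
    letters = list(alphabet)
    a = rng.choice(letters, size=length)
    b = a.copy()
    n_mismatch = round(length * (1.0 - target_identity / 100.0))
    pos = rng.choice(length, size=n_mismatch, replace=False)
    for p in pos:
        others = [x for x in letters if x != a[p]]
        b[p] = rng.choice(others)
    return "".join(a), "".join(b)
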