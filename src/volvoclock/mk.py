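"""Mk-model likelihoods, model fitting, and marginal ancestral states.

The Mk model is a continuous-time Markov chain on k discrete states running
along the branches of a chronogram (branch lengths in time units).  Rate
structures: ER (one shared rate), ARD (one rate per ordered state pair),
ORDERED (adjacent-state transitions only, one rate per direction per step),
and CUSTOM (an explicit allowed-transition mask).  Tip data enter through
Felsenstein pruning; transition probabilities are matrix exponentials
computed by eigendecomposition with a scaling-and-squaring fallback for
defective rate matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg
from scipy.optimize import minimize

from .tables import MISSING
from .tree import RootedTree

__all__ = [
    "MkModel",
    "mk_loglik",
    "fit_mk",
    "FitMkResult",
    "akaike_weights",
    "marginal_asr",
    "ASRResult",
]

_STRUCTURES = ("ER", "ARD", "ORDERED", "CUSTOM")


@dataclass
class MkModel:
    """State space + rate-matrix structure + root-state prior choice.

    ``rates`` is the free-parameter vector; its layout depends on
    ``structure`` (see :meth:`rate_matrix`).  ``root_prior`` is one of
    "stationary" (default), "uniform", or "conditional" (FitzJohn-style
    data-conditioned weights).
    """

    states: list[str]
    structure: str = "ER"
    rates: np.ndarray = field(default_factory=lambda: np.array([1.0]))
    root_prior: str = "stationary"
    mask: np.ndarray | None = None  # CUSTOM: boolean allowed-transition matrix

    def __post_init__(self) -> None:
        if self.structure not in _STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}")
        self.rates = np.atleast_1d(np.asarray(self.rates, dtype=float))
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")
        if len(self.rates) != self.n_params:
            raise ValueError(
                f"{self.structure} with {self.k} states needs {self.n_params} "
                f"rates, got {len(self.rates)}"
            )

    @property
    def k(self) -> int:
        return len(self.states)

    @property
    def n_params(self) -> int:
        k = self.k
        if self.structure == "ER":
            return 1
        if self.structure == "ARD":
            return k * (k - 1)
        if self.structure == "ORDERED":
            return 2 * (k - 1)
        return int(self.mask.sum())

    def rate_matrix(self) -> np.ndarray:
        """Q with rows summing to zero; disallowed transitions exactly 0.

        Parameter layout: ER ``[q]``; ARD row-major over ordered pairs
        (0,1),(0,2),...,(1,0),...; ORDERED forward rates q(i->i+1) for
        i=0..k-2 then backward rates q(i+1->i); CUSTOM row-major over
        allowed (masked) off-diagonal entries.
        """
        k = self.k
        Q = np.zeros((k, k))
        if self.structure == "ER":
            Q[:] = self.rates[0]
        elif self.structure == "ARD":
            idx = 0
            for i in range(k):
                for j in range(k):
                    if i != j:
                        Q[i, j] = self.rates[idx]
                        idx += 1
        elif self.structure == "ORDERED":
            fwd, bwd = self.rates[: k - 1], self.rates[k - 1 :]
            for i in range(k - 1):
                Q[i, i + 1] = fwd[i]
                Q[i + 1, i] = bwd[i]
        else:  # CUSTOM
            if self.mask is None:
                raise ValueError("CUSTOM structure requires a mask")
            idx = 0
            for i in range(k):
                for j in range(k):
                    if i != j and self.mask[i, j]:
                        Q[i, j] = self.rates[idx]
                        idx += 1
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def stationary_distribution(self) -> np.ndarray:
        """Left null vector of Q normalised to sum to 1 (uniform fallback
        for rate matrices without a unique stationary law)."""
        Q = self.rate_matrix()
        k = self.k
        A = np.vstack([Q.T, np.ones(k)])
        b = np.zeros(k + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(A, b, rcond=None)
        if np.any(pi < -1e-8) or not np.isfinite(pi).all():
            return np.full(k, 1.0 / k)
        pi = np.clip(pi, 0.0, None)
        return pi / pi.sum()

    def root_weights(self, root_partial: np.ndarray) -> np.ndarray:
        """Root-state prior vector given the root's partial likelihoods.

        ``root_prior`` may also be an explicit probability vector (e.g. a
        known ancestral condition established by outgroups outside the
        tree, the equivalent of phytools' ``pi=`` argument).
        """
        if isinstance(self.root_prior, (list, tuple, np.ndarray)):
            pi = np.asarray(self.root_prior, dtype=float)
            if pi.shape != (self.k,) or pi.sum() <= 0:
                raise ValueError("root prior vector must match the state space")
            return pi / pi.sum()
        if self.root_prior == "uniform":
            return np.full(self.k, 1.0 / self.k)
        if self.root_prior == "stationary":
            return self.stationary_distribution()
        if self.root_prior == "conditional":
            total = root_partial.sum()
            if total <= 0:
                return np.full(self.k, 1.0 / self.k)
            return root_partial / total
        raise ValueError(f"unknown root prior {self.root_prior!r}")

    def with_rates(self, rates: np.ndarray) -> "MkModel":
        return MkModel(
            states=list(self.states), structure=self.structure,
            rates=np.asarray(rates, dtype=float), root_prior=self.root_prior,
            mask=None if self.mask is None else self.mask.copy(),
        )


def transition_matrices(Q: np.ndarray, ts: np.ndarray) -> np.ndarray:
    """P(t) = exp(Qt) for a batch of durations, shape (len(ts), k, k).

    Eigendecomposition when Q is diagonalisable and well-conditioned;
    otherwise scipy's scaling-and-squaring expm per duration.
    """
    ts = np.asarray(ts, dtype=float)
    k = Q.shape[0]
    try:
        w, U = np.linalg.eig(Q)
        Uinv = np.linalg.inv(U)
        if np.linalg.cond(U) > 1e8:
            raise np.linalg.LinAlgError("ill-conditioned eigenbasis")
        E = np.exp(np.outer(ts, w))  # (n, k)
        P = np.einsum("ij,nj,jl->nil", U, E, Uinv).real
    except np.linalg.LinAlgError:
        P = np.stack([scipy.linalg.expm(Q * t) for t in ts])
    P = np.clip(P, 0.0, None)
    P /= P.sum(axis=2, keepdims=True)
    return P


def _tip_partials(tree: RootedTree, tip_states: Mapping[str, str], model: MkModel):
    index = {s: i for i, s in enumerate(model.states)}
    partials = {}
    for t in tree.tips:
        sym = tip_states.get(tree.labels[t], MISSING)
        vec = np.ones(model.k)
        if sym != MISSING:
            if sym not in index:
                raise ValueError(
                    f"state {sym!r} at tip {tree.labels[t]!r} outside state "
                    f"space {model.states}"
                )
            vec = np.zeros(model.k)
            vec[index[sym]] = 1.0
        partials[t] = vec
    return partials


def _pruning(tree: RootedTree, tip_states, model: MkModel):
    """Post-order partial likelihoods with log-scaling.

    Returns (below, log_scale, P) where below[v] is the scaled partial
    likelihood vector of the data below node v, log_scale the accumulated
    log normalisations, and P the per-branch transition matrices (indexed by
    child node).
    """
    durations = tree.durations()
    Q = model.rate_matrix()
    P = transition_matrices(Q, durations)
    tip_part = _tip_partials(tree, tip_states, model)
    below = np.zeros((tree.n_nodes, model.k))
    log_scale = 0.0
    for v in tree.postorder():
        if tree.is_tip(v):
            below[v] = tip_part[v]
        else:
            vec = np.ones(model.k)
            for c in tree.children[v]:
                vec = vec * (P[c] @ below[c])
            m = vec.max()
            if m <= 0:
                return below, -math.inf, P
            below[v] = vec / m
            log_scale += math.log(m)
    return below, log_scale, P


def mk_loglik(
    tree: RootedTree, tip_states: Mapping[str, str], model: MkModel
) -> float:
    """Log-likelihood of the tip data under the Mk CTMC (pruning algorithm)."""
    below, log_scale, _ = _pruning(tree, tip_states, model)
    if not math.isfinite(log_scale):
        return -math.inf
    root_vec = below[tree.root]
    weights = model.root_weights(root_vec)
    lik = float(weights @ root_vec)
    if lik <= 0:
        return -math.inf
    return math.log(lik) + log_scale


@dataclass
class FitMkResult:
    model: MkModel
    loglik: float
    n_params: int
    converged: bool
    degenerate: bool = False


def fit_mk(
    tree: RootedTree,
    tip_states: Mapping[str, str],
    structure: str = "ER",
    states: Sequence[str] | None = None,
    root_prior: str = "stationary",
    mask: np.ndarray | None = None,
    n_restarts: int = 5,
    seed: int = 0,
    rate_bounds: tuple[float, float] = (1e-9, 1e3),
) -> FitMkResult:
    """Maximum-likelihood Mk rates by bounded quasi-Newton on log-rates.

    Multi-start (``n_restarts`` seeded random restarts around a
    parsimony-informed initial rate) guards against local optima in ARD and
    ordered models.  A character with a single observed state has a flat
    likelihood in q and is flagged degenerate.
    """
    if states is None:
        states = sorted({s for s in tip_states.values() if s != MISSING})
    observed = {s for s in tip_states.values() if s != MISSING}
    template = MkModel(
        states=list(states), structure=structure,
        rates=np.ones(_n_params_for(structure, len(states), mask)),
        root_prior=root_prior, mask=mask,
    )
    if len(observed) < 2:
        model = template.with_rates(np.full(template.n_params, rate_bounds[0]))
        return FitMkResult(model, mk_loglik(tree, tip_states, model),
                           template.n_params, True, degenerate=True)

    total_time = float(tree.durations().sum())
    from .parsimony import fitch_count

    min_changes, _ = fitch_count(tree, tip_states, states=list(states))
    q0 = max(min_changes, 1) / max(total_time, 1e-12)
    rng = np.random.default_rng(seed)
    lo, hi = math.log(rate_bounds[0]), math.log(rate_bounds[1])
    bounds = [(lo, hi)] * template.n_params

    def negloglik(log_rates: np.ndarray) -> float:
        model = template.with_rates(np.exp(log_rates))
        ll = mk_loglik(tree, tip_states, model)
        return 1e10 if not math.isfinite(ll) else -ll

    best = None
    starts = [np.full(template.n_params, math.log(q0))]
    for _ in range(n_restarts - 1):
        jitter = rng.uniform(math.log(1 / 30), math.log(30), template.n_params)
        starts.append(np.clip(math.log(q0) + jitter, lo, hi))
    converged = False
    for x0 in starts:
        res = minimize(negloglik, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)
    model = template.with_rates(np.exp(best.x))
    return FitMkResult(model, -float(best.fun), template.n_params, converged)


def _n_params_for(structure: str, k: int, mask: np.ndarray | None) -> int:
    if structure == "ER":
        return 1
    if structure == "ARD":
        return k * (k - 1)
    if structure == "ORDERED":
        return 2 * (k - 1)
    if mask is None:
        raise ValueError("CUSTOM structure requires a mask")
    return int(mask.sum())


def akaike_weights(fits: Sequence[tuple[float, int]]) -> np.ndarray:
    """Akaike weights from (log-likelihood, n_params) pairs.

    AIC = 2k - 2 logL; weight_m = exp(-delta_m / 2) / sum exp(-delta / 2).
    Invariant under adding a constant to all log-likelihoods.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fitted models")
    aic = np.array([2.0 * k - 2.0 * ll for ll, k in fits])
    delta = aic - aic.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


@dataclass
class ASRResult:
    """Marginal ancestral-state probabilities at every internal node."""

    probabilities: dict[int, np.ndarray]  # node id -> vector over states
    model: MkModel
    loglik: float

    def top_state(self, node: int) -> str:
        return self.model.states[int(np.argmax(self.probabilities[node]))]


def marginal_asr(
    tree: RootedTree, tip_states: Mapping[str, str], model: MkModel
) -> ASRResult:
    """Marginal posterior state probabilities by up-down message passing.

    Consistent with :func:`mk_loglik`'s root treatment: the root prior is
    the model's ``root_prior`` vector, and each node's marginal combines its
    below-partials with the message from the rest of the tree.
    """
    below, log_scale, P = _pruning(tree, tip_states, model)
    root = tree.root
    weights = model.root_weights(below[root])
    loglik = math.log(float(weights @ below[root])) + log_scale

    above = np.zeros((tree.n_nodes, model.k))
    above[root] = weights
    probs: dict[int, np.ndarray] = {}
    for v in tree.preorder():
        if not tree.is_tip(v):
            p = above[v] * below[v]
            total = p.sum()
            probs[v] = p / total if total > 0 else np.full(model.k, 1 / model.k)
        # messages to children: above[c] = ((above[v] * prod_{sibs} M_sib) @ P[c])
        msgs = {c: P[c] @ below[c] for c in tree.children[v]}
        for c in tree.children[v]:
            partial = above[v].copy()
            for d in tree.children[v]:
                if d != c:
                    partial = partial * msgs[d]
            vec = partial @ P[c]
            m = vec.max()
            above[c] = vec / m if m > 0 else vec
    return ASRResult(probs, model, loglik)
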