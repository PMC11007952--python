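"""Bayesian node-age estimation on a fixed rooted topology.

The sampler is Metropolis-within-Gibbs over internal node ages (uniform
slide moves inside each node's parent/child window), per-branch rates
(multiplicative proposals), clock and birth–death hyperparameters, and an
occasional whole-tree age/rate scaling move that traverses the age-rate
ridge.  The prior combines the birth–death node-age density (conditioned on
the root age, which is uniform up to ``root_max``), soft-bound fossil
calibration densities at calibrated nodes, and the chosen relaxed-clock
prior on branch rates.  The data enter through a branch-length observation
model — Poisson substitution counts or a normal approximation — rather than
a full phylogenetic likelihood over alignments: the dating mathematics
(priors, clocks, calibrations, HPD summaries) is the point, and the tree
plus branch lengths are its sufficient inputs at this scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io import resolve_calibrations
from .rate_models import RateProcessParams, branch_rate_logdensity
from .soft_bounds import _bd_F, calibration_logdensity
from .tables import Calibration, CalibrationTable
from .tree import RootedTree
from .synthetic import BranchData

__all__ = [
    "DatingModel",
    "PosteriorSamples",
    "branch_loglik",
    "mcmc_date",
    "fossil_cross_validate",
]


@dataclass
class DatingModel:
    """Everything the sampler needs apart from the branch data."""

    tree: RootedTree
    calibrations: CalibrationTable
    clock: RateProcessParams
    birth: float = 0.02
    death: float = 0.01
    root_max: float = 2000.0
    use_bd_prior: bool = True
    sample_hyperparams: bool = True
    hyperprior_means: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.clock.validate()
        self.node_calibrations = resolve_calibrations(self.tree, self.calibrations)
        mins = [c.min_age for c in self.calibrations if c.min_age is not None]
        if mins and self.root_max <= max(mins):
            raise ValueError(
                f"root_max {self.root_max} not above oldest calibration "
                f"minimum {max(mins)}"
            )

    def hyper_mean(self, name: str, default: float) -> float:
        return self.hyperprior_means.get(name, default)


@dataclass
class PosteriorSamples:
    """MCMC draws: node ages, branch rates, hyperparameters."""

    tree: RootedTree
    node_ages: np.ndarray  # (draws, n_nodes); tip columns are 0
    rates: np.ndarray  # (draws, n_nodes); root column unused
    hyper: dict[str, np.ndarray]
    chain_id: np.ndarray
    generation: np.ndarray
    burnin_fraction: float
    acceptance: dict[str, float] = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.node_ages.shape[0]

    def split_chains(self) -> list["PosteriorSamples"]:
        out = []
        for cid in np.unique(self.chain_id):
            m = self.chain_id == cid
            out.append(
                PosteriorSamples(
                    self.tree, self.node_ages[m], self.rates[m],
                    {k: v[m] for k, v in self.hyper.items()},
                    self.chain_id[m], self.generation[m],
                    self.burnin_fraction, self.acceptance,
                )
            )
        return out

    def age_draws(self, node: int) -> np.ndarray:
        return self.node_ages[:, node]


# ----------------------------------------------------------------------
def branch_loglik(tree: RootedTree, branch_rates, data: BranchData) -> float:
    """Log likelihood of the branch observations given rates and durations.

    Poisson mode: count_b ~ Pois(rate_b * duration_b * sites); normal mode:
    length_b ~ Normal(rate_b * duration_b, SE_b^2).  The expected branch
    length in substitutions/site is rate x duration throughout.
    """
    durations = tree.durations()
    total = 0.0
    for v in range(tree.n_nodes):
        if tree.parent[v] < 0:
            continue
        mu = float(branch_rates[v]) * float(durations[v])
        if data.mode == "poisson":
            lam = mu * data.sites
            c = float(data.counts[v])
            if lam <= 0:
                if c > 0:
                    raise ValueError(
                        f"zero-duration branch above node {v} with nonzero count"
                    )
                continue
            total += c * math.log(lam) - lam - float(gammaln(c + 1.0))
        else:
            se = float(data.ses[v])
            z = (float(data.lengths[v]) - mu) / se
            total += -0.5 * z * z - math.log(se) - 0.5 * math.log(2 * math.pi)
    return total


# ----------------------------------------------------------------------
class _Sampler:
    """One MCMC chain with cached per-term log densities.

    Every move recomputes only the posterior terms it touches; a
    from-scratch recomputation (`full_log_posterior`) is used for hyper and
    scale moves and serves as the correctness oracle in tests.
    """

    def __init__(self, model: DatingModel, data: BranchData | None,
                 rng: np.random.Generator, prior_only: bool = False):
        self.model = model
        self.data = data
        self.rng = rng
        self.prior_only = prior_only or data is None
        tree = model.tree
        self.tree = tree
        self.n = tree.n_nodes
        self.root = tree.root
        self.parent = [int(p) for p in tree.parent]
        self.children = [list(c) for c in tree.children]
        self.is_tip = [tree.is_tip(v) for v in range(self.n)]
        self.internal = [v for v in range(self.n) if not self.is_tip[v]]
        self.nonroot = [v for v in range(self.n) if self.parent[v] >= 0]
        self.nonroot_internal = [v for v in self.internal if v != self.root]
        self.cal = dict(model.node_calibrations)
        self.clock_model = model.clock.model
        # state
        self.hyper = {
            "nu": model.clock.base_rate,
            "sigma2": model.clock.variance,
            "theta": model.clock.reversion,
            "birth": model.birth,
            "death": model.death,
        }
        self.ages = self._initial_ages()
        nu0 = self._initial_rate()
        self.hyper["nu"] = nu0
        self.rates = [nu0] * self.n
        self.rates[self.root] = 0.0
        # caches
        self.ll = [0.0] * self.n
        self.rp = [0.0] * self.n
        self.bdp = [0.0] * self.n
        self.calterm = {v: 0.0 for v in self.cal}
        self.bd_norm = 0.0
        self.refresh_all()
        self.accept = {
            "age": [0, 0], "age_comp": [0, 0], "rate": [0, 0],
            "hyper": [0, 0], "scale": [0, 0],
        }

    # -- initialization ------------------------------------------------
    def _initial_ages(self) -> list[float]:
        tree, rng = self.tree, self.rng
        cal_vals = [
            c.max_age if c.max_age is not None else c.min_age * 1.2
            for c in self.cal.values()
        ]
        target_root = min(
            self.model.root_max * 0.9,
            (max(cal_vals) * 1.3) if cal_vals else self.model.root_max * 0.5,
        )
        depth = {v: 0 for v in range(self.n)}
        for v in tree.postorder():
            if not self.is_tip[v]:
                depth[v] = 1 + max(depth[c] for c in self.children[v])
        scale = target_root / max(depth[self.root], 1)
        for _attempt in range(200):
            ages = [0.0] * self.n
            for v in tree.postorder():
                if self.is_tip[v]:
                    continue
                base = max(ages[c] for c in self.children[v])
                ages[v] = base + scale * rng.uniform(0.5, 1.5)
                if v in self.cal:
                    c = self.cal[v]
                    lo = max(base + 1e-6, (c.min_age or 0.0))
                    hi = c.max_age if c.max_age is not None else lo * 1.1 + scale
                    if hi > lo:
                        ages[v] = rng.uniform(lo, hi)
                    ages[v] = max(ages[v], base + 1e-6)
            if ages[self.root] > self.model.root_max:
                shrink = self.model.root_max * 0.95 / ages[self.root]
                ages = [a * shrink for a in ages]
            if self._finite_start(ages):
                return ages
        raise RuntimeError(
            "no calibration-feasible starting ages found after bounded search"
        )

    def _finite_start(self, ages) -> bool:
        for v, c in self.cal.items():
            if not math.isfinite(calibration_logdensity(ages[v], c)):
                return False
        return True

    def _initial_rate(self) -> float:
        if self.prior_only:
            return self.hyper["nu"]
        total_dur = sum(
            self.ages[self.parent[v]] - self.ages[v] for v in self.nonroot
        )
        if self.data.mode == "poisson":
            total_len = float(self.data.counts.sum()) / self.data.sites
        else:
            total_len = float(np.sum(self.data.lengths))
        return max(total_len / max(total_dur, 1e-12), 1e-8)

    # -- scalar posterior terms ----------------------------------------
    def _dur(self, v: int) -> float:
        return self.ages[self.parent[v]] - self.ages[v]

    def _ll_term(self, v: int, rate: float, dur: float) -> float:
        if self.prior_only:
            return 0.0
        d = self.data
        mu = rate * dur
        if d.mode == "poisson":
            lam = mu * d.sites
            c = float(d.counts[v])
            if lam <= 0:
                return 0.0 if c == 0 else -math.inf
            return c * math.log(lam) - lam - float(gammaln(c + 1.0))
        se = float(d.ses[v])
        z = (float(d.lengths[v]) - mu) / se
        return -0.5 * z * z - math.log(se) - 0.5 * math.log(2 * math.pi)

    def _params(self) -> RateProcessParams:
        return RateProcessParams(
            self.clock_model, self.hyper["nu"], self.hyper["sigma2"],
            self.hyper["theta"],
        )

    def _rp_term(self, v: int, rate: float, dur: float) -> float:
        p = self.parent[v]
        parent_rate = None if p == self.root else self.rates[p]
        return branch_rate_logdensity(rate, parent_rate, dur, self._params())

    def _bdp_term(self, v: int, age: float) -> float:
        if not self.model.use_bd_prior:
            return 0.0
        b, d = self.hyper["birth"], self.hyper["death"]
        r = b - d
        if age <= 0:
            return -math.inf
        if abs(r) < 1e-12 * max(b, 1e-300):
            return -2.0 * math.log1p(b * age)
        e = math.exp(-r * age)
        return 2.0 * math.log(abs(r)) - r * age - 2.0 * math.log(abs(b - d * e))

    def _bd_norm_term(self) -> float:
        total = -math.log(self.model.root_max)
        if self.model.use_bd_prior and self.nonroot_internal:
            total -= len(self.nonroot_internal) * math.log(
                _bd_F(self.ages[self.root], self.hyper["birth"], self.hyper["death"])
            )
        return total

    def _hyperprior(self) -> float:
        m = self.model
        total = 0.0
        if m.sample_hyperparams:
            pairs = [
                ("nu", m.hyper_mean("nu", 0.01)),
                ("sigma2", m.hyper_mean("sigma2", max(m.clock.variance, 1e-8) * 10)),
                ("birth", m.hyper_mean("birth", 0.1)),
                ("death", m.hyper_mean("death", 0.1)),
            ]
            if self.clock_model == "CIR":
                pairs.append(
                    ("theta", m.hyper_mean("theta", max(m.clock.reversion, 1e-3)))
                )
            for name, mean in pairs:
                x = self.hyper[name]
                if x <= 0:
                    return -math.inf
                total += -x / mean - math.log(mean)
        return total

    # -- cache refresh / full posterior --------------------------------
    def refresh_all(self) -> None:
        for v in self.nonroot:
            dur = self._dur(v)
            self.ll[v] = self._ll_term(v, self.rates[v], dur)
            self.rp[v] = self._rp_term(v, self.rates[v], dur)
        for v in self.nonroot_internal:
            self.bdp[v] = self._bdp_term(v, self.ages[v])
        for v in self.cal:
            self.calterm[v] = calibration_logdensity(self.ages[v], self.cal[v])
        self.bd_norm = self._bd_norm_term()

    def log_posterior(self) -> float:
        total = self.bd_norm + self._hyperprior()
        for v in self.nonroot:
            total += self.ll[v] + self.rp[v]
        for v in self.nonroot_internal:
            total += self.bdp[v]
        for v in self.cal:
            total += self.calterm[v]
        return total

    def full_log_posterior(self) -> float:
        """From-scratch recomputation (oracle for the cached terms)."""
        self.refresh_all()
        return self.log_posterior()

    # -- moves ----------------------------------------------------------
    def age_move(self, v: int) -> None:
        lo = max(self.ages[c] for c in self.children[v])
        hi = self.model.root_max if v == self.root else self.ages[self.parent[v]]
        if hi <= lo:
            return
        new_age = lo + self.rng.random() * (hi - lo)
        old_age = self.ages[v]
        branches = list(self.children[v])
        if v != self.root:
            branches.append(v)
        old_terms = [(self.ll[b], self.rp[b]) for b in branches]
        delta = 0.0
        self.ages[v] = new_age
        new_terms = []
        for b in branches:
            dur = self._dur(b)
            nll = self._ll_term(b, self.rates[b], dur)
            nrp = self._rp_term(b, self.rates[b], dur)
            new_terms.append((nll, nrp))
        delta += sum(a + b for a, b in new_terms) - sum(a + b for a, b in old_terms)
        old_bdp = new_bdp = 0.0
        if v != self.root:
            old_bdp = self.bdp[v]
            new_bdp = self._bdp_term(v, new_age)
            delta += new_bdp - old_bdp
        old_norm = new_norm = self.bd_norm
        if v == self.root:
            new_norm = self._bd_norm_term()
            delta += new_norm - old_norm
        old_cal = new_cal = 0.0
        if v in self.cal:
            old_cal = self.calterm[v]
            new_cal = calibration_logdensity(new_age, self.cal[v])
            delta += new_cal - old_cal
        self.accept["age"][1] += 1
        if delta >= 0 or self.rng.random() < math.exp(delta):
            for b, (nll, nrp) in zip(branches, new_terms):
                self.ll[b], self.rp[b] = nll, nrp
            if v != self.root:
                self.bdp[v] = new_bdp
            self.bd_norm = new_norm
            if v in self.cal:
                self.calterm[v] = new_cal
            self.accept["age"][0] += 1
        else:
            self.ages[v] = old_age

    def age_move_compensated(self, v: int) -> None:
        """Slide a node age while rescaling adjacent branch rates so each
        branch's expected length (rate x duration) is unchanged.

        The likelihood is invariant under this move, so it traverses the
        age-rate ridge that defeats plain single-age updates; the Jacobian
        of the rate rescaling is the product of old/new duration ratios.
        """
        lo = max(self.ages[c] for c in self.children[v])
        hi = self.model.root_max if v == self.root else self.ages[self.parent[v]]
        if hi <= lo:
            return
        new_age = lo + self.rng.random() * (hi - lo)
        old_age = self.ages[v]
        scaled = list(self.children[v])
        if v != self.root:
            scaled.append(v)
        old_rates = {b: self.rates[b] for b in scaled}
        old_durs = {b: self._dur(b) for b in scaled}
        # rp terms also change on grandchild branches for autocorrelated clocks
        affected = set(scaled)
        if self.clock_model in ("LN", "CIR"):
            for c in self.children[v]:
                affected.update(self.children[c])
        affected = [b for b in affected if self.parent[b] >= 0]
        old_terms = {b: (self.ll[b], self.rp[b]) for b in affected}
        self.ages[v] = new_age
        jacobian = 0.0
        ok = True
        for b in scaled:
            new_dur = self._dur(b)
            if new_dur <= 0:
                ok = False
                break
            self.rates[b] = old_rates[b] * old_durs[b] / new_dur
            jacobian += math.log(old_durs[b]) - math.log(new_dur)
        if not ok:
            self.ages[v] = old_age
            for b, r in old_rates.items():
                self.rates[b] = r
            return
        new_terms = {}
        delta = jacobian
        for b in affected:
            dur = self._dur(b)
            nll = self._ll_term(b, self.rates[b], dur)
            nrp = self._rp_term(b, self.rates[b], dur)
            new_terms[b] = (nll, nrp)
            delta += nll + nrp - old_terms[b][0] - old_terms[b][1]
        old_bdp = new_bdp = 0.0
        if v != self.root:
            old_bdp = self.bdp[v]
            new_bdp = self._bdp_term(v, new_age)
            delta += new_bdp - old_bdp
        new_norm = self.bd_norm
        if v == self.root:
            new_norm = self._bd_norm_term()
            delta += new_norm - self.bd_norm
        new_cal = 0.0
        if v in self.cal:
            new_cal = calibration_logdensity(new_age, self.cal[v])
            delta += new_cal - self.calterm[v]
        self.accept["age_comp"][1] += 1
        if math.isfinite(delta) and (
            delta >= 0 or self.rng.random() < math.exp(delta)
        ):
            for b, t in new_terms.items():
                self.ll[b], self.rp[b] = t
            if v != self.root:
                self.bdp[v] = new_bdp
            self.bd_norm = new_norm
            if v in self.cal:
                self.calterm[v] = new_cal
            self.accept["age_comp"][0] += 1
        else:
            self.ages[v] = old_age
            for b, r in old_rates.items():
                self.rates[b] = r

    def rate_move(self, v: int, step: float = 0.6) -> None:
        old_rate = self.rates[v]
        factor = math.exp(self.rng.uniform(-step, step))
        new_rate = old_rate * factor
        hastings = math.log(factor)  # multiplicative proposal
        autocorr = self.clock_model in ("LN", "CIR")
        branches = [v] + (self.children[v] if autocorr else [])
        branches = [b for b in branches if b in range(self.n) and self.parent[b] >= 0]
        old_terms = [(self.ll[b], self.rp[b]) for b in branches]
        self.rates[v] = new_rate
        new_terms = []
        for b in branches:
            dur = self._dur(b)
            rate = self.rates[b]
            nll = self.ll[b] if b != v else self._ll_term(b, rate, dur)
            nrp = self._rp_term(b, rate, dur)
            new_terms.append((nll, nrp))
        delta = sum(a + b for a, b in new_terms) - sum(a + b for a, b in old_terms)
        self.accept["rate"][1] += 1
        if delta + hastings >= 0 or self.rng.random() < math.exp(delta + hastings):
            for b, (nll, nrp) in zip(branches, new_terms):
                self.ll[b], self.rp[b] = nll, nrp
            self.accept["rate"][0] += 1
        else:
            self.rates[v] = old_rate

    def hyper_move(self, name: str, step: float = 0.3) -> None:
        old = self.hyper[name]
        factor = math.exp(self.rng.uniform(-step, step))
        old_hp = self._hyperprior()
        self.hyper[name] = old * factor
        try:
            self._params().validate()
        except ValueError:
            self.hyper[name] = old
            return
        delta = math.log(factor)  # multiplicative-proposal Hastings term
        if name in ("nu", "sigma2", "theta"):
            new_terms = {
                v: self._rp_term(v, self.rates[v], self._dur(v))
                for v in self.nonroot
            }
            delta += sum(new_terms.values()) - sum(
                self.rp[v] for v in self.nonroot
            )

            def commit():
                for v, t in new_terms.items():
                    self.rp[v] = t
        else:  # birth / death: node-age prior terms only
            new_bdp = {
                v: self._bdp_term(v, self.ages[v]) for v in self.nonroot_internal
            }
            new_norm = self._bd_norm_term()
            delta += (
                sum(new_bdp.values())
                - sum(self.bdp[v] for v in self.nonroot_internal)
                + new_norm
                - self.bd_norm
            )

            def commit():
                for v, t in new_bdp.items():
                    self.bdp[v] = t
                self.bd_norm = new_norm

        delta += self._hyperprior() - old_hp
        self.accept["hyper"][1] += 1
        if math.isfinite(delta) and (
            delta >= 0 or self.rng.random() < math.exp(delta)
        ):
            commit()
            self.accept["hyper"][0] += 1
        else:
            self.hyper[name] = old

    def scale_move(self, step: float = 0.15) -> None:
        factor = math.exp(self.rng.uniform(-step, step))
        old_lp = self.log_posterior()
        snapshot = self._snapshot_caches()
        old_ages = list(self.ages)
        old_rates = list(self.rates)
        for v in self.internal:
            self.ages[v] *= factor
        for v in self.nonroot:
            self.rates[v] /= factor
        if self.ages[self.root] > self.model.root_max:
            self.ages = old_ages
            self.rates = old_rates
            return
        self.refresh_all()
        new_lp = self.log_posterior()
        jacobian = (len(self.internal) - len(self.nonroot)) * math.log(factor)
        delta = new_lp - old_lp + jacobian
        self.accept["scale"][1] += 1
        if delta >= 0 or self.rng.random() < math.exp(delta):
            self.accept["scale"][0] += 1
        else:
            self.ages = old_ages
            self.rates = old_rates
            self._restore_caches(snapshot)

    def _snapshot_caches(self):
        return (
            list(self.ll), list(self.rp), list(self.bdp),
            dict(self.calterm), self.bd_norm,
        )

    def _restore_caches(self, snap) -> None:
        self.ll, self.rp, self.bdp, self.calterm, self.bd_norm = (
            list(snap[0]), list(snap[1]), list(snap[2]), dict(snap[3]), snap[4],
        )

    def sweep(self, index: int) -> None:
        for v in self.internal:
            self.age_move(v)
        if not self.prior_only:
            for v in self.internal:
                self.age_move_compensated(v)
        if not self.prior_only or self.clock_model in ("LN", "CIR"):
            for v in self.nonroot:
                self.rate_move(v)
        if self.model.sample_hyperparams:
            names = ["nu", "sigma2", "birth", "death"]
            if self.clock_model == "CIR":
                names.append("theta")
            for name in names:
                self.hyper_move(name)
        if index % 10 == 0:
            self.scale_move()


# ----------------------------------------------------------------------
def mcmc_date(
    model: DatingModel,
    data: BranchData | None,
    n_gen: int = 10000,
    sample_every: int = 10,
    seed: int = 0,
    n_chains: int = 2,
    burnin: float = 0.2,
    prior_only: bool = False,
) -> PosteriorSamples:
    """Run the dating MCMC and return post-burn-in posterior samples.

    One generation is one full Metropolis-within-Gibbs sweep.  The first
    ``burnin`` fraction of each chain's retained draws is discarded
    (default 20%).  Deterministic under a fixed seed.
    """
    if data is not None and not prior_only:
        if len(data.lengths) != model.tree.n_nodes:
            raise ValueError("branch data do not match the topology")
    all_ages, all_rates, all_chain, all_gen = [], [], [], []
    hyper_keys = ["nu", "sigma2", "theta", "birth", "death"]
    all_hyper: dict[str, list] = {k: [] for k in hyper_keys}
    acceptance: dict[str, float] = {}
    for chain in range(n_chains):
        rng = np.random.default_rng([int(seed), chain])
        sampler = _Sampler(model, data, rng, prior_only=prior_only)
        kept_ages, kept_rates, kept_gen = [], [], []
        kept_hyper: dict[str, list] = {k: [] for k in hyper_keys}
        for g in range(1, n_gen + 1):
            sampler.sweep(g)
            if g % sample_every == 0:
                kept_ages.append(list(sampler.ages))
                kept_rates.append(list(sampler.rates))
                kept_gen.append(g)
                for k in hyper_keys:
                    kept_hyper[k].append(sampler.hyper[k])
        n_burn = int(burnin * len(kept_ages))
        all_ages.extend(kept_ages[n_burn:])
        all_rates.extend(kept_rates[n_burn:])
        all_gen.extend(kept_gen[n_burn:])
        all_chain.extend([chain] * (len(kept_ages) - n_burn))
        for k in hyper_keys:
            all_hyper[k].extend(kept_hyper[k][n_burn:])
        for key, (acc, tot) in sampler.accept.items():
            acceptance[f"chain{chain}_{key}"] = acc / tot if tot else math.nan
    return PosteriorSamples(
        tree=model.tree,
        node_ages=np.array(all_ages),
        rates=np.array(all_rates),
        hyper={k: np.array(v) for k, v in all_hyper.items()},
        chain_id=np.array(all_chain),
        generation=np.array(all_gen),
        burnin_fraction=burnin,
        acceptance=acceptance,
    )


# ----------------------------------------------------------------------
def fossil_cross_validate(
    model: DatingModel,
    data: BranchData | None,
    n_gen: int = 2000,
    sample_every: int = 5,
    seed: int = 0,
    n_chains: int = 1,
) -> tuple[pd.DataFrame, float]:
    """Leave-one-calibration-out re-dating.

    For each calibration i the dating is re-run without it; the deviation
    D_i is the posterior mean age of calibration i's node minus the
    calibration's midpoint (min for min-only rows).  Returns the per-fossil
    table (D_i, D_i^2) and the total sum of squared deviations.
    """
    if len(model.calibrations) < 2:
        raise ValueError("fossil cross-validation needs at least 2 calibrations")
    rows = []
    for cal in model.calibrations:
        remaining = model.calibrations.drop(cal.name)
        if all(r.min_age is None for r in remaining):
            raise ValueError(
                f"removing {cal.name!r} leaves no minimum bound anywhere"
            )
        sub = DatingModel(
            tree=model.tree, calibrations=remaining, clock=model.clock,
            birth=model.birth, death=model.death, root_max=model.root_max,
            use_bd_prior=model.use_bd_prior,
            sample_hyperparams=model.sample_hyperparams,
            hyperprior_means=model.hyperprior_means,
        )
        samples = mcmc_date(
            sub, data, n_gen=n_gen, sample_every=sample_every,
            seed=seed, n_chains=n_chains,
        )
        node = model.tree.mrca(cal.tip_a, cal.tip_b)
        post_mean = float(samples.node_ages[:, node].mean())
        d = post_mean - cal.midpoint
        rows.append(
            {
                "calibration": cal.name,
                "node": node,
                "posterior_mean": post_mean,
                "reference_age": cal.midpoint,
                "deviation": d,
                "squared_deviation": d * d,
            }
        )
    table = pd.DataFrame(rows)
    return table, float(table["squared_deviation"].sum())
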