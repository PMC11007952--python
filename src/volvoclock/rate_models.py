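"""Relaxed-clock rate processes: LN, CIR, UGAM, WN prior densities.

Autocorrelated processes (LN: geometric Brownian log-rates; CIR: mean-
reverting square-root diffusion with a gamma stationary law) make a branch's
rate depend on its parent branch's rate across the elapsed time.
Uncorrelated processes draw each branch's rate independently: UGAM i.i.d.
gamma; WN gamma with variance inversely proportional to branch duration, so
long branches average away rate noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.special import gammaln, ive

__all__ = ["RateProcessParams", "rate_prior_logdensity", "CLOCK_MODELS"]

CLOCK_MODELS = ("LN", "CIR", "UGAM", "WN")


@dataclass
class RateProcessParams:
    """Hyperparameters of a branch-rate process.

    base_rate: long-run mean rate nu (subst/site/My).
    variance: variance-scale sigma^2 (units depend on the model: log-rate
      variance per My for LN; diffusion scale for CIR; rate variance for
      UGAM; rate variance x My for WN).
    reversion: CIR mean-reversion strength theta (1/My); unused elsewhere.
    """

    model: str
    base_rate: float
    variance: float
    reversion: float = 0.0

    def validate(self) -> None:
        if self.model not in CLOCK_MODELS:
            raise ValueError(f"unknown clock model {self.model!r}")
        if self.base_rate <= 0 or self.variance < 0:
            raise ValueError("base rate must be > 0 and variance >= 0")
        if self.model == "CIR":
            if self.reversion <= 0:
                raise ValueError("CIR requires reversion > 0")
            if self.variance > 0 and not self.stationary_shape > 1.0:
                raise ValueError(
                    "CIR stationarity condition violated: need "
                    "2*theta*nu/sigma^2 > 1"
                )

    @property
    def stationary_shape(self) -> float:
        """Shape of the CIR stationary gamma distribution, 2 theta nu / sigma^2."""
        return 2.0 * self.reversion * self.base_rate / self.variance


# ----------------------------------------------------------------------
# scalar building blocks (used in the MCMC hot loop)
# ----------------------------------------------------------------------
def gamma_logpdf(x: float, shape: float, scale: float) -> float:
    if x <= 0:
        return -math.inf
    return (
        (shape - 1.0) * math.log(x)
        - x / scale
        - shape * math.log(scale)
        - float(gammaln(shape))
    )


def lognormal_step_logpdf(rate: float, parent_rate: float, s2dt: float) -> float:
    """Child log-rate ~ Normal(log parent rate, sigma^2 * dt)."""
    if rate <= 0 or parent_rate <= 0:
        return -math.inf
    if s2dt <= 0:
        return 0.0 if abs(rate - parent_rate) < 1e-300 else -math.inf
    z = math.log(rate) - math.log(parent_rate)
    return -0.5 * z * z / s2dt - 0.5 * math.log(2 * math.pi * s2dt) - math.log(rate)


def cir_step_logpdf(
    rate: float, parent_rate: float, dt: float,
    nu: float, s2: float, theta: float,
) -> float:
    """Exact CIR transition density (noncentral chi-square form)."""
    if rate <= 0 or parent_rate <= 0:
        return -math.inf
    if dt <= 0 or s2 <= 0:
        return 0.0 if abs(rate - parent_rate) < 1e-300 else -math.inf
    edt = math.exp(-theta * dt)
    c = 2.0 * theta / (s2 * (1.0 - edt))
    df = 4.0 * theta * nu / s2
    nc = 2.0 * c * parent_rate * edt
    x = 2.0 * c * rate
    # log ncx2.pdf(x; df, nc) + log(2c), via the exponentially scaled Bessel I
    q = df / 4.0 - 0.5
    sq = math.sqrt(nc * x)
    bess = float(ive(2.0 * q, sq))
    if bess <= 0 or not math.isfinite(bess):
        # near the deterministic limit (tiny sigma^2) the scaled Bessel
        # underflows; use the moment-matched Gaussian approximation, which
        # is asymptotically exact in that regime
        m = nu + (parent_rate - nu) * edt
        v = (
            parent_rate * s2 / theta * (edt - edt * edt)
            + nu * s2 / (2.0 * theta) * (1.0 - edt) ** 2
        )
        if v <= 0:
            return 0.0 if abs(rate - m) < 1e-300 else -math.inf
        z = (rate - m) ** 2 / v
        return -0.5 * z - 0.5 * math.log(2 * math.pi * v)
    return (
        math.log(2.0 * c)
        - math.log(2.0)
        - (x + nc) / 2.0
        + q * math.log(x / nc)
        + math.log(bess)
        + sq
    )


def cir_stationary_logpdf(rate: float, nu: float, s2: float, theta: float) -> float:
    shape = 2.0 * theta * nu / s2
    scale = s2 / (2.0 * theta)
    return gamma_logpdf(rate, shape, scale)


def branch_rate_logdensity(
    rate: float,
    parent_rate: float | None,
    dt: float,
    params: RateProcessParams,
) -> float:
    """Log prior density of one branch's rate given its parent's rate.

    ``parent_rate`` is None for branches hanging off the root: autocorrelated
    models then use their stationary/base-rate law.
    """
    nu, s2 = params.base_rate, params.variance
    m = params.model
    if m == "UGAM":
        if s2 == 0:
            return 0.0 if abs(rate - nu) < 1e-300 else -math.inf
        return gamma_logpdf(rate, nu * nu / s2, s2 / nu)
    if m == "WN":
        if s2 == 0 or dt <= 0:
            return 0.0 if abs(rate - nu) < 1e-300 else -math.inf
        var = s2 / dt
        return gamma_logpdf(rate, nu * nu / var, var / nu)
    if m == "LN":
        base = nu if parent_rate is None else parent_rate
        return lognormal_step_logpdf(rate, base, s2 * dt)
    if m == "CIR":
        if parent_rate is None:
            return cir_stationary_logpdf(rate, nu, s2, params.reversion)
        return cir_step_logpdf(rate, parent_rate, dt, nu, s2, params.reversion)
    raise ValueError(f"unknown clock model {m!r}")


def rate_prior_logdensity(tree, branch_rates, params: RateProcessParams) -> float:
    """Joint log prior of all branch rates under the chosen process.

    Branch rates are indexed by child node; the root entry is ignored.
    UGAM factorizes over branches; WN additionally depends on branch
    durations; LN and CIR chain parent branch -> child branch, with
    root-adjacent branches anchored to the base rate (LN) or the stationary
    law (CIR).  Elapsed time for an autocorrelated step is the child
    branch's own duration.
    """
    params.validate()
    durations = tree.durations()
    total = 0.0
    for v in range(tree.n_nodes):
        p = tree.parent[v]
        if p == -1:
            continue
        parent_rate = None if p == tree.root else float(branch_rates[p])
        total += branch_rate_logdensity(
            float(branch_rates[v]), parent_rate, float(durations[v]), params
        )
        if not math.isfinite(total):
            return -math.inf
    return total
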