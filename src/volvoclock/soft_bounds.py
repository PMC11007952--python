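"""Soft-bound fossil calibration densities and the birth–death node-age prior.

A soft bound places a small, fixed probability mass *outside* the stated
fossil age bounds instead of truncating hard: for a two-sided calibration
the default is 2.5% below the minimum and 2.5% above the maximum, with the
remaining 95% uniform between the bounds; for a minimum-only calibration 5%
of the mass falls below the minimum.  Tails are exponential with their rate
chosen so the density is continuous at each bound.
"""

from __future__ import annotations

import math

import numpy as np

from .tables import Calibration

__all__ = ["calibration_logdensity", "bd_age_prior", "bd_node_age_logpdf"]


def _two_sided_params(cal: Calibration):
    lo, hi = cal.min_age, cal.max_age
    p_low, p_high = cal.tail_low, cal.tail_high
    core = 1.0 - p_low - p_high
    h = core / (hi - lo)  # uniform plateau height
    return lo, hi, p_low, p_high, h


def calibration_logdensity(age: float, cal: Calibration, scale: float | None = None) -> float:
    """Log density of a node age under a soft-bound calibration.

    Two-sided: density is a uniform plateau of mass 1 - tail_low - tail_high
    on [min, max] with exponential tails of mass tail_low below and
    tail_high above, each matched continuously to the plateau height.  A
    tail mass of 0 recovers a hard bound (density 0 outside).

    Minimum-only: mass 1 - tail_low sits in an exponential (diffuse)
    component above the minimum with scale ``scale`` (default min/2), and
    mass tail_low in an exponential tail below the minimum, again matched
    continuously.  Integrates to 1 in both cases.
    """
    if age <= 0:
        return -math.inf
    if cal.max_age is not None and cal.min_age is not None:
        lo, hi, p_low, p_high, h = _two_sided_params(cal)
        if lo <= age <= hi:
            return math.log(h)
        if age < lo:
            if p_low == 0.0:
                return -math.inf
            lam = h / p_low  # continuity at the bound: p_low * lam = h
            return math.log(h) - lam * (lo - age)
        if p_high == 0.0:
            return -math.inf
        lam = h / p_high
        return math.log(h) - lam * (age - hi)
    # minimum-only
    lo = cal.min_age
    p_low = cal.tail_low
    if scale is None:
        scale = lo / 2.0
    h = (1.0 - p_low) / scale  # density just above the bound
    if age >= lo:
        return math.log(h) - (age - lo) / scale
    if p_low == 0.0:
        return -math.inf
    lam = h / p_low
    return math.log(h) - lam * (lo - age)


# ----------------------------------------------------------------------
# Birth–death node-age prior (conditioned on root age and taxon count)
# ----------------------------------------------------------------------
def _bd_F(t: float, birth: float, death: float) -> float:
    """Antiderivative of the per-node age kernel p1; F(t)/F(T) is the CDF."""
    r = birth - death
    if abs(r) < 1e-12 * max(birth, 1e-300):
        return t / (1.0 + birth * t)
    e = math.exp(-r * t)
    return (1.0 - e) / (birth - death * e)


def bd_node_age_logpdf(t: float, root_age: float, birth: float, death: float) -> float:
    """Log density of one (non-root) node age under the conditioned process.

    Given the root age T, the n-2 non-root speciation times of a complete-
    sampling birth–death tree are i.i.d. with density p1(t)/F(T) on (0, T),
    where p1(t) = r^2 e^{-rt} / (birth - death e^{-rt})^2 and F is its
    antiderivative; the critical case birth = death has the closed form
    p1(t) = 1/(1 + birth t)^2, F(t) = t/(1 + birth t).
    """
    if not 0.0 < t < root_age:
        return -math.inf
    r = birth - death
    if abs(r) < 1e-12 * max(birth, 1e-300):
        log_p1 = -2.0 * math.log1p(birth * t)
    else:
        e = math.exp(-r * t)
        log_p1 = 2.0 * math.log(abs(r)) - r * t - 2.0 * math.log(abs(birth - death * e))
    return log_p1 - math.log(_bd_F(root_age, birth, death))


def bd_age_prior(
    tree,
    ages: np.ndarray,
    birth: float,
    death: float,
    root_max: float,
) -> float:
    """Joint log prior of all internal node ages.

    Non-root internal ages are i.i.d. conditioned on the root age; the root
    age itself is uniform on (0, root_max].  Invalid configurations
    (parent <= child, root above root_max) get -inf.
    """
    root = tree.root
    root_age = float(ages[root])
    if root_age > root_max or root_age <= 0:
        return -math.inf
    total = -math.log(root_max)  # uniform root-age prior
    for v in range(tree.n_nodes):
        p = tree.parent[v]
        if p >= 0 and ages[p] <= ages[v]:
            return -math.inf
    for v in range(tree.n_nodes):
        if tree.is_tip(v) or v == root:
            continue
        total += bd_node_age_logpdf(float(ages[v]), root_age, birth, death)
        if not math.isfinite(total):
            return -math.inf
    return total


def bd_sample_node_ages(
    n: int, root_age: float, birth: float, death: float, rng
) -> np.ndarray:
    """Direct i.i.d. draws of non-root node ages (inverse-CDF); simulation
    oracle for the MCMC prior."""
    u = rng.random(n) * _bd_F(root_age, birth, death)
    r = birth - death
    if abs(r) < 1e-12 * max(birth, 1e-300):
        return u / (1.0 - birth * u)
    # invert F: u = (1 - e)/(birth - death e)  =>  e = (1 - birth u)/(1 - death u)
    e = (1.0 - birth * u) / (1.0 - death * u)
    return -np.log(e) / r
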