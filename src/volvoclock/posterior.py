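"""Posterior summaries: HPD intervals, convergence diagnostics, chronograms."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import write_annotated_tree
from .tree import RootedTree

__all__ = [
    "hpd_interval",
    "convergence_check",
    "ConvergenceReport",
    "Chronogram",
    "summarize_chronogram",
    "format_hpd",
]


def hpd_interval(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(mass * n)`` sorted draws.

    This is the highest-posterior-density interval for unimodal marginals;
    by construction no contiguous interval with the same sample count is
    shorter.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 100:
        raise ValueError(f"need >= 100 draws for an HPD interval, got {n}")
    m = int(math.ceil(mass * n))
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def format_hpd(lower: float, upper: float, decimals: int = 0) -> str:
    """Render an HPD interval older-bound-first, e.g. ``"349-237"``."""
    return f"{upper:.{decimals}f}-{lower:.{decimals}f}"


# ----------------------------------------------------------------------
# Convergence: rank-normalized split R-hat and effective sample size
# ----------------------------------------------------------------------
def _rank_normalize(chains: np.ndarray) -> np.ndarray:
    """Fractional ranks across all chains mapped through the normal quantile."""
    from scipy.stats import norm, rankdata

    flat = chains.reshape(-1)
    ranks = rankdata(flat, method="average")
    z = norm.ppf((ranks - 3.0 / 8.0) / (flat.size + 0.25))
    return z.reshape(chains.shape)


def _split_chains(chains: np.ndarray) -> np.ndarray:
    m, n = chains.shape
    half = n // 2
    return np.vstack([chains[:, :half], chains[:, half : 2 * half]])


def split_rhat(chains: np.ndarray) -> float:
    """Rank-normalized split R-hat for one parameter, chains shape (m, n)."""
    z = _rank_normalize(_split_chains(np.asarray(chains, dtype=float)))
    m, n = z.shape
    means = z.mean(axis=1)
    if np.allclose(z, z.flat[0]):
        return 1.0
    B = n * means.var(ddof=1)
    W = z.var(axis=1, ddof=1).mean()
    if W <= 0:
        return math.inf
    var_plus = (n - 1) / n * W + B / n
    return float(math.sqrt(var_plus / W))


def ess(chains: np.ndarray) -> float:
    """Bulk effective sample size (Geyer initial monotone sequence)."""
    z = _rank_normalize(_split_chains(np.asarray(chains, dtype=float)))
    m, n = z.shape
    if np.allclose(z, z.flat[0]):
        return float(m * n)
    means = z.mean(axis=1, keepdims=True)
    centered = z - means
    # per-chain autocovariances via FFT
    nfft = int(2 ** math.ceil(math.log2(2 * n)))
    f = np.fft.rfft(centered, nfft, axis=1)
    acov = np.fft.irfft(f * np.conj(f), nfft, axis=1)[:, :n].real / n
    W = z.var(axis=1, ddof=1).mean()
    B = n * z.mean(axis=1).var(ddof=1) if m > 1 else 0.0
    var_plus = (n - 1) / n * W + B / n
    mean_acov = acov.mean(axis=0)
    rho = 1.0 - (W - mean_acov) / var_plus
    # Geyer: sum consecutive pairs while positive and monotone
    tau = 1.0
    prev_pair = math.inf
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        pair = min(pair, prev_pair)
        tau += 2.0 * pair
        prev_pair = pair
        t += 2
    return float(m * n / tau)


@dataclass
class ConvergenceReport:
    table: pd.DataFrame  # parameter, rhat, ess
    passed: bool
    rhat_threshold: float
    ess_threshold: float


def convergence_check(
    chains: "list",
    rhat_threshold: float = 1.1,
    ess_threshold: float = 100.0,
) -> ConvergenceReport:
    """Rank-normalized split R-hat and ESS for every internal node age.

    ``chains`` is a list of PosteriorSamples (one per chain, equal length)
    or a list of per-chain {name: 1-D array} dicts.  Passes iff R-hat is
    below and ESS above their thresholds for all parameters.
    """
    if len(chains) < 2:
        raise ValueError("need at least 2 chains")
    param_arrays = [_chain_params(c) for c in chains]
    names = list(param_arrays[0])
    for pa in param_arrays[1:]:
        if list(pa) != names or any(
            len(pa[k]) != len(param_arrays[0][k]) for k in names
        ):
            raise ValueError("chains have unequal parameterization or length")
    rows = []
    for name in names:
        stacked = np.vstack([pa[name] for pa in param_arrays])
        rows.append(
            {"parameter": name, "rhat": split_rhat(stacked), "ess": ess(stacked)}
        )
    table = pd.DataFrame(rows)
    passed = bool(
        (table["rhat"] < rhat_threshold).all() and (table["ess"] > ess_threshold).all()
    )
    return ConvergenceReport(table, passed, rhat_threshold, ess_threshold)


def _chain_params(chain) -> dict[str, np.ndarray]:
    if isinstance(chain, dict):
        return {k: np.asarray(v, dtype=float) for k, v in chain.items()}
    # PosteriorSamples: every internal node age
    out = {}
    tree = chain.tree
    for v in range(tree.n_nodes):
        if not tree.is_tip(v):
            out[f"age_{v}"] = chain.node_ages[:, v]
    return out


# ----------------------------------------------------------------------
@dataclass
class Chronogram:
    """Per-node posterior mean age and 95% HPD interval."""

    tree: RootedTree
    mean: np.ndarray
    hpd_low: np.ndarray
    hpd_high: np.ndarray
    mass: float = 0.95

    def table(self) -> pd.DataFrame:
        rows = []
        for v in range(self.tree.n_nodes):
            if self.tree.is_tip(v):
                continue
            rows.append(
                {
                    "node": v,
                    "mean_age": self.mean[v],
                    "hpd_low": self.hpd_low[v],
                    "hpd_high": self.hpd_high[v],
                    "hpd": format_hpd(self.hpd_low[v], self.hpd_high[v]),
                }
            )
        return pd.DataFrame(rows)


def summarize_chronogram(samples, mass: float = 0.95) -> tuple[Chronogram, str]:
    """Posterior mean + HPD per node, and the annotated NEXUS tree text.

    Draws are assumed to be post burn-in.  HPD intervals are stored as
    (lower, upper) numerically and printed older-bound-first.
    """
    tree = samples.tree
    n = tree.n_nodes
    mean = np.zeros(n)
    lo = np.zeros(n)
    hi = np.zeros(n)
    annotations = {}
    for v in range(n):
        if tree.is_tip(v):
            continue
        draws = samples.node_ages[:, v]
        mean[v] = float(draws.mean())
        if np.ptp(draws) == 0:
            lo[v] = hi[v] = float(draws[0])
        else:
            lo[v], hi[v] = hpd_interval(draws, mass)
        annotations[v] = {"age": mean[v], "hpd_low": lo[v], "hpd_high": hi[v]}
    chron = Chronogram(tree, mean, lo, hi, mass)
    dated = tree.with_ages(mean)
    text = write_annotated_tree(dated, annotations)
    return chron, text
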