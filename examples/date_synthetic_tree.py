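"""Bayesian node dating on synthetic data with known true ages.

Simulates a 12-tip birth-death chronogram, draws branch rates from the CIR
relaxed clock, generates Poisson substitution counts, calibrates three nodes
with soft bounds around the truth, and re-estimates node ages by MCMC.
"""

import numpy as np

import volvoclock as vc
from volvoclock.dating import DatingModel, mcmc_date
from volvoclock.posterior import convergence_check, summarize_chronogram
from volvoclock.rate_models import RateProcessParams

seed = 42
params = RateProcessParams("CIR", base_rate=1e-3, variance=2e-5, reversion=0.05)
tree = vc.sim_bd_tree(12, birth=0.02, death=0.01, seed=seed)
rates = vc.sim_rates(tree, params, seed=seed + 1)
data = vc.sim_branch_data(tree, rates, sites=1000, seed=seed + 2)

internal = [v for v in range(tree.n_nodes) if not tree.is_tip(v) and v != tree.root]
rng = np.random.default_rng(seed + 3)
nodes = [tree.root] + list(rng.choice(internal, 2, replace=False))
cals = vc.sim_calibrations(tree, nodes, width=0.1 * tree.ages[tree.root], seed=seed + 4)

model = DatingModel(tree=tree, calibrations=cals, clock=params,
                    root_max=2 * float(tree.ages.max()))
samples = mcmc_date(model, data, n_gen=4000, sample_every=4, seed=seed, n_chains=2)

report = convergence_check(samples.split_chains())
print(f"convergence: pass={report.passed}  "
      f"max R-hat={report.table['rhat'].max():.3f}  "
      f"min ESS={report.table['ess'].min():.0f}")

chron, _ = summarize_chronogram(samples)
print(f"{'node':>4} {'truth':>8} {'post mean':>10} {'95% HPD':>16} {'inside':>6}")
for v in range(tree.n_nodes):
    if tree.is_tip(v):
        continue
    inside = chron.hpd_low[v] <= tree.ages[v] <= chron.hpd_high[v]
    hpd = vc.format_hpd(chron.hpd_low[v], chron.hpd_high[v], 1)
    print(f"{v:>4} {tree.ages[v]:>8.1f} {chron.mean[v]:>10.1f} {hpd:>16} {str(inside):>6}")

# Each row compares a true simulated node age (My) with its posterior mean
# and 95% highest-posterior-density interval; with well-calibrated inference
# the truth falls inside the HPD for ~95% of nodes.
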