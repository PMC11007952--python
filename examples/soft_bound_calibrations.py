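"""Soft-bound fossil calibrations: how much mass lies outside the bounds.

Loads the packaged 14-fossil Archaeplastida calibration table, builds the
soft-bound density for one two-sided row (Bangiomorpha) and one minimum-only
row (oldest Zygnemataceae), and integrates each tail numerically.
"""

import math

from scipy.integrate import quad

import volvoclock as vc
from volvoclock.soft_bounds import calibration_logdensity

cals = vc.archaeplastida_calibrations()
print(f"loaded {len(cals)} fossil calibrations")

bang = next(c for c in cals if c.name == "Bangiomorpha")
f = lambda x: math.exp(calibration_logdensity(x, bang))
above = quad(f, bang.max_age, bang.max_age + 2000, limit=600)[0]
below = quad(f, 1e-6, bang.min_age, limit=600)[0]
print(f"Bangiomorpha [{bang.min_age:g}, {bang.max_age:g}] My:")
print(f"  mass above max = {100*above:.3f}%   mass below min = {100*below:.3f}%")

zygn = next(c for c in cals if c.name == "Oldest_Zygnemataceae")
g = lambda x: math.exp(calibration_logdensity(x, zygn))
below = quad(g, 1e-6, zygn.min_age, limit=600)[0]
print(f"Oldest Zygnemataceae (MIN {zygn.min_age:g} My):")
print(f"  mass below min = {100*below:.3f}%")

# Each tail is the small probability that the fossil's true age violates its
# stated bound: 2.5% per side for a two-sided range, 5% below a pure minimum,
# instead of truncating the prior hard at the bounds.
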