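"""Mechanism discrimination: polarity symmetry of the attraction.

If a tick carried a fixed net charge, it would be attracted to one electrode
polarity and repelled by the other; if the force comes from induced
polarization (dielectric polarization or image charging), attraction is
polarity-blind.  This script (i) simulates the +/- threshold comparison and
tests it with the permutation Mann-Whitney and Levene procedures, and
(ii) evaluates both candidate force models in solved rig fields at +750 V
and -750 V to show their sign signatures.
"""

import numpy as np

from electrotick import (
    ParticleModel,
    TickPopulationModel,
    bootstrap_median_ci,
    levene_test,
    mann_whitney_permutation,
    mechanism_forces,
    rig_probe_point,
    simulate_polarity_groups,
)
from electrotick.solver import rig_solution

# --- the statistical comparison on synthetic polarity groups --------------
data = simulate_polarity_groups(TickPopulationModel(), seed=4)
x = data.loc[data.polarity == "+", "threshold_voltage_V"]
y = data.loc[data.polarity == "-", "threshold_voltage_V"]
mw = mann_whitney_permutation(x, y, seed=0)
lev = levene_test(x, y)
for sign, vals in (("+", x), ("-", y)):
    ci = bootstrap_median_ci(vals, seed=0)
    print(f"polarity {sign}: median threshold {np.median(vals):.0f} V "
          f"(bootstrap 95% CI {ci.ci[0]:.0f}-{ci.ci[1]:.0f})")
print(f"Mann-Whitney U = {mw.statistic:.1f}, permutation p = {mw.p_value:.2f}")
print(f"Levene F = {lev.statistic:.2f}, p = {lev.p_value:.2f}")
print("-> no polarity effect, as expected under the induction mechanism\n")

# --- the force models in the solved fields ---------------------------------
tick = ParticleModel(q=1e-12, alpha=1e-18)  # illustrative q and alpha
point = rig_probe_point(0.0005)
pos = rig_solution(gap=0.003, voltage=750.0, h_fine=1e-4)
neg = rig_solution(gap=0.003, voltage=-750.0, h_fine=1e-4)
for name, sol in (("+750 V", pos), ("-750 V", neg)):
    induced, fixed = mechanism_forces(sol, tick, point)
    print(f"{name}: induced-dipole force z = {induced[1]:+.3e} N, "
          f"fixed-charge force z = {fixed[1]:+.3e} N")
print()
print("The induced-dipole force is identical under both polarities (it")
print("scales with grad |E|^2) while the fixed-charge force flips sign —")
print("equal attraction at both polarities implicates induction.")
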