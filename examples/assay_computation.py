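"""From raw assay readings to the eight surface properties.

Shows the individual assay computations on constructed inputs: the MATH
hydrophobicity fraction, the titration charge profile of a two-site
protonation model (net charge at pH 8, total acidity, point of zero
charge), and EPS quantitation through a linear standard curve.
"""

import numpy as np

import colisurf as cs
from colisurf.assays import (
    StandardCurve, charge_at, eps_concentration, hydrophobic_partitioning,
    net_charge_profile, point_of_zero_charge, total_acidity,
)
from colisurf.cohort import model_net_charge, titration_curve_from_model

# --- MATH hydrophobicity -------------------------------------------------
h = hydrophobic_partitioning(initial_od=0.40, aqueous_od=0.04)
print(f"MATH hydrophobicity (0.40 -> 0.04): {h:.2f}")
# 90% of cells partitioned into the dodecane phase

# --- titration charge accounting ----------------------------------------
sites = [(1.2e-4, 5.0), (0.8e-4, 8.5)]  # (density meq/1e8 cells, pKa)
offset = 9.0e-5
ph = np.round(np.arange(4.0, 10.01, 0.05), 10)
sample, blank = titration_curve_from_model(sites, ph, n_bact=1e8, offset=offset)
profile = net_charge_profile(sample, blank)

q8 = charge_at(profile, 8.0)
print(f"net charge at pH 8.0 : {q8: .3e} meq/1e8 cells "
      f"(model: {model_net_charge(8.0, sites, offset): .3e})")
print(f"total acidity        : {total_acidity(profile): .3e} meq/1e8 cells")
print(f"point of zero charge : {point_of_zero_charge(profile):.2f} pH")
# the PZC is where deprotonation overtakes the fixed positive offset charge

# --- EPS standards -------------------------------------------------------
conc = np.array([0.0, 50.0, 100.0, 200.0, 400.0])  # ug per assay
curve = StandardCurve(conc, 0.002 * conc + 0.02)
eps = eps_concentration(absorbance=0.52, curve=curve, n_cells=4.5e10)
print(f"EPS protein at A=0.52, 4.5e10 cells: {eps:.3f} ug / 1e8 cells")
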