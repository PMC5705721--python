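#!/usr/bin/env python
"""Mechanical summary: bending rigidities and network moduli.

Converts the measured tubule geometry (persistence length with and
without branch points, mean outer radius) into filament and membrane
bending rigidities, and evaluates the honeycomb-foam scaling of the
network moduli at the observed slenderness.  Writes
results/mechanics_summary.json.
"""

from pathlib import Path

from ermech import fileio
from ermech.mechanics import honeycomb_moduli, tubule_mechanics

BASE = Path(__file__).resolve().parent.parent / "results"

L_P_ALL_UM = 3.03  # whole-network persistence length
L_P_BETWEEN_UM = 4.71  # between branch points
RADIUS_NM = 44.1
BRANCH_SPACING_UM = 3.0  # mid-range of the 1-5 um junction spacing

if __name__ == "__main__":
    summary = {}
    for name, lp in (("all_tubules", L_P_ALL_UM), ("between_junctions", L_P_BETWEEN_UM)):
        rep = tubule_mechanics(lp, RADIUS_NM, 298.0)
        summary[name] = rep.to_dict()
        print(f"{name}: L_p = {lp} um -> kappa_mem = {rep.kappa_mem_kT:.3g} kT "
              f"= {rep.kappa_mem_J:.3g} J; kappa_pol = {rep.kappa_pol_Jm:.3g} J m")
    moduli = honeycomb_moduli(2 * RADIUS_NM, BRANCH_SPACING_UM)
    summary["network_moduli"] = moduli.to_dict()
    print(f"honeycomb network (2r/L = {2 * RADIUS_NM * 1e-3 / BRANCH_SPACING_UM:.2g}): "
          f"E_in/E = {moduli.ratio_Ein_E:.2g}, G_in/E = {moduli.ratio_Gin_E:.2g}, "
          f"E_out/E = {moduli.ratio_Eout_E:.2g}")
    fileio.write_json(summary, BASE / "mechanics_summary.json")
    print("wrote", BASE / "mechanics_summary.json")
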