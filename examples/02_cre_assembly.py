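"""Deduplicate sampled snapshots into a conformer-rotamer ensemble (CRE).

Samples a two-torsion toy molecule with RMSD-biased metadynamics, locally
optimizes the snapshots (samplers always refine before filtering, since
raw finite-temperature geometries are all slightly distinct), then reduces
them to distinct conformers with the energy / RMSD / rotational-constant
criteria and the staged 15/10/6 kcal/mol retention windows.
"""

import numpy as np
from scipy.optimize import minimize

from crebind import (
    Ensemble,
    MTDParams,
    ToyTorsionModel,
    embed,
    measure_torsions,
    run_mtd,
    staged_refine,
    toy_energy,
)

model = ToyTorsionModel(
    n_torsions=2,
    amplitudes=((2.0, 0.4),) * 2,   # kcal/mol barrier terms
    multiplicities=((3, 1),) * 2,   # three-fold wells plus a one-fold tilt
    phases=((0.0, 0.0),) * 2,
)
sampled = run_mtd(model, MTDParams(steps=3000, T=300.0, seed=1))
print(f"sampled {len(sampled)} accepted snapshots")

optimized = []
for s in list(sampled)[::10]:
    res = minimize(lambda p: toy_energy(model, p), measure_torsions(s))
    phi = np.mod(res.x + np.pi, 2 * np.pi) - np.pi
    optimized.append(embed(model, phi))
print(f"locally optimized every 10th snapshot: {len(optimized)} structures")

cre = staged_refine(Ensemble(optimized), windows=(15.0, 10.0, 6.0))
print(f"survivors per window stage (15/10/6 kcal/mol): {cre.stage_counts}")
print(f"final CRE: {cre.n_conformers} conformer groups, "
      f"{cre.n_structures} structures")
print("representatives (kcal/mol above the global minimum):")
e0 = cre.representative_energies.min()
for g in cre.groups:
    print(f"  {g.representative.energy_total - e0:6.3f}  "
          f"(+{len(g.rotamers)} rotamer images)")
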