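"""Trajectory statistics on a synthetic enzyme-peptide contact system.

Builds a small synthetic trajectory in which a key hydrogen bond
(His6 backbone NH to an enzyme carbonyl) is present in a prescribed
fraction of frames, then recovers the contact population, the RMSD
series and a backbone dihedral series — the statistics used to judge
Michaelis-complex stability.
"""

import numpy as np
import pandas as pd

from acecleave.traj import (
    HBondSpec,
    Trajectory,
    hbond_populations,
    rmsd_series,
    synth_trajectory,
    zinc_geometry_check,
)

atoms = pd.DataFrame({
    "name":    ["N", "H", "CA", "C", "O", "ZN", "NE2", "NE2", "OE1", "OW"],
    "resname": ["HIS", "HIS", "HIS", "ALA", "ALA", "ZN", "HIS", "HIS", "GLU", "HOH"],
    "resid":   [6, 6, 6, 332, 332, 1, 361, 365, 389, 500],
    "chain":   ["P", "P", "P", "E", "E", "Z", "E", "E", "E", "W"],
})
d = 2.1 / np.sqrt(3)
coords = np.array([[
    [0, 0, 0], [1, 0, 0], [0, 1.5, 0], [3, 0, 1], [3.5, 0, 0],
    [8, 8, 8], [8 + d, 8 + d, 8 + d], [8 + d, 8 - d, 8 - d],
    [8 - d, 8 + d, 8 - d], [8 - d, 8 - d, 8 + d],
]], dtype=float)
template = Trajectory(atoms, coords)

contact = HBondSpec(donor="P:6:N", hydrogen="P:6:H", acceptor="E:332:O")
schedule = np.zeros(200, dtype=bool)
schedule[:178] = True  # contact held in 89% of frames
traj = synth_trajectory(template, {contact: schedule}, jitter_sigma=0.05, seed=3)

(pop,) = hbond_populations(traj, [contact])
print(f"contact {pop.spec.label}: population {pop.population:.2f} "
      "(constructed at 0.89; a stable scissile-bond contact)")

series = rmsd_series(traj, "P:*:*")
print(f"peptide RMSD vs frame 0: mean {series.mean():.3f} A, "
      f"max {series.max():.3f} A over {traj.n_frames} frames")

zn = zinc_geometry_check(traj, "Z:1:ZN",
                         ["E:361:NE2", "E:365:NE2", "E:389:OE1", "W:500:OW"])
print(f"tetrahedral zinc coordination retained in "
      f"{100 * zn['retained'].mean():.1f}% of frames")
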