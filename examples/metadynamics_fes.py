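"""Well-tempered metadynamics on a toy double well, start to finish.

Runs a short multiple-walker well-tempered run (gamma = 10, initial hill
height 1.2 kJ/mol, hills every 10 ps with adaptive widths) on a tilted
2-D double well, then reconstructs the free-energy surface from the
hills and reports the free-energy difference between the two basins.

This is a scaled-down illustration; `metadyn.double_well_benchmark`
runs the full calibrated version with both reconstruction routes.
"""

import numpy as np

from ampardyn import metadyn

pot = metadyn.ToyPotential.double_well(barrier=6.0, tilt=2.837, ky=30.0)
params = metadyn.WTParams()  # T=300 K, gamma=10, h0=1.2 kJ/mol, 10 ps deposits
print(f"bias factor gamma = {params.gamma}, effective T = {params.T * params.gamma:.0f} K")

log, samples = metadyn.run_toy_metad(
    pot, params, langevin=(30.0, 0.2, 300.0), n_steps=20_000, n_walkers=4,
    seed=1, domain=((-1.9, 1.9), (-2.5, 2.5)), sigma_floor=0.05, sigma_cap=0.5,
)
print(f"deposited {len(log)} hills over {max(h.time for h in log.hills):.0f} ps")
print(f"hill heights decayed from {log.hills[0].height:.2f} "
      f"to {np.mean([h.height for h in log.hills[-8:]]):.2f} kJ/mol (well-tempering)")

fes = metadyn.fes_from_hills(log, params, ((-1.9, 1.9, 77), (-1.5, 1.5, 61)))
dF = metadyn.well_free_energy_difference(fes)
print(f"basin free-energy difference: {dF:.2f} kJ/mol "
      f"(quadrature reference for this potential: 5.00)")
# A short run lands within ~1-2 kJ/mol; the calibrated benchmark run
# (120k steps) recovers the reference within 1 kJ/mol by both routes.
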