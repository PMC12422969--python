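"""Conformational coordinates of a two-lobed receptor-domain dimer.

Builds a synthetic dimer with a prescribed displacement torsion of -25
degrees (a "displaced" conformation) and zero opening, then recomputes
both coordinates from the atom positions, and finally tracks a
trajectory that drifts from flat (0 degrees) to displaced (-25 degrees).
"""

import numpy as np

from ampardyn import confcoords, synthgen

# one displaced dimer ------------------------------------------------------
spec = synthgen.DimerSpec(torsion=-25.0, opening=0.0, noise=0.0, seed=7)
dimer = synthgen.make_two_lobe_dimer(spec)
cp = confcoords.coords_pair(dimer, spec.lobe_definition())
print(f"displacement torsion: {cp.displacement_torsion:+.3f} deg  (prescribed -25)")
print(f"opening angle:        {cp.opening_angle:+.3f} deg  (prescribed 0)")
# Near 0 deg means a flat dimer; around -25 deg matches displaced dimers.

# a flat-to-displaced trajectory ------------------------------------------
schedule = [(t, 0.0) for t in np.linspace(0.0, -25.0, 50)]
frames = synthgen.make_dimer_trajectory(schedule, synthgen.DimerSpec(seed=7, noise=0.2))
series = confcoords.coords_series(frames, spec.lobe_definition())
print("\nfirst / middle / last frame of the drift:")
print(series.iloc[[0, 24, 49]].to_string(index=False))
# The torsion column follows the prescribed 0 -> -25 deg schedule; the
# 0.2 A coordinate noise perturbs the recovered angles by a few tenths
# of a degree.
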