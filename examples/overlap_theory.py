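"""Contractile-unit overlap theory on random motor placements.

Scatters N_M = 52 reference motors (462 nm, 24 arms) on a 20-µm periodic
bundle, evaluates the maximum cooperative group Xi and the predicted bundle
force F_est = 547.2 * Xi pN, and shows how confining the motors to a
fraction f of the bundle raises both.
"""

import numpy as np

from actomyosim.overlap import (estimate_force, sample_bundle_placements,
                                xi_max)

print(f"{'f':>6s} {'E[Xi]':>8s} {'E[F_est] (pN)':>14s}")
for f in (1.0, 0.5, 0.25, 0.12, 0.06):
    xis = []
    for s in range(100):
        motors = sample_bundle_placements(52, np.random.default_rng(s), f=f)
        xis.append(xi_max(motors, box=20000.0).Xi)
    e_xi = np.mean(xis)
    print(f"{f:6.2f} {e_xi:8.2f} {estimate_force(e_xi, 24):14.0f}")

print("\nSmaller f packs the same 52 motors into a shorter stretch of"
      "\nbundle: more pairs overlap beyond the 420-nm critical length, the"
      "\nstrongest cooperative group grows, and so does the predicted force.")
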