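"""Sparse motors in the thinnest disorganized bundle: eta ~ 1/N_M.

An 8-filament bundle (N_F = 2 lane grid, 27-nm pitch) with four motors
placed anywhere (f = 1) and dense permanent cross-linkers.  Sparse motors
rarely overlap, so each forms its own contractile unit; units in series do
not add forces, hence the bundle delivers roughly a single motor's force
and eta = F_tot / F_M_max ~ 1/4.

Takes a couple of minutes.
"""

from actomyosim.experiments import run_thin_bundle

res = run_thin_bundle(seed=1, duration_s=9.0)
print(f"F_tot   = {res.F_tot:7.1f} pN")
print(f"F_M_max = {res.F_M_max:7.1f} pN")
print(f"eta     = {res.eta:7.3f}   (1/N_M = 0.25 for four motors)")
print(f"per-motor |z| arm forces (pN): "
      f"{[round(x) for x in res.F_M_per_motor]}")
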