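"""Build bipolar motors of the three architecture families and compare.

Prints, for each variant, the backbone length L_M and the critical overlap
length L_c = 2*L_sp*(N_a/4 - 1) two motors must share before their forces
add.  A long bare zone lengthens the motor *without* raising L_c, which is
why it helps cooperative force generation.
"""

from actomyosim import build_motor, critical_length

VARIANTS = [
    ("reference (N_a=24)", 24, 42, 42),
    ("more arms (N_a=48)", 48, 42, 42),
    ("long bare zone (N_a=16, L_bz=714)", 16, 714, 42),
    ("wide spacing (N_a=16, L_sp=138)", 16, 138, 138),
]

print(f"{'variant':38s} {'L_M (nm)':>9s} {'L_c (nm)':>9s} {'segments':>9s}")
for name, N_a, L_bz, L_sp in VARIANTS:
    m = build_motor(N_a, L_bz, L_sp)
    print(f"{name:38s} {m.L_M:9.0f} {critical_length(N_a, L_sp):9.0f} "
          f"{m.segment_count:9d}")

print("\nEqual-length motors (966 nm): the bare-zone variant needs only a"
      "\n252-nm overlap to cooperate fully, the wide-spacing variant 828 nm.")
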