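"""Pulse tables of the three coding variants and the clinical-unit law.

Builds the sequential (S), paired (P) and triplet (T) stimulation schedules
and converts a few clinical-unit amplitudes to output current.
"""
from cisim import sound_coding as sc

for variant in ("S", "P", "T"):
    t = sc.build_pulse_table(variant)
    print(f"variant {variant}: {len(t.groups)} groups per 540 us cycle, "
          f"gap {t.gap_us:.1f} us after each group")
    print(f"  groups: {t.groups}")

print()
for cu in (50, 250, 471):
    ua = sc.cu_to_microamps(cu, phase_us=18.0)
    print(f"{cu:3d} CU at 18 us phase -> {ua:7.1f} uA")
print("Per-channel rate is 1/540 us =", f"{1e6 / 540:.0f} pulses/s",
      "for every variant: the gaps keep simultaneous variants at the same rate.")
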