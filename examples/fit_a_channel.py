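"""Virtual fitting of one channel under two neural-health conditions.

Builds a small electrode-nerve interface, applies healthy and severe
degeneration, and estimates the most-comfortable level (MCL) of a mid-array
virtual channel from the spike activity of its fitting group.
"""
from cisim import cochlea, excitation, fitting
from cisim.anf import NeuronParams

base = cochlea.build_geometry(cochlea.CochleaConfig(n_fibers=301))
params = NeuronParams()

for health in ("healthy", "severe"):
    itf = cochlea.apply_degeneration(base, cochlea.HEALTH_PRESETS[health],
                                     sd_nodes=3, seed=1)
    model = excitation.ExcitationModel(itf)
    group = fitting.select_fitting_group(8, model)
    mcl = fitting.estimate_mcl(8, model, params, seeds=(0, 1, 2))
    print(f"{health:8s}: channel 8 MCL = {mcl:3d} CU "
          f"(T = {round(0.1 * mcl)} CU, fitting group of {len(group)} fibers)")

print("Degenerated fibers need more current for the same spike probability,"
      " so the severe MCL is higher.")
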