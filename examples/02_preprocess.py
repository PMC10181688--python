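"""From raw intensities to filtered hemoglobin: OD -> MBLL -> band-pass.

Simulates one run, converts its two-wavelength intensities to optical
density, inverts the modified Beer-Lambert law, and applies the zero-phase
FIR(71) 0.01-0.4 Hz band-pass.
"""

import numpy as np

import nirsconn as nc

truth = nc.make_ground_truth(M=4, K=0, seed=1)
experiment = nc.simulate_experiment(truth, conditions=["barefoot"], seed=1)
geometry, recording = experiment.geometry, experiment.runs[0].recording

od = nc.optical_density(recording)
hb = nc.mbll(od, geometry, fs=recording.fs,
             run_condition=recording.run_condition,
             event_markers=recording.event_markers)
taps = nc.design_fir_bandpass(nc.FilterSpec(order=71, band=(0.010, 0.400),
                                            fs=recording.fs))
filtered = nc.apply_filter(hb, taps)

print(f"intensities : {recording.intensities.shape} (channels x time)")
print(f"HbO (uM)    : {hb.hbo.shape} -- one row per source-detector pair")
print(f"HbO sd before/after filtering: "
      f"{hb.hbo.std():.3f} / {filtered.hbo.std():.3f} uM")
demean = lambda a: a - a.mean(axis=1, keepdims=True)
print(f"MBLL inversion error vs simulator truth (DC removed): "
      f"{np.max(np.abs(demean(hb.hbo) - demean(experiment.runs[0].hb.hbo))):.2e} uM")
print("\nThe filter keeps the hemodynamic band (10-400 mHz) and removes")
print("fast noise; zero-phase application preserves the lag structure the")
print("connectivity model depends on.")
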