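"""Full imaging pipeline: render an agonist-evoked Ca2+ transient and
quantify it back to concentration.

A two-channel time-lapse (cells with punctate nanosensor foci, shot/read
noise, per-channel bleaching) is generated from a known Ca(t) rising from
100 nM to 400 nM, then pushed through ROI extraction, background
subtraction, photobleach correction, ratio computation and dose-response
inversion.
"""

import numpy as np

import ionoptode as ion

comp = ion.DEFAULT_COMPOSITION
eq = ion.default_equilibrium(comp)

series, _ = ion.make_calibration_series(
    comp, eq, noise=ion.NoiseSpec.plate_reader(seed=1), n_replicates=9
)
fit = ion.fit_hill(series)

spec = ion.TransientSpec()  # 100 nM baseline, 400 nM peak, 1 s frames, 10 min
t, ca = ion.make_transient_trace(spec, frame_interval=1.0)
stack, truth = ion.render_stack(
    (t, ca), comp, eq, noise=ion.NoiseSpec.paper_like(seed=2), shape=(128, 128)
)
print(f"rendered {stack.n_frames} frames of {stack.frame_shape} "
      f"({len(truth.cell_masks)} cells)")

traces, summaries = ion.quantify_timelapse(
    stack,
    truth.roi_set(),
    fit,
    stimulus_frame=int(spec.onset),
    static_reference=True,                       # reference dye ~ion-independent
    quiescent_windows=[(480, stack.n_frames)],   # trace has recovered by then
    peak_search_s=120.0,                         # store release peaks early
)

print(f"\n{'ROI':8s} {'baseline':>10s} {'peak':>10s} {'t_peak':>7s} {'recovery':>9s}")
for name, s in summaries.items():
    print(f"{name:8s} {s['baseline_molar']*1e9:8.0f} nM {s['peak_molar']*1e9:8.0f} nM "
          f"{s['time_to_peak_s']:5.0f} s {s['recovery_fraction']:9.2f}")
print(f"\ngenerator truth: baseline {spec.baseline*1e9:.0f} nM, peak {spec.peak*1e9:.0f} nM")
print("baseline/peak within ~10% of truth shows the ratio -> concentration "
      "chain is quantitative at this noise level, not merely qualitative.")
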