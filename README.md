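# perfviz

Quantitative assessment of intraoperative tissue perfusion from optical
imaging, built around a porcine model of partial pancreatic ischemia. The
package implements the full analysis chain as a tested, reusable library:

- **Fluorescence slope cartography.** After an intravenous indocyanine-green
  bolus, each pixel's fluorescence rises to a maximum; well-perfused tissue
  fills fast, ischemic tissue slowly. The perfusion surrogate is the slope
  `(I_peak − I_baseline) / t_peak` of the per-pixel inflow curve, computed
  from a 40 s video at 25 fps. Because absolute fluorescence falls with
  camera distance (inverse-square law), every frame is first divided by the
  mean signal of a constant-fluorescence reference card placed in the scene.
- **StO2 mapping and zone classification.** Hyperspectral imaging yields a
  per-pixel tissue oxygen saturation map (percent). Vital, transition and
  ischemic regions are segmented by StO2 thresholds (defaults 63% / 33%).
- **Enhanced-reality registration.** The static StO2 map is deformed onto
  the fluorescence cartography by affine moving least squares from manually
  picked landmark pairs, then alpha-blended onto the live surgical video.
- **Capillary density morphometry.** Confocal-endomicroscopy-like frames are
  segmented for elongated bright vessels; the functional capillary density
  area index is `mean diameter × total centerline length / FOV area`.
- **Lactate prediction.** Local capillary lactate (LCL) in excess of the
  systemic level follows an exponential law in either perfusion metric,
  `LCL = exp(−a·x + b) + systemic`, fitted by nonlinear least squares and
  validated by leave-one-subject-out cross-validation, paired Wilcoxon model
  comparison, Spearman correlation and a Fisher-z sample-size formula.

No imaging data from the original experiment is released, so the package
ships a first-class synthetic-data generator (`perfviz.synthgen`) that
emulates the experiment with analytic ground truth: three-zone scenes with
zone-dependent inflow kinetics and StO2 levels, a constant reference card,
global distance attenuation, vessel phantoms of known geometry, and cohorts
drawn from the exponential lactate models. Every estimator is tested
against that ground truth.

## Worked example

```python
from perfviz.pipeline import PipelineConfig, run_experiment

report = run_experiment(PipelineConfig(seed=1))
for zone in ("vital", "transition", "ischemic"):
    s = report["imaging"]["sto2_by_zone"][zone]
    f = report["imaging"]["slope_by_zone"][zone]
    print(f"{zone:10s} StO2 {s['mean']:5.1f} ± {s['sd']:4.1f} %   "
          f"slope {f['mean']:.4f} ± {f['sd']:.4f} /s")
print("Spearman LCL~StO2 :", round(report["cohort"]["spearman"]["lcl_vs_sto2"]["rho"], 3))
print("CV mean error StO2 model:",
      round(report["cohort"]["cv_error_summaries"]["sto2"]["mean"], 2), "mmol/L")
```

prints

```
vital      StO2  76.6 ±  5.8 %   slope 0.1225 ± 0.0596 /s
transition StO2  48.9 ±  6.8 %   slope 0.0732 ± 0.0236 /s
ischemic   StO2  16.6 ±  4.9 %   slope 0.0212 ± 0.0022 /s
Spearman LCL~StO2 : -0.882
CV mean error StO2 model: 2.51 mmol/L
```

The ischemia gradient is visible in both modalities (vital > transition >
ischemic in StO2 and inflow slope), lactate rises as oxygenation falls
(negative rank correlation), and the cross-validated lactate prediction
error is a couple of mmol/L at the 6-subject, 18-record scale. The same
experiment is available from the shell:

```sh
perfviz run --seed 1 --out rundir/       # full experiment + artifacts
perfviz report rundir/                   # scatter/fit and zone figures
perfviz lact samplesize --r 0.78         # -> 13 paired values
```

Each stage also has its own subcommand (`perfviz synth ...`,
`perfviz fler slope ...`, `perfviz er warp ...`, `perfviz fcda run ...`,
`perfviz lact fit|cv|compare ...`) operating on TIFF/CSV files; see
`perfviz --help`.

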