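# qmpm — quantitative multiphoton microscopy of vascular function

`qmpm` turns intravital multiphoton time-lapse imaging of a fluorescent
tracer into quantitative measures of vascular function. It was built
for bone-marrow vasculature imaged through the mouse calvarium, where a
150-kDa dextran bolus leaks from sinusoidal vessels into the marrow,
but applies to any single-plane tracer time-lapse with pixel-size and
frame-interval calibration.

From one acquisition the pipeline measures:

- **K_trans** (1/min) — the volume transfer constant of tracer from
  blood to the extravascular extracellular space (EES), from a
  two-compartment fit with equal exchange rates (Tofts form):

      C_t(t) = K_trans · ∫₀ᵗ C_b(τ) · exp(−(K_trans/v_ec)(t−τ)) dτ

- **v_ec** — the fractional EES, i.e. the tissue volume fraction the
  tracer can reach;
- **vascular permeability** (um/min) — `K_trans / (S/V)`, with `S/V`
  the vascular surface area per image volume from the segmented lumen;
- **single-vessel morphometry and velocimetry** — inner diameters and
  vessel density from skeletonised blood masks, and intravascular cell
  velocities (mm/s) from fast time-lapses, paired per vessel with
  diameter.

Supporting stages — phase-correlation drift coregistration, Otsu
compartment segmentation, compartment-curve extraction, biexponential
blood-clearance fits — are part of the package, as is a seeded
synthetic-stack generator that renders ground-truthed acquisitions
(vessel geometry, bolus input function, leakage kinetics, moving cells,
photon noise, frame drift) so every stage is validated by parameter
recovery. See `docs/methods.md` for the model, assumptions and
numerical choices.

## Worked example

Simulate one default acquisition (256 × 256 um field, 1 um/px, 1 Hz for
10 min, bolus arrival drawn from 6–12 s, K_trans = 0.05/min,
v_ec = 0.30, blood-curve SNR ≈ 20, 3.5/−2.5 px of drift), then run the
full pipeline on it:

```python
from qmpm.synthetic import SimulationConfig, simulate_stack
from qmpm.registration import estimate_drift, apply_drift_correction
from qmpm.segmentation import segment_compartments, SegmentationStrategy
from qmpm.kinetics import extract_time_curves, TwoCompartmentModel

config = SimulationConfig(drift_total_px=(3.5, -2.5), include_blood_pool=True)
stack, truth = simulate_stack(config, seed=42)

track = estimate_drift(stack, channel="blood_pool", reference=0)
corrected = apply_drift_correction(stack, track)
masks = segment_compartments(
    corrected, SegmentationStrategy(blood_channel="blood_pool")
)
blood, tissue = extract_time_curves(corrected, masks, channel="tracer")

results = TwoCompartmentModel(blood, tissue).fit()
results.attach_surface_area(masks.surface_area_per_volume())
print(results.summary())
```

prints

```
Two-compartment leakage model
=============================================
n time points                             601
bolus arrival (s)                       11.00
K_trans (1/min)                      0.050723
v_ec (fraction)                       0.29787
permeability (um/min)                  1.5097
S/V (1/um)                           0.033597
R-squared                             0.98986
residual SS                        0.00016386
identifiable                             True
=============================================
```

The fitted `K_trans` (0.0507/min) and `v_ec` (0.298) recover this
stack's programmed ground truth (0.05/min, 0.30) to about 1% after
drift correction and automatic segmentation; `permeability` is
`K_trans` divided by the measured surface area per volume, and
`identifiable` confirms the tissue uptake rose clearly above the
pre-arrival noise floor. `results.plot_fit()` overlays the fitted
tissue curve on the measured ones, and `results.summary()` gains
bootstrap confidence intervals when fitted with `fit(bootstrap=200,
seed=...)`.

Vessel morphometry and velocimetry work from a blood mask and a fast
time-lapse:

```python
from qmpm.vasculometry import (
    skeletonize_vessels, vessel_diameters, vessel_density,
    track_cells, cell_velocities,
)

skel = skeletonize_vessels(masks.blood, stack.pixel_size_um)
diameters = vessel_diameters(skel)          # per-segment + field mean, um
density = vessel_density(skel, masks.analyzable_area_mm2)   # 1/mm^2
```

## Command line

The same pipeline is scriptable through a thin CLI (configs are YAML,
records JSON, tables CSV, stacks TIFF):

```sh
qmpm simulate     --config sim.yaml  --out stacks/
qmpm fit          --config fit.yaml  --out run1/
qmpm vasculometry --config vasc.yaml --out run2/
qmpm report       --records runs/    --out summary.csv
```

Every record embeds the seed and a config hash; reruns with the same
config and seed reproduce outputs bit for bit.

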