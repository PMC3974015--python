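# cerevasc

Analysis pipeline for **negative-contrast Cerenkov luminescence imaging
(CLI)** of blood vessels, with a forward scene simulator that provides
exact ground truth.

## The problem

When a beta-emitting radiotracer with long blood residence (e.g.
[68Ga]GaCl3) distributes through a mouse, the Cerenkov light from all
deeper tissue forms a diffuse *backlight* at the skin surface. Superficial
blood vessels absorb red/near-infrared light strongly, so they appear as
dark lines against that backlight — they are imaged by the light they
*remove*, not the light they emit. This package is for imaging scientists
who want to quantify that negative contrast:

* **Decay bookkeeping** — A(t) = A₀·2^(−t/T½) with Ga-68 (67.71 min) and
  F-18 (109.77 min) constants; forward decay and correction back to
  injection time.
* **Phantom calibration** — OLS fit of ROI radiance (p/s/cm²/sr) against
  vial activity (MBq); the slope is the nuclide's light yield, and slope
  ratios compare nuclides (Ga-68 ≈ 11.9× F-18).
* **Vessel attenuation** — for a vessel ROI with congruent flanking ROIs
  immediately left and right: attenuation = 1 − mean(vessel)/mean(flanks).
  The same local-ratio statistic against a rim reference gives the
  radiance reduction of a necrotic tumor core.
* **Biodistribution** — %ID/g from gamma counts, muscle-normalized
  activity and optical-flux ratios, and the per-organ light-to-activity
  ratio (blood ≈ 0.05: the most activity, the least light).
* **Cohort statistics** — pooled-variance two-tailed Student's t test of
  tumor-side vs contralateral vessel attenuation (Welch optional).
* **Simulation** — phantom well plates, backlit mouse scenes with
  semicircular-profile vessels, tumors and necrotic cores, Gaussian PSF,
  Poisson shot noise, dark floor and cosmic spikes, all reproducible from
  one master seed. Details and assumptions: `docs/methods.md`.

## Worked example

```python
import json
from cerevasc import sample_cohort, measure_cohort, cohort_report
from cerevasc.physics import GA68, ActivitySample, decay_correct_activity

# Scan-time activity of a mouse injected with 14 MBq, imaged 50 min later
print(round(decay_correct_activity(ActivitySample(14, 50), GA68), 1))

# A 13-mouse synthetic cohort: one tumor-side vessel (true attenuation
# ~ N(10%, 4%)) and one contralateral vessel (~ N(3%, 1%)) per mouse,
# rendered and measured with the flanking-ROI estimator.
scenes = sample_cohort(13, seed=7)
report = cohort_report(measure_cohort(scenes))
print(json.dumps(report, indent=1))
```

prints `8.4` (MBq remaining at scan time) and then

```json
{
 "groups": {
  "non-tumor-side": {
   "n": 13, "mean": 0.02402656777393943, "sd": 0.007557580008962423,
   "min": 0.012527742621838311, "max": 0.036735395470283594
  },
  "tumor-side": {
   "n": 13, "mean": 0.09636855798782464, "sd": 0.025312983789758374,
   "min": 0.061381480657363485, "max": 0.15393049236073664
  }
 },
 "test": {
  "t": -9.873626166012787, "df": 24.0, "p": 6.3e-10,
  "significant_at_0_05": true, "welch": false,
  "groups": ["non-tumor-side", "tumor-side"]
 }
}
```

The tumor-side vessels of this particular cohort attenuate 9.6% ± 2.5% of
the backlight versus 2.4% ± 0.8% on the contralateral side, and the pooled
t test finds the difference highly significant — the dilated tumor
vasculature removes roughly three times more light.

The same pipeline is scriptable from the shell:

```bash
cerevasc simulate-cohort --n 13 --seed 7 --out runs/cohort
cerevasc quantify-vessels --manifest runs/cohort/manifest.csv --out runs/measurements.csv
cerevasc cohort-stats --measurements runs/measurements.csv --out runs/report.json
```

Other subcommands: `simulate-phantom`, `calibrate`, `simulate-mouse`,
`biodist`. Images are 32-bit float TIFFs with JSON metadata sidecars;
every output directory gets a provenance record with the master seed and a
configuration digest.

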