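# pulsefeat

Peripheral (arteriole/capillary) hemodynamics from multi-wavelength
finger photoplethysmography.

A PPG measured at a green (~525 nm) and a near-infrared (~940 nm)
wavelength probes two tissue depths: green light stops in the
superficial capillary bed, near-infrared light reaches the deeper
arterioles. `pulsefeat` turns such dual-channel recordings into two
hemodynamic indices:

* **1/FWHM_VPG** — reciprocal full width at half maximum of the
  velocity plethysmogram's systolic peak, an index of upstroke
  steepness that tracks distal blood pressure;
* **green-vs-NIR a-wave delay** — the lag of the green acceleration
  plethysmogram (APG) a-wave behind the near-infrared one, a surrogate
  for the arteriole-to-capillary pulse transit time (Bramwell–Hill:
  PWV² = ΔP·V/(ρ·ΔV), so a longer delay means a lower distal pulse
  pressure).

The package implements the full chain — 0.5–20 Hz zero-phase band-pass,
smoothed differentiation to VPG/APG, beat segmentation, APG a–e wave
detection with sub-sample peak timing, pulse height S with baseline
slope correction, template-subtraction SNR with the strict SNR < 200
exclusion rule, Welch group comparison — plus a calibrated
dual-wavelength PPG simulator that provides ground truth for every
stage, so the whole pipeline is testable without access to clinical
recordings. Intended users are physiological-signal researchers and
wearable-device engineers.

## Worked example

```python
from pulsefeat import PRESETS, run_pipeline, simulate_cohort, compare_groups
import pandas as pd

records_d, truth_d = simulate_cohort(PRESETS["diabetes"], 50, seed=7)
records_c, truth_c = simulate_cohort(PRESETS["control"], 21, seed=8)
feats_d, qc_d, _ = run_pipeline(records_d)
feats_c, qc_c, _ = run_pipeline(records_c)

print(f"diabetes  1/FWHM_VPG {feats_d['inv_fwhm_vpg'].mean():.2f} 1/s, "
      f"delay {feats_d['delay_green_nir'].mean()*1000:.1f} ms "
      f"({len(feats_d)} records kept)")
print(f"control   1/FWHM_VPG {feats_c['inv_fwhm_vpg'].mean():.2f} 1/s, "
      f"delay {feats_c['delay_green_nir'].mean()*1000:.1f} ms "
      f"({len(feats_c)} records kept)")
both = pd.concat([feats_d, feats_c], ignore_index=True)
res = compare_groups(both, "inv_fwhm_vpg")
print(f"Welch t = {res.t:.2f}, p = {res.p_value:.2e} ({res.direction})")
```

Output:

```
diabetes  1/FWHM_VPG 5.67 1/s, delay 27.3 ms (48 records kept)
control   1/FWHM_VPG 7.94 1/s, delay 11.7 ms (21 records kept)
Welch t = 5.85, p = 2.87e-06 (control > diabetes)
```

The simulated diabetes group shows the lower upstroke steepness and the
longer capillary transit delay; two diabetes records were dropped by
the SNR < 200 rule, mirroring how real low-quality recordings are
excluded.

The same flow is available from the shell:

```
pulsefeat simulate --preset control --n 5 --seed 1 --out data/
pulsefeat process data/*.csv --out results/
pulsefeat compare results/features.csv --out results/
```

Waveforms travel as CSV (`time,green,red,nir`, red/nir optional) with a
YAML metadata sidecar per record; all outputs are plain delimited text
with the configuration echoed in `#` header lines.

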