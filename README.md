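# scintimon

A toolkit for the computational stack of a scintillator-camera beam
monitor for ultra-high dose rate (FLASH) radiotherapy. A thin
(sub-millimetre water-equivalent) scintillator sheet sits in the
treatment beam and is viewed obliquely by a fast CMOS camera; each
camera frame is reduced in real time to beam centroid, RMS widths and
integrated signal, converted to dose and compared against the treatment
plan, asserting a beam interlock on any out-of-tolerance deviation.

The package provides, as testable desk-scale code:

- **`scintimon.beam`** — beam and dose models: the double-Gaussian
  (core + tail) transverse profile
  `f(x) = A_n e^{-(x-c)^2/2σ_n^2} + A_w e^{-(x-c)^2/2σ_w^2}`,
  the full width at three-quarters maximum (FW3QM) defining the beam
  core, dose per pulse `DPP = φ · dE/dx` from charge fluence and
  stopping power, average/instantaneous/cumulative dose rates, and
  Birks quenching `dL/dx = S·(dE/dx)/(1 + k_B·dE/dx)`.
- **`scintimon.simulate`** — a synthetic frame generator with the
  monitor's optical and statistical structure: projective (homography)
  mapping of the beam plane onto the sensor with Jacobian density
  weighting, inverse-square optical-path vignetting, Poisson
  photoelectron statistics, Gaussian readout noise, ADC quantization,
  sparse background hits, beam scans and pulse trains with
  fluence-proportional scintillator degradation and a per-pulse dose
  ledger.
- **`scintimon.calibration`** — flat-field correction matrix on a ~1 mm
  mesh, normalized direct-linear-transform homography estimation,
  differential degradation monitoring with a replacement flag, and the
  ADC → photoelectron → Gy gain chain.
- **`scintimon.pipeline`** — the per-frame firmware-style analysis:
  pedestal subtraction, thresholded 8-connected beam finding,
  ADC-weighted moments refined in a 17×17 box, plan-LUT comparison,
  interlock decisions with a residual-dose bound, and a modelled
  per-stage latency ledger in 4 ns FPGA ticks.
- **`scintimon.characterize`** — stepper-scan spatial resolution (RMS of
  linear-fit residuals), pixel re-binning, band-averaged profiles,
  double-Gaussian fits, profile-vs-profile residual comparison, the
  ratio-of-ratios radiation-hardness trend and dose-response linearity.
- **`scintimon.background`** — bremsstrahlung signal/background budgets
  per frame, fast-neutron hit estimates for proton operation, and
  shield-effectiveness bookkeeping.
- **`scintimon.cli`** — a `scintimon` command with `simulate`,
  `flatfield`, `calibrate-homography`, `degradation`, `analyze`,
  `scan-resolution`, `profile-fit`, `hardness`, `linearity` and
  `project-background` subcommands. Frames travel as 16-bit TIFF with a
  JSON sidecar; tables and plans as CSV.

## Worked example

Dose bookkeeping for a pulsed 8 MeV electron beam whose 1 ns pulses
carry 3.3 nC, with 37% of the charge inside the 0.304 cm² beam core
(the FW3QM disc), delivered at 30 Hz for 15 minutes:

```python
from scintimon.scenarios import beam_core_dosimetry

for k, v in beam_core_dosimetry().items():
    print(f"{k}: {v:.4g}")
```

```
charge_fluence_nC_per_cm2: 4.016
stopping_power_MeVcm2_per_g: 2
dose_per_pulse_Gy: 8.033
avg_dose_rate_Gy_per_s: 241
instantaneous_dose_rate_Gy_per_s: 8.033e+09
cumulative_dose_kGy: 216.9
```

The charge fluence (4.0 nC/cm²) times the water mass stopping power for
8 MeV electrons (2.0 MeV·cm²/g) gives 8.0 Gy per pulse; at 30 Hz that is
a 240 Gy/s time-averaged dose rate — well inside the FLASH regime — and
216 kGy accumulated over the quarter-hour run, while the 1 ns pulse
width pushes the instantaneous rate to 8×10⁹ Gy/s.

Simulating that same run with a −0.025%/kGy scintillator degradation and
1.6% pulse-to-pulse beam noise, and analysing it with the
ratio-of-ratios trend (beam-core signal over an off-beam control region,
each normalized to time zero):

```python
from scintimon.scenarios import run_hardness_benchmark

r = run_hardness_benchmark(seed=1)
print(f"recovered slope: {100 * r.slope_per_kGy:.4f} %/kGy "
      f"(injected {100 * r.injected_per_kGy:.4f})")
```

```
recovered slope: -0.0237 %/kGy (injected -0.0250)
```

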