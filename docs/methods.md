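# Methods

This note records the models implemented in `scintimon`, the defaults
and units of the parameters that matter, what the synthetic frames do
and do not emulate, and the numerical choices made where the design was
genuinely open.

## Beam and dose models

**Transverse profile.** Each transverse axis of the beam spot is a
double Gaussian, a narrow primary core plus a wide low-amplitude tail
sharing one center:

    f(x) = A_n exp(-(x-c)^2 / 2σ_n^2) + A_w exp(-(x-c)^2 / 2σ_w^2)

with the constraint σ_w > σ_n so the components keep their roles. The
printed functional form this models is sometimes written without the
minus sign or with an ambiguous (x/2σ)² grouping; only the standard
Gaussian is normalizable and consistent with millimetre-scale σ values,
so that is what is implemented. The 2D spot is the separable product of
the two axis profiles.

**Beam core (FW3QM).** The dosimetric beam core is bounded by the
outermost crossings of 3/4 of the profile peak. Crossings are located
by scanning inward from each end of the sampled profile and linearly
interpolating between the bracketing samples; exact-threshold ties
resolve outward. For a single Gaussian the width is 2σ√(2 ln 4/3) ≈
1.5171σ, used as a closed-form oracle in the tests.

**Dose per pulse.** DPP = φ · dE/dx, with φ the charge fluence of the
pulse (nC/cm²) and dE/dx the mass stopping power (MeV·cm²/g). The
elementary charge is fixed at 1.602176634×10⁻¹⁹ C and MeV→J at
1.602176634×10⁻¹³; for singly charged particles these factors cancel
exactly, so DPP in Gy equals the product of the two numbers in the
units above. A small embedded table carries water stopping powers
(electrons 6–100 MeV, protons 170–240 MeV, rounded from the standard
NIST tabulations; 2.0 MeV·cm²/g for 8 MeV electrons) and can be
overridden from a CSV file. Average dose rate is DPP·f_rep,
instantaneous is DPP/δt_pulse, cumulative is average rate × duration.

**Birks quenching.** dL/dx = S·(dE/dx)/(1 + k_B·dE/dx). Kept as a model
component only; the scintillator's k_B is not constrained by anything
in this package.

## Synthetic frames

A scene is a beam spot (separable double Gaussian with a total
photoelectron yield), a 3×3 homography from beam-plane mm to sensor
pixels, an optional inverse-square vignette, and a sparse-background
rate. Rendering is by inverse mapping: each pixel center is pulled back
to the beam plane, the normalized 2D beam density is evaluated there,
and the Jacobian determinant of the inverse homography supplies the
area weight, so the pixel sum of expected photoelectrons equals the
injected yield for a contained spot. Pixel values are then

    ADC = clip(round(pedestal + g·(Poisson(μ) + N(0, σ_read))), 0, 2^bits − 1)

with g the gain in ADC counts per photoelectron and σ_read the readout
noise in electrons. Background hits are single-pixel impulses with
Poisson frame counts and exponentially distributed amplitudes — the
occupancy of direct x-ray conversions is what matters downstream, not
their spectrum, which is not constrained by the source material. A
frame is flagged saturated when more than 1% of beam pixels reach the
top of the ADC range. Rendering is a pure function of (scene, sensor,
seed): identical inputs give bit-identical frames.

Two sensor presets bracket the hardware classes: a ~2 MP low-noise
camera (1920×1080, 2.5 e⁻ read noise, gain 2800/1080 ≈ 2.59 ADC/PE from
the calibration point below) and a 1 MP camera read in a 212×212 ROI
(≈45k pixels, 15 e⁻). Exact pixel counts of the real cameras are not
public; these are stand-ins with the stated noise and ROI scale. Tests
mostly use a 160×120 desk-scale sensor with a 16-bit ADC so bright
compact spots do not clip.

**Pulse trains and degradation.** A pulse train scales each pulse's
yield by a common Gaussian beam-current fluctuation (default off;
the hardness benchmark uses the measured 1.6% RMS) and by local
scintillator degradation 1 − r·D(x), where r is the fractional loss
per kGy and D(x) the cumulative local dose. Local dose is
fluence-proportional: D(x) = (DPP per ledger) × rel(x), with rel the
beam intensity normalized so its fluence-weighted mean over the FW3QM
core is 1 — the ledger's DPP is the core dose, so the measured core
signal degrades at exactly r per ledger-kGy by construction. Dose is
accounted for every pulse; a `frame_stride` argument renders every
n-th pulse so the 27 000-pulse hardness schedule stays tractable
(900 frames at stride 30, ~3 s on one CPU).

What the simulator does **not** emulate: lens point-spread and
astigmatism, scintillator afterglow (decay time is far below exposure
times), energy-loss straggling and multiple scattering, ray-traced
optics, and any background amplitude spectrum beyond the exponential
stand-in. Passing tests therefore validate the analysis chain's
statistics and geometry, not camera-specific image texture.

## Calibration

**Flat field.** A calibration-screen image is reduced to mesh cells
(default 1 mm, converted to pixels via the configured scale);
cell correction = mean(reference cell)/mean(cell), with the reference
cell exactly 1. Cells only partially inside the active area are
dropped rather than extrapolated (edge cells are unconstrained);
non-positive cells raise a dead-region error naming them. Application
multiplies the pedestal-subtracted frame by the bilinear interpolation
of the cell values (the interpolation order is not specified anywhere
authoritative; bilinear matches the smooth, >1 cm variation scale the
mesh is meant to sample). The flat-field source is ideal by
construction in simulation; its own pre-calibration is out of scope.
The flattening criterion is evaluated on cell means: per-pixel shot
noise is not spatial structure the matrix can or should remove.

**Homography.** Estimated by the normalized direct linear transform:
Hartley similarity normalization of both point sets, SVD of the 2n×9
design matrix, storage with h₃₃ = 1. Noise-free correspondences are
recovered to numerical precision; rank deficiency (collinear or
repeated points) is detected from the second-smallest singular value.
An oblique-view constructor builds the camera geometry (default 40°
tilt) for simulation. Treatment plans are transformed once into sensor
coordinates at load time; images are never warped during monitoring.

**Degradation monitor.** Per-cell fractional loss 1 − current/reference
between two screen images; the replace flag fires when the
area-weighted mean loss exceeds 1% (configurable).

**Gain chain.** Gy = ADC / (ADC per PE) / (PE per Gy). The anchor
calibration points are 2800 ADC ↔ 1080 PE at the beam peak and 1080 PE
per 0.17 Gy frame.

## Real-time pipeline

Pedestal maps come from averaged beam-off dark frames. Residuals are
clamped at zero after subtraction — symmetric noise would otherwise
bias ADC-weighted moments; the cost is a small positive floor far below
the beam-finding threshold, and it is deliberate. Beam finding
thresholds at k·σ_noise (default k = 5, chosen for a sub-percent
false-positive rate per frame; no authoritative value exists) and takes
the 8-connected component with the largest integral, ties broken by the
smaller x then y of the peak pixel. Moments are ADC-weighted means and
second central moments; the final position and widths are recomputed in
an odd-sized box (default 17×17) centered on the half-up-rounded coarse
centroid, clipped and flagged at frame edges.

Plan comparison runs in sensor coordinates against the nearest plan
record (the aggregation rule when several records are nearby is not
specified; nearest-record is the simplest consistent choice). Trigger
reasons in evaluation order: no_beam, position (beam-plane distance
beyond pos_tol_mm), dose_high/dose_low (fractional deviation beyond
dose_tol, default 10% per the governing interlock standard), width
(only when the plan carries planned widths; the plan format has a width
tolerance but no mandatory width column). Each decision carries the
residual-dose bound R·dT (dose rate × response interval, 0.005 Gy at
100 Gy/s and 50 μs). After the first interlock the stream halts;
frames inside one response interval are still integrated so the
delivered residual dose can be checked against the bound.

Latency is modelled, never measured: per-stage tick counts on a 4 ns
clock are configuration constants (frame 12500, transfer 10700, beam
finding 68, position 76, widths 47; total 10891 ticks ≈ 43.6 μs). The
package makes no wall-clock claims.

## Characterization analyses

- **Scan resolution**: centroids regressed on commanded positions by
  ordinary least squares; resolution = RMS of residuals divided by the
  fitted slope (beam-plane units).
- **Re-binning**: n×n supercell sums, remainders dropped with a flag;
  totals conserved when dimensions divide.
- **Band profiles**: mean over a band of rows/columns.
- **Double-Gaussian fit**: Levenberg–Marquardt within bounds;
  initializer at the argmax with σ_n from FWHM/2.355, tail at 10% of
  peak and 10σ_n (no authoritative initialization exists). If the
  optimizer swaps component roles they are swapped back so σ_w > σ_n;
  a vanishing tail on single-Gaussian input is legitimate (nested
  model). Residual RMS is reported as % of peak.
- **Profile comparison**: both profiles peak-normalized (the measured
  comparisons are of relative amplitudes), the second resampled onto
  the first's axis by linear interpolation over the overlap; RMS of
  the difference in %.
- **Hardness**: R(t) = (A_s(t)/A_s(0)) / (A_con(t)/A_con(0)) with A_s
  the beam-core (FW3QM disc) mean and A_con a same-area off-beam
  control disc; R is exactly invariant under any common multiplicative
  drift. The loss slope is the OLS slope of R against cumulative dose.
  In the simulated benchmark the control disc sits 35 mm into the beam
  tail and receives a few percent of the core fluence, biasing the
  recovered slope low by that fraction — within the 10% recovery
  budget, and representative of a real control region that is never
  perfectly dose-free.
- **Linearity**: OLS over points below a configurable dose cap (the
  exclusion of a saturating top point is configuration, not
  hard-coded); per-point fractional deviation (y − ŷ)/ŷ.

## Background budgets

For pulsed electron delivery, n_pulses = rate × delivery time,
DPP = total dose / n_pulses, signal = (PE per Gy) × DPP, background =
0.9% of signal (the measured shielded background fraction), and the
final column divides the background (rounded to the nearest PE, per the
printed-table convention) by the 2.3 e⁻ dark noise. The benchmark
delivery is 10 Gy over 0.2 s; the signal × pulses product is constant
across pulse rates and the per-frame background falls inversely with
rate. For protons, neutrons per frame N_n = φ·A_sens·(I_p/e)·δt and the
interacting fraction Q = τ·σ·η (1 barn = 10⁻²⁴ cm²); with the default
constants Q = 0.45%, which prints as 0.4% at one decimal. Shield
bookkeeping accepts pre-tabulated background/signal percentages (the
published table's percentages are not all reproducible from its own ADC
columns under a single rounding rule) or computes them half-up to one
decimal; reduction factors are unshielded/shielded percentages, one
decimal, averaged over energies.

## Problem sizes and determinism

All simulations in the tests and benchmarks run on 160×120-pixel
sensors; the hardness benchmark renders 900 of its 27 000 pulses and
completes in seconds, chosen as the smallest sizes at which the
statistical checks have comfortable power. Every stochastic path takes
an explicit integer seed (NumPy `default_rng`); streams derive
per-frame seeds from a `SeedSequence`, and identical seeds reproduce
identical bytes.

## Known limitations

- The homography-based width conversion to mm uses the isotropic
  square-root of the Jacobian at the centroid; strongly oblique views
  make widths direction-dependent, which the plan width check ignores.
- The correction matrix assumes smooth (≫ mesh) non-uniformities;
  pixel-scale fixed-pattern noise is not modelled or corrected.
- Degradation is linear in dose with no annealing or recovery term.
- The latency ledger is an accounting device; it asserts nothing about
  any real DAQ.
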