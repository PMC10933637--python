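# Methods

This note documents the models behind `muxecog`, the defaults and why they
were chosen, the numerical decisions, and what the synthetic data can and
cannot say about real recordings.

## Pixel impedance model

A recording pixel is an electrode–electrolyte interface in series with its
selection TFT. The impedance is

```
Z(ω) = R_TFT + Z_elec(ω) ∥ 1/(jωC_par),
Z_elec(ω) = R_s + (Z_CPE ∥ R_ct),      Z_CPE = 1/(Q (jω)^α),  ω = 2πf.
```

* `R_s` (Ω) — solution/track series resistance; sets the high-frequency
  plateau together with `R_TFT`.
* `Q` (S·sᵅ), `α ∈ (0,1]` — constant-phase element describing the non-ideal
  double layer; `α = 1` is an ideal capacitor.
* `R_ct` (Ω) — charge-transfer resistance; dominates the DC limit
  (|Z| → R_s + R_TFT + R_ct as f → 0).
* `R_TFT` (Ω) — switch ON resistance, 0 for a pixel without a TFT. In the
  linear region it scales inversely with channel width, `R_ON ∝ 1/W`.
* `C_par` (F) — parasitic/solution capacitance. Its attachment point is a
  genuine modeling choice: we place it across the electrode branch
  (R_s + CPE ∥ R_ct) with `R_TFT` outside, because the parasitic is an
  electrode/solution property and measurements show the switch acting as a
  pure series-resistance increase. With `C_par = 0` the placement is moot.

**Fitting.** `fit_impedance` minimizes modulus-weighted complex residuals
`(Z_model − Z)/|Z|` with Levenberg–Marquardt; the weighting keeps decades with
small |Z| from being ignored in spectra spanning >4 orders of magnitude.
Positive parameters are optimized in log space and `α` through a logistic map,
so the unconstrained LM step can never leave the physical domain (a hard clip
at `α = 1` was found to trap the optimizer at the boundary). `R_TFT` is held
fixed at the value supplied in the initial guess: it is measured independently
from transfer curves and is exactly degenerate with `R_s` in a blind fit —
comparisons of pixels with/without a switch are done by comparing the fitted
series resistances. Default initialization reads `R_s` from the
high-frequency plateau, `R_ct` from the low-frequency plateau, and `Q`, `α`
from the mid-band slope of log|Z|. Non-convergence is flagged on the returned
fit object and warned about, never silent; near-constant spectra and spans
under two decades are rejected.

Parameter recovery depends on identifiability: all four parameters are
recovered to better than ~2% from 1%-noise spectra only when each leaves a
signature inside the measured window (1 Hz–100 kHz) — e.g. a 500 MΩ `R_ct`
whose shoulder lies far below 1 Hz is *not* identifiable from such a window,
and the tests use parameter sets whose features are in-window.

**Turn-on voltage.** `extract_v_on` uses a current criterion
`I_DS > 1 nA · (W/L)`; the threshold scales with geometry so devices of
different widths report comparable values. It is reported for device
characterization only.

**Thermal noise.** `johnson_noise_rms` evaluates √(4·k_B·T·R·B) at a default
T = 298 K. Noise bookkeeping uses RMS quadrature arithmetic
(`quadrature_add/subtract`), the standard way independent noise powers
combine; subtraction refuses `component > total` (negative power).

## Acquisition-chain model

The chain is behavioral, not transistor-level: each stage implements the one
property that matters downstream.

* **Schedule.** N electrodes (one grid row per select line) share a data line;
  slots last `1/(N·f_ch)`, every electrode is visited once per `1/f_ch` frame.
  Scan order is ascending rows by default (configurable); the count of
  super-channels for an array is `ceil(n_electrodes/N)`.
* **DC offsets.** Electrode open-circuit potentials are drawn Gaussian
  (mean 397 mV, SD 115 mV, the measured statistics of gold microelectrodes in
  saline) and attenuated by the divider `z_in/(z_in + z_dc)`. The readout DC
  input impedance is a free parameter; the default of 5 MΩ (≈100× attenuation
  against a 500 MΩ electrode) is a package choice of a plausible value, not a
  measured one. The divider is applied to the DC offset only: at signal
  frequencies the electrode impedance is orders of magnitude lower and the
  attenuation negligible.
* **Settling.** The shared line relaxes toward the active electrode's level
  with a single-pole constant τ = (R_s + R_TFT)·C_line (C_line default 50 pF —
  a synthetic knob, not a measured value; τ = 0 gives instant settling). The
  residual of the previous slot after integration,
  `(τ/T)(1 − e^(−T/τ))` for slot length T, is the crosstalk mechanism.
* **Windowed integration.** The incremental-ΔΣ converter is modeled as a
  per-slot boxcar average — its anti-aliasing property — with equivalent noise
  bandwidth `N·f_ch/2` and transfer |sinc(f/slot rate)|; quantization noise is
  folded into the configured readout noise figure. `simulate_tdm` evaluates
  settling + integration with the exact continuous-time slot solution
  (`u + (v_prev − u)(τ/T)(1 − e^(−T/τ))`), so no stream oversampling is
  needed; `compose_superchannel`/`windowed_integrate` expose the same stages
  as inspectable oversampled streams (default 16 samples per slot) for
  step-waveform visualization and filter tests.
* **Noise injection.** Readout noise is white over the noise bandwidth; its
  per-slot SD is either derived from a flat density (for folding experiments)
  or calibrated so the demultiplexed in-band (1–500 Hz) RMS equals the
  configured figure (default 1.55 µVrms — with f_ch = 1 kHz the demultiplexed
  samples are white over 0–500 Hz, of which the 1–500 Hz band holds 499/500 of
  the power). Flicker noise is off by default (single-switch pixels contribute
  no amplifying TFT 1/f noise). Electrode thermal noise uses Re Z at 1 kHz
  over the same bandwidth, flat — full frequency-dependent synthesis is out of
  scope.
* **Offset compensation.** Per slot position, the DC level is estimated from
  the first ~128 ms, quantized to the DAC step (default 1 mV), clipped to the
  compensation range (default 160 mV peak-to-peak around the super-channel
  median; out-of-range channels are flagged saturated) and subtracted. Loop
  updates occur as a Poisson process at the configured glitch rate and leave
  logged DC steps — the artifact the offline stitcher removes. The real
  loop's update law is unpublished; configurable-rate stepping reproduces its
  observable consequence (sporadic DC shifts).
* **Demultiplexing** de-interleaves slot samples to per-electrode traces at
  `f_ch`; per-channel slot-center timestamp offsets are kept in annotations
  rather than resampled away.
* **Addressing mode** records one selected row continuously at `f_ch` (no
  folding penalty) through a first-order 1–500 Hz analog band-pass;
  unselected rows couple in only via a configurable OFF-leakage fraction
  (default 0).

With white noise limited to `N·f_ch/2`, the demultiplexed in-band noise power
grows linearly with N (the folding law); the simulator reproduces slope 1
within Monte-Carlo error, and an N = 16 chain returns a common 1 mV
peak-to-peak tone at 0.354 mVrms per channel when noise is off.

## Synthetic cortical fields

The generator emulates anesthetized-rodent epidural recordings:

* **Background**: white Gaussian noise shaped to a 1/f amplitude spectrum
  (power ∝ 1/f², the typical LFP roll-off), scaled to 150 µVrms by default,
  mixed from a grid-common and per-channel component (50/50 by default) so
  nearby channels correlate.
* **Events**: Gaussian-windowed sinusoids. Delta (2 ± 0.5 Hz, ~200 µV,
  near-global), spindles (13 ± 1 Hz, ~60 µV, σ ≈ 700 µm footprint), ripples
  (134 ± 9 Hz, 80 µV, σ = 500 µm — a ≈2×1.5 mm² half-power patch at 500 µm
  pitch). Ripple durations are log-normal with median 96 ms and log-SD 0.5
  (population SD ≈58 ms), clipped to 30–350 ms; rate 0.75 events/s.
* **Duration convention**: an event's nominal duration is the span where its
  envelope exceeds ~20% of peak (envelope σ = duration/3.6). This is chosen
  to mean the same thing as what an envelope-threshold detector measures at
  typical event-to-background ratios (4–6×), so generator and detector
  durations are directly comparable.
* **Placement**: event count is Poisson(rate·duration); centers are placed by
  a hard-core process enforcing a minimum onset gap (default 250 ms for
  ripples — a physiological refractory), so the configured rate is realized
  without detector-side merge losses. A field too short for the drawn events
  raises. With coupling enabled, ripple centers snap (±80 ms) to the nearest
  trough→crest transition of the placed delta waves — a qualitative
  implementation of delta-phase coupling; no quantitative coupling strength
  is modeled because none is established.
* **SSEPs**: a first Gaussian lobe (amplitude 580 µV at 20 ms latency by
  default, 10 ms FWHM) plus an optional broader opposite-polarity lobe,
  rescaled after summation so the template's measured first peak equals the
  configured amplitude; Gaussian spatial footprint (σ = 500 µm, half-power
  across 2–3 electrodes) with an optional weaker, delayed ipsilateral mirror.
  Trial-to-trial variability defaults to 10% amplitude CV and 1 ms latency SD
  — stand-ins of plausible magnitude, configurable, as the real variability
  is not quantified.

What passing tests on this data do **not** show: robustness to volume
conduction and dipole geometry, non-stationary anesthesia states, movement or
electromagnetic artifacts, or background spectra with band-specific peaks;
the background's ripple-band power is low (σ ≈ 1.6 µV in 100–200 Hz at the
default 150 µVrms), so real detection problems are harder than the synthetic
ones unless the detector-band SNR is matched, which the precision/recall
tests do explicitly (events injected at a stated ratio of peak detection
envelope to band-limited background RMS).

## Analysis chain

All offline filters are zero-phase (forward–backward Butterworth), doubling
the effective order but preserving event timing; stated orders are per pass.
Bands ending at Nyquist (500 Hz at 1 kS/s) are realized with the upper corner
at 0.99·Nyquist.

* **In-band noise**: first-order 1 Hz high-pass, Welch PSD with 1 s Hann
  segments and no overlap (1 Hz resolution, matching the band's lower edge;
  segment length is a package choice), integrated 1–500 Hz, square root.
  Channels above 10 µVrms are masked as defective before summary statistics.
* **Ripple detection**: 100–200 Hz third-order band-pass, rectify, 10 ms
  moving-average envelope; thresholds are multiples of the SD of the
  *filtered* (pre-rectification) trace — boundary 1×SD, peak 2.5×SD; events
  closer than 30 ms merge; durations outside 20–400 ms are discarded; peak
  frequency from the event segment's periodogram. A flat trace yields no
  events (no division by zero). Note the rectified-smoothed envelope of a
  burst of peak amplitude A is ≈(2/π)A, so the effective peak criterion on
  the true envelope is ≈3.9×SD.
* **Event statistics**: rate = n/duration (2 decimals), median ± SD duration
  (ms), mean ± SD peak frequency; an empty population reports n = 0, rate 0
  and NaN-flagged statistics.
* **Band power**: 2nd-order band-pass, analytic-signal envelope, RMS over the
  window; gamma maps use the 30–500 Hz band in 10–50 ms post-stimulus.
* **SSEP averaging**: trigger-aligned epochs, arithmetic mean, baseline
  subtraction with the 50 ms pre-trigger mean (the peak-measurement reference
  is a package choice), polarity-agnostic first-peak search in 0–50 ms;
  edge-clipped trials are dropped with a warning.
* **Spectrograms**: Hamming windows of 1024 (1–55 Hz view) or 512 samples
  (50–500 Hz view), 90% overlap.
* **Crosstalk**: victim spectral amplitude at the aggressor frequency
  (integrated periodogram peak) over aggressor amplitude, in dB.
* **Glitch stitching**: first differences beyond 10× the MAD-based SD mark
  steps; each step minus the local median slope is subtracted from all later
  samples. Idempotent; warns when >1% of samples are flagged.

## Reproducibility and problem sizes

Every stochastic component is driven by named `numpy` SeedSequence streams;
identical configs and seeds give bitwise-identical traces and byte-identical
CSV outputs end to end. The bundled experiments use a 16×16 grid at 10 s for
chain-level checks, 129 s single-patch fields for ripple statistics, 50–60 s
fields across 20–50 seeds for detector scoring, and 8 s runs × 50 seeds for
the noise-folding regression — sizes chosen to put Monte-Carlo error well
inside the tolerances being tested while keeping the suite quick on one CPU.

## Known limitations

* The ΔΣ modulator, its decimation filter and quantization are not modeled
  beyond the boxcar + noise-figure abstraction.
* Electrode noise is flat (Re Z at 1 kHz); real electrodes are colored.
* The EDO compensation loop's dynamics (acquisition, tracking) are reduced to
  static cancellation plus random-step glitches.
* No volume conduction: spatial footprints are imposed, not propagated from
  sources.
* The trace container is a package-local format (float32 + JSON sidecar), not
  a community standard; conversion shims are out of scope.
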