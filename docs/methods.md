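# Methods

`perfquant` studies how the temporal resolution of ECG-triggered
first-pass perfusion imaging biases myocardial blood flow (MBF)
quantification, and how well four analysis strategies compensate for it.
Everything rests on the indicator-dilution model

    Ct(t) = (Ca ⊛ h)(t),        h(t) = F · R(t),

where `Ca` is the arterial input function (AIF), `Ct` the myocardial
tissue curve, `h` the impulse response function (IRF), `F` the flow in
mL/g/s, and `R` the residue function with `R(0) = 1`, non-increasing,
and `∫R dt = MTT = Vb/F` (central volume theorem; `Vb` is the myocardial
blood volume in mL/g).

## Synthetic data

**Reference curves.** Dense, noise-free curves are generated on a 30 Hz
grid spanning 20 minutes — effectively continuous relative to bolus
dynamics, and long enough to capture full contrast clearance.

* *AIF*: an impulse injection passed through a serial cascade of six
  first-order mixing compartments (rate 0.6 s⁻¹ each), delayed by 10 s,
  plus a geometric series of recirculation passes (fraction 0.3, delay
  25 s, one extra dispersion stage of 12 s per pass). The defaults give
  a first-pass bolus with FWHM ≈ 8.8 s and time-to-peak ≈ 8 s after the
  delay — typical of left-ventricular enhancement after an intravenous
  bolus. Stage kernels are normalized to unit discrete area so the
  cascade conserves tracer mass on the grid; the total curve area is
  `amplitude / (1 − recirculation_fraction)` to ~1e−6 relative.
* *Residue function*: two-parameter Fermi form
  `R(t) = (1+e^(−τ/w)) / (1+e^((t−τ)/w))` with the plateau-to-width
  ratio fixed at `τ/w = 4` and the width solved by a bracketed 1-D root
  find so the trapezoidal area equals the target MTT (0.1% or better).
  Reference flows 1–5 mL/g/min at `Vb = 0.3` mL/g give MTTs of
  18/9/6/4.5/3.6 s.
* *Tissue curves*: `Ca ⊛ h` evaluated with trapezoidal product
  quadrature (the endpoint correction matters because `h` jumps to its
  maximum at t = 0). The tissue-to-AIF area ratio then equals `Vb` to
  machine precision.

**Degradation.** Each acquisition samples the dense pair once per
heartbeat (`Δt = 60/HR` s) by nearest-dense-sample lookup. A single
uniform shift in ±0.5 s, drawn independently for AIF and tissue, models
arrival-time detection error; the recorded time stamps stay nominal, so
the shift is invisible downstream. Rician noise
`v → sqrt((v+g₁)² + g₂²)` is then applied with one sigma per reference
flow level, chosen so the noise-free tissue peak has SNR 20; the same
absolute sigma applies to the AIF (whose peak is ~4× higher, matching
the blood-pool/myocardium signal ratio in magnitude images). The
default study grid is 5 flows × 5 heart rates (30–150 bpm) × 1000
realizations; tests and the acceptance script use 100 realizations per
cell, which resolves cell means to a standard error of ~0.5–3% while
keeping a full sweep within a few minutes on one core.

All randomness derives from one master seed via
`SeedSequence(master_seed, spawn_key=(cell, repetition))`, so any two
analyses of the same dataset see identical noise draws (paired seeds).

## Quantification

All three quantifiers fit (or solve for) a *per-sample* IRF `g` through
the discrete convolution `tissue[j] ≈ Σᵢ aif[i]·g[j−i]`, deliberately
carrying no Δt factor: this reproduces how quantification behaves when
the sampling interval is ignored, which is the failure mode under
study. The estimated flow is `raw_amplitude / Δt_norm × 60 × density`,
where `raw_amplitude = max g` and `Δt_norm` depends on the analysis
approach:

| approach       | time vector given to the fit | Δt_norm            |
|----------------|------------------------------|--------------------|
| none           | sample index                 | 1 (assumed 1 s)    |
| input_time     | true seconds                 | 1                  |
| scaling        | sample index                 | input Δt           |
| interpolation  | interpolated seconds         | interpolated Δt    |

Because the discrete fit is invariant to relabeling the time axis,
`input_time` returns exactly the same flow as `none` — it fixes the
IRF's width but not its height — while `scaling` and `interpolation`
restore the amplitude. Uncorrected analysis therefore overestimates MBF
at low heart rates (Δt > 1 s) and underestimates it at high rates, by
roughly the factor Δt/1 s.

* **Fermi-constrained deconvolution** fits
  `g(t) = A / (1 + e^((t−τ)/w))` by bounded trust-region least squares
  (amplitude, plateau half-width, transition width; analytic-free
  Jacobian; up to three perturbed restarts on non-convergence).
* **Regularized SVD deconvolution** builds the lower-triangular Toeplitz
  matrix from the AIF samples and filters singular values with Tikhonov
  factors `s²/(s²+λ²)`, `λ = 0.15·s_max` by default. That weight is the
  smallest value in the conventional 0.1–0.2 range at which the TSVD
  and Fermi estimates agree within 15% on clean dense data across the
  full flow range; the residual low-side bias (−2 to −10%, growing with
  flow) is the price of the spectral filter and is reported, not hidden.
* **One-compartment model** fits `h(t) = F·e^(−F·t/V)` with flow `F` and
  distribution volume `V` free.

**Preprocessing.** Contrast arrival is detected on the AIF: baseline
mean + 5 SD locates the upslope, then the index walks back to the foot
(last sample within 1 SD of baseline); on noise-free data the threshold
falls back to 5% of peak. Each curve's pre-arrival samples estimate its
Rician noise scale (`σ̂² = mean(M²)/2`, Rayleigh second moment); the
noise floor is removed by `M → sqrt(max(M²−2σ̂², 0))` and the residual
pre-arrival mean is subtracted. Without the floor correction, baseline
subtraction removes the Rayleigh mean (~1.25σ) from in-bolus samples
that never carried it, deflating MBF by 10–20% at tissue SNR 20.
Skipping the residual-mean subtraction instead leaves a positive floor
on near-zero samples that feeds a right-skewed amplitude instability at
coarse sampling; the combination used here was the most accurate of the
variants evaluated (see Limitations).

The analysis window keeps `window_s` (default 20 s, optionally 100 s)
after arrival *plus* a 4 s pre-arrival lead-in: lead-in samples are ≈ 0
after baseline correction but give the discrete convolution its full
AIF history, making the fit insensitive to arrival-detection
granularity. Model-based fits evaluate the convolution with a
trapezoidal endpoint correction (still per-sample units); with the
plain one-sided sum, a first-order O(Δt) quadrature error of −4 to
−10% would persist even after interpolation to 240–600 bpm. Windowing
uses true seconds for every approach so all four see identical samples.

A fit-for arrival-delay parameter is available
(`QuantConfig.delay_bound_s`) but disabled by default: with noisy
curves a free delay lets the model slide along interpolation-correlated
noise, inflating both the spread and the mean of the amplitude
estimates severalfold. The injected jitter is zero-mean, so leaving it
unmodeled costs variance, not bias.

**Interpolation correction** resamples both baseline-corrected curves to
a fixed rate before windowing, with linear, piecewise-cubic Hermite
(pchip), cubic-spline (not-a-knot), or smoothing-spline algorithms. The
smoothing spline minimizes `p·Σr² + (1−p)·∫f″²` with `p = 0.9` by
default (`p → 1` recovers interpolation; implemented via scipy's
`make_smoothing_spline` with `λ = (1−p)/p`). The target grid never
extrapolates beyond the source range. When the source rate is an
integer multiple of the target rate, the pass-through algorithms return
the source samples exactly.

## Monte Carlo experiment

Every realization is quantified under every requested configuration;
cells aggregate the mean/SD of estimated MBF and of the signed
percentage error `PE = 100·(est − ref)/ref`. Failed fits are excluded
from the means, counted, and any cell with a failure rate above 20% is
flagged invalid. The interpolated-HR sweep re-runs the full analysis at
each rate in a grid (default 60–900 bpm) on the *same* dataset and
reports, per rate, the maximum over the 25 cells of |cell-mean PE|,
plus the smallest rate at which that maximum drops below given
thresholds (10% and 5% by default). Cubic-spline summary curves over
the HR axis are provided for presentation only and never feed any
statistic.

## What the simulation does and does not emulate

The generator reproduces heart-rate-governed sampling, arrival-time
detection error, and magnitude-image noise on concentration-like
curves. It does not simulate MR signal formation (saturation-recovery
readout, T1-to-concentration conversion), dual-bolus protocols, motion,
coil-sensitivity structure, or pixelwise spatial variation. Passing
tests therefore demonstrate correctness of the sampling/quantification
chain under an idealized concentration-domain model, not end-to-end
fidelity to scanner data.

## Numerical choices and degenerate inputs

Optimizer tolerances are 1e−12 (xtol/ftol/gtol) with at most 400
residual evaluations and parameter scaling from the initial guess. An
all-zero tissue curve yields zero flow without error; an all-zero AIF
raises for the deconvolution methods (singular system). Curves must
start before contrast arrival; arrival detection raises on flat curves.
Windows that out-span the data keep the whole remainder and log a
warning. `median_dt` supplies the Δt for the scaling approach on
non-uniform (variable heart rate) time vectors, which discounts ECG
mistrigger outliers.

## Known limitations

* At tissue peak SNR 20, the three-parameter Fermi amplitude is weakly
  identified at coarse sampling, leaving a noise-induced low-side bias
  of up to ~8–9% in the worst (high flow × high HR) cells that is flat
  in the interpolated rate — interpolation cannot remove what noise has
  destroyed. At SNR 40 the same pipeline's worst cells sit near −4%.
  The package reports this bias rather than constraining it away.
* Because the model-based fits use second-order quadrature, the
  benefit of interpolating beyond ~120 bpm is small here; pipelines
  with first-order discrete convolution show a much stronger dependence
  on the interpolated rate.
* The TSVD flow estimate carries a deliberate regularization bias that
  grows with flow; comparing absolute accuracy *between* methods is out
  of scope.
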