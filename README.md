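# perfquant

Monte Carlo assessment of how temporal resolution — the one-sample-per-
heartbeat acquisition of ECG-triggered first-pass perfusion imaging —
biases myocardial blood flow (MBF) quantification, and how well common
correction strategies compensate for it.

The package is aimed at researchers developing or validating cardiac
perfusion quantification pipelines. It provides:

* a **simulator** that builds dense ground-truth arterial input (AIF)
  and myocardial tissue curves from the indicator-dilution model
  `Ct = Ca ⊛ h`, `h(t) = F·R(t)`, `∫R dt = MTT = Vb/F`, then degrades
  them with heart-rate sampling (Δt = 60/HR s), ±0.5 s arrival-time
  jitter, and Rician noise;
* three **quantifiers**: Fermi-function-constrained deconvolution,
  regularized-SVD (Tikhonov-filtered) deconvolution, and one-compartment
  tracer-kinetic modeling;
* four **analysis approaches** for the sampling interval: ignore it
  (`none`, equivalent to assuming Δt = 1 s), use the true time vector
  without amplitude normalization (`input_time`), scale the flow by
  1/Δt (`scaling`), or interpolate the curves to a fixed rate before
  quantification (`interpolation`; linear / pchip / cubic-spline /
  smoothing-spline);
* an **experiment layer** that runs the full 5 × 5 grid of reference
  flows (1–5 mL/g/min at Vb = 0.3 mL/g) × input heart rates
  (30–150 bpm), summarizes the signed percentage error
  `PE = 100·(est − ref)/ref` per cell, and sweeps the interpolated
  heart rate up to 900 bpm.

See `docs/methods.md` for the model, parameter defaults, and numerical
choices.

## Worked example

```python
import numpy as np
from perfquant import (AcquisitionParams, QuantConfig, make_reference_pair,
                       resample_at_hr, add_rician_noise, quantify)

# ground truth: MBF 3 mL/g/min, Vb 0.3 mL/g  ->  MTT 6 s
pair = make_reference_pair(mbf=3.0, vb=0.3)

# acquire it at 120 bpm (one sample every 0.5 s) with arrival jitter + noise
rng = np.random.default_rng(0)
acq = AcquisitionParams(input_hr=120.0, jitter_limit=0.5,
                        noise_sigma=pair.tissue.values.max() / 20)
aif = add_rician_noise(resample_at_hr(pair.aif, acq, rng), acq.noise_sigma, rng)
tis = add_rician_noise(resample_at_hr(pair.tissue, acq, rng), acq.noise_sigma, rng)

for corr in ("none", "scaling", "interpolation"):
    res = quantify(aif, tis, QuantConfig(method="fermi", correction=corr))
    print(f"{corr:14s} MBF = {res.mbf:5.2f} mL/g/min")
```

prints

```
none           MBF =  1.34 mL/g/min
scaling        MBF =  2.68 mL/g/min
interpolation  MBF =  2.68 mL/g/min
```

Ignoring the 0.5 s sampling interval halves the estimate (the fitted
per-sample IRF amplitude is read as if Δt were 1 s); scaling by 1/Δt or
interpolating to a fixed 240 bpm grid restores it to ~2.7 mL/g/min —
this particular noise and jitter draw still costs ~10% against the true
3 mL/g/min, which is within one standard deviation of the Monte Carlo
spread for this cell.

The same pipeline is scriptable from the shell:

```bash
perfquant simulate   --config run.yaml --out sim/        # write curves + truth
perfquant quantify   --curves sim/realization_000000.csv --out result.json
perfquant experiment --config run.yaml --out exp/        # full MC summary table
perfquant sweep      --config run.yaml --out sweep/      # interpolated-HR sweep
```

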