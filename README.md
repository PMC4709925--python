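# adcdesign

Optimal b-value selection for monoexponential model fitting, with apparent
diffusion coefficient (ADC) imaging as the motivating application — plus
the Monte Carlo machinery to evaluate any candidate acquisition design
under realistic MRI magnitude (Rician) noise.

## The problem

Diffusion-weighted MRI measures a signal that decays monoexponentially
with the diffusion weighting b (s/mm²):

    m(b) = m0 · exp(−b·D)

where `m0` is the unweighted signal intensity and `D` is the apparent
diffusion coefficient (mm²/s). Fitting is done on the log scale, where the
model is linear in `x = [ln m0, D]` with design matrix rows `[1, −b_i]`.
The precision of the least-squares estimate is governed by the information
matrix

    M = AᵀA = [[N, −Σb_i], [−Σb_i, Σb_i²]],   Cov(x̂) = σ²·M⁻¹,

so choosing the b-values *is* choosing the estimator's covariance.
The D-optimal criterion maximises

    det M = N·Σb_i² − (Σb_i)²,

which depends only on the b-values — not on the tissue parameters. Its
closed-form solution is a two-point design: place n measurements at
`b_min` and N−n at `b_max`, with n = N/2 for even N and (N+1)/2 for odd N.
This contrasts with Gaussian-CRLB designs from earlier work, which must be
re-derived whenever the expected D changes.

The package provides:

- `model` — the signal model, design matrix, information matrix and the
  exact least-squares covariance;
- `designs` — D-optimal, equidistant (ED), transcribed Gaussian-CRLB
  reference designs, a generic numeric CRLB minimiser, and an exhaustive
  grid-search oracle that certifies the closed-form rule on small instances;
- `noise` — Rician magnitude sampling and diagnostics for how well the
  zero-mean / equal-variance assumptions hold on log-measurements
  (they hold for SNR ≳ 10);
- `estimation` — log-linear least squares for (m0, D);
- `montecarlo` — the design-evaluation engine, sensitivity sweeps over
  D, N, b_max and SNR, and head-to-head comparisons under common random
  numbers;
- `phantom` — synthetic intensity maps and a pixelwise version of the
  evaluation experiment (bias/std maps of m̂0);
- a CLI (`adcdesign`) exposing all of the above.

## Worked example

Generate the three-point D-optimal design on b ∈ [0, 2000] s/mm²:

```bash
$ adcdesign design --method dopt --n 3 --bmin 0 --bmax 2000
0,0,2000
```

Two acquisitions at b=0 and one at b_max — not three spread-out points.

Compare the ten-point D-optimal design against the Gaussian-CRLB reference
design at a high diffusivity (D = 3×10⁻³ mm²/s, m0 = 500, SNR = 10,
20000 Monte Carlo trials):

```bash
$ adcdesign compare --methods dopt,gcrlb --d 0.003 --n 10 --nmc 20000 --seed 1
method,bias_D,std_D,bias_m0,std_m0,mc_se_D,mc_se_m0,n_mc,n_failed
dopt,-0.00188,0.000145,0.260,22.3,1.03e-06,0.158,20000,0
gcrlb,-0.00207,0.000260,-280.7,48.2,1.84e-06,0.341,20000,0
```

(Values abbreviated; the command prints full precision.) Read: the
D-optimal design estimates m0 essentially without bias (+0.26 on a true
value of 500) while the CRLB reference design underestimates it by ~280
intensity units with nearly twice the spread; both designs underestimate D
itself at this diffusivity, because the decayed signal at b = 2000 sits far
below the Rician noise floor — high ADC values are intrinsically hard to
estimate accurately at clinical SNR.

The same engine is available as a library:

```python
from adcdesign import (MonoexpParams, NoiseSpec, d_optimal_design, evaluate_design)

res = evaluate_design(
    d_optimal_design(10, 0.0, 2000.0),
    MonoexpParams(m0=500.0, D=1.2e-3),
    NoiseSpec(sigma_G=50.0),      # SNR = m0/sigma_G = 10
    n_mc=20000, seed=1,
)
print(100 * abs(res.bias_D) / 1.2e-3)   # -> 14.2 (% relative error of D̂)
```

Even the optimal design misses D = 1.2×10⁻³ mm²/s by ~14% on average —
the practical accuracy limit for high diffusivities.

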