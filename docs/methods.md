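# Methods

## Model and estimator

The signal model is the monoexponential decay m(b) = m0·exp(−b·D) with
m0 > 0 (intensity units) and D > 0 (mm²/s); b-values are in s/mm² and no
unit conversion happens anywhere in the package. Estimation is log-linear
least squares: y_i = ln m_i, x = [ln m0, D], A has rows [1, −b_i], and
x̂ solves the normal equations (computed via an SVD-based least-squares
factorisation, which agrees with the normal-equations solution to machine
precision for these 2-column problems). The −b sign convention means D̂ is
read directly from x̂[1].

Under i.i.d. zero-mean noise of variance σ² on y, x̂ is unbiased with
Cov(x̂) = σ²(AᵀA)⁻¹. Note the unbiasedness is in x: on the natural scale
m̂0 = exp(x̂[0]) is lognormal with the exact offset
E[m̂0] − m0 = m0·(exp(Cov₀₀/2) − 1). Tests assert that closed form rather
than pretending m̂0 itself is unbiased.

## Designs

- **D-optimal** (closed form): n points at b_min, N−n at b_max, n = N/2
  (even N) or (N+1)/2 (odd N). det M = n(N−n)(b_max−b_min)², independent
  of (m0, D). For odd N the mirrored design (majority at b_max) has equal
  det; the canonical output puts the majority at b_min because low-b
  acquisitions have higher SNR under magnitude noise. The mirrored variant
  is available via `majority_high=True`.
- **Equidistant (ED)**: N uniformly spaced points, endpoints included.
  Coincides with the D-optimal design at N = 2.
- **GCRLB reference**: transcribed constants from prior Gaussian-CRLB
  work — (0, 820) for N = 2 and (0, 0, 700×6, b_max, b_max) for N = 10,
  valid for D ∈ [0.1, 3]×10⁻³ mm²/s. They are labelled reference values
  because this package does not re-derive them; whether the interior 700
  depends on b_max is not documented in the source material, so it is held
  fixed for every b_max.
- **Numeric CRLB minimiser**: minimises the Gaussian-noise CRLB of D̂ for
  the *nonlinear* model (Fisher information from the signal Jacobian
  [e^{−bD}, −m0·b·e^{−bD}], i.i.d. Gaussian magnitude noise). It exists to
  exhibit the contrast with the D-optimal rule: its solution depends on
  the assumed D (the optimal two-point spacing scales as 1/D). The search
  is multi-start L-BFGS-B on log(CRLB) over box-normalised coordinates;
  the raw objective spans many orders of magnitude over b-values of order
  10³, which starves finite-difference gradients.
- **Grid-search oracle**: exhaustive enumeration of all b-value multisets
  on a uniform grid (guarded to ≤ 10⁷ multisets), ties broken by the
  lexicographically smallest multiset so results are deterministic. It
  certifies the closed-form rule on small instances and is independent of
  it.

## Noise model

Magnitude MRI noise is Rician: the measurement is |m + w_R + j·w_I| with
w_R, w_I ~ N(0, σ_G²) per channel, and SNR ≡ m0/σ_G throughout. The
log-linear estimator's assumptions (zero-mean, equal-variance noise on
ln m) hold only approximately under Rician noise; the `noise` module
measures the defects by Monte Carlo — the mean offset E[ln|m+w|] − ln m
and the gap between Var[ln|m+w|] and the delta-method reference σ_G²/m².
Both shrink as SNR grows and are negligible beyond SNR ≈ 10, which is why
estimation degrades at high b·D where the decayed signal falls below the
noise floor.

The `gaussian-log` family (additive i.i.d. Gaussian noise directly on
ln m) is included although real scanners do not produce it: it is the one
channel where σ²·M⁻¹ is exact, so it serves as the closed-form oracle for
validating the Monte Carlo engine end to end.

## Monte Carlo engine

One evaluation simulates n_mc data sets (default 20000), fits each by
log-linear least squares in a single vectorised batch, and reports bias
(E[D̂]−D, E[m̂0]−m0), empirical standard deviations, and Monte Carlo
standard errors (std/√n_mc) so estimator spread and simulation
uncertainty are never conflated. Seeding: one root seed per experiment;
substreams derive deterministically from (seed, key) via SeedSequence
spawn keys, so results are independent of execution order. Comparisons
between design methods reuse the identical noise substream (common random
numbers), sharpening contrasts at fixed n_mc; in sweeps, each swept value
gets its own substream shared by all methods, so at N = 2 — where the
D-optimal and ED designs coincide — their rows are bit-identical.

Trials that produced a nonpositive measurement would be excluded and
counted (`n_failed`), but under both noise families measurements are
positive with probability one, so any such failure raises immediately:
it indicates a pipeline bug, not bad luck.

Sweep defaults mirror the simulation conditions used throughout the
evaluation: m0 = 500, D = 1×10⁻³ mm²/s, N = 10, b ∈ [0, 2000] s/mm²,
SNR = 10, Rician noise, n_mc = 20000. Where the source material gives
both 2000 and 1500 s/mm² for b_max in the same experiment, the package
defaults to 2000 and leaves b_max a parameter.

## Log-noise diagnostics: numerical choices

The SNR ladder diagnostic (σ_G = 20, m = 5σ_G…20σ_G) uses common random
numbers across SNR levels: all levels share one set of (w_R, w_I) draws.
The population mean offsets above SNR 5 are at the 10⁻⁷ level (the
second-order Taylor terms of ln|m+w| cancel in expectation for complex
noise), so with independent draws any finite-sample estimate is pure
Monte Carlo noise and the monotone improvement with SNR is invisible.
With shared draws the leading error term scales as 1/SNR and the
monotonicity shows through. The monotonicity test runs this diagnostic at
2×10⁶ trials, the resolution needed to separate variance-gap differences
at the 10⁻⁵ level; the CLI default remains 20000, which is ample for the
qualitative SNR-5-versus-20 contrast.

## Phantom experiment

The pixelwise experiment runs the evaluation engine with m0 = I(i,j) at
every positive-intensity pixel of a synthetic 8-bit-like map
(piecewise-constant tiles, a smooth gradient, or concentric rings, each on
a zero background). The noise floor is fixed (default σ_G = 5), so SNR
varies across the image with local intensity. Zero-intensity background is
masked, not fitted (ln 0 is undefined). Pixels with equal intensity are
statistically identical, so the engine runs once per distinct intensity on
a substream keyed by the intensity value — results depend only on
(intensity, seed), never on pixel position, and a full 64×64 map at
n_mc = 20000 stays desk-scale. Outputs are CSV matrices of the m̂0 bias
and standard deviation (NaN off-mask); PNG renderings are an optional
extra and carry no bit-exactness contract.

The synthetic phantom emulates the *range* of intensities of a real
mean-diffusivity image, not its anatomy, spatial correlation, partial
voluming, or coil-profile shading. Passing tests therefore demonstrate the
estimator and design behaviour as a function of local SNR, not performance
on any particular anatomical image.

## What the simulations do and do not show

The generator emulates single-coil magnitude data with spatially
independent, homogeneous Rician noise and a purely monoexponential decay.
Real acquisitions add perfusion contamination at low b, non-Gaussian
diffusion at high b, multi-coil noncentral-χ noise, and motion/eddy
artefacts — none of which are modelled; the b-range bounds are the only
lever offered against them. Conclusions about design orderings (D-optimal
vs ED vs CRLB reference) are therefore statements about this idealised
channel, though the orderings' driver — det M geometry plus the Rician
floor at high b·D — is expected to carry over qualitatively.

## Known limitations

- The D-optimal rule optimises det M for the *log-linear* estimator; it
  is not re-derived for MLE, WLS or median estimators.
- Designs for hardware-coupled constraints (TE/b coupling, gradient duty
  cycle) are out of scope.
- The numeric CRLB minimiser is a local method with multi-start; for
  N ≥ 3 its landscape has permutation-equivalent optima and the returned
  design is canonicalised only by sorting.
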