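# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `hardiopt`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Conventions

**q-space.** The wavevector magnitude satisfies `b = q^2 t`, so free
Gaussian diffusion attenuates as `E = exp(-q^2 t D) = exp(-b D)` and the
signal/propagator pair is `E(q) = Int p(r) exp(i q . r) d^3r`,
`p(r) = (2 pi)^-3 Int E(q) exp(-i q . r) d^3q`. This convention is fixed by
requiring the isotropic mono-exponential signal to invert to the Gaussian
propagator `(4 pi t D)^{-3/2} exp(-r^2 / 4 t D)`; all DOT formulas follow
from it. Internally lengths are mm, times are seconds (accepted as ms in
APIs because protocol tables print ms), diffusivities mm²/s, q in 1/mm.

**Spherical harmonics.** Real, symmetric, orthonormal basis over even
degrees `l <= lmax <= 8`: `m < 0 -> sqrt(2) Im Y_l^|m|`, `m = 0 -> Y_l^0`,
`m > 0 -> sqrt(2) Re Y_l^m`, Condon–Shortley phase as in scipy. Columns are
ordered `(l asc, m asc)`; a band limit `lmax` carries
`R = (lmax+1)(lmax+2)/2` coefficients. Orthonormality is verified against a
Gauss–Legendre(θ) × uniform(φ) product quadrature, which is exact for
band-limited integrands. Fits are plain least squares — no
Laplace–Beltrami or other regularization anywhere, so coefficients are
directly comparable across the four reconstructions.

**Effective diffusion time.** `t = Delta - delta/3`. The five preset
protocols (b = 1000…4000 s/mm²) carry their pulse timings; arbitrary
b-values require explicit timings.

## Signal model

A fiber population is an impermeable cylinder (length `L = 5 mm`, radius
`rho = 5 µm`, internal free diffusivity `D0 = 2.02e-3 mm²/s`) with uniform
spin density. Under the narrow-pulse approximation the attenuation
separates: `E(q) = E_par(q cos θ) E_perp(q sin θ)`.

* `E_perp`: Neumann eigenmode expansion on the reflecting disc. Modes are
  `J_n(beta_nk r / rho) e^{i n phi}` with `beta_nk` the roots of `J_n'`;
  the squared Fourier overlap of each mode has a closed form
  (Lommel integral), and the k-sum / n-sum are truncated by explicit tail
  bounds (target 1e-6, error raised on non-convergence). At the preset
  protocols the dimensionless time `D0 t / rho^2 ≈ 1.9–2.7`, so only a
  handful of modes contribute.
* `E_par`: the analogous reflecting-interval series exists
  (`parallel="series"`), but since `sqrt(2 D0 t) ≈ 11 µm << L` the free
  Gaussian `exp(-q_par^2 t D0)` is the default. The two differ by a real
  wall correction of ~6e-4 in absolute attenuation at b = 2000 (the image
  contribution is only suppressed by `exp(-q^2 sigma^2/2)`, not
  exponentially in L); the equivalence test asserts this measured 1e-3
  bound, and the correction is far below every downstream tolerance.

**Monte Carlo oracle.** An independent random-walk simulator (uniform
start, Gaussian per-axis steps `sqrt(2 D0 t/n)`, specular reflection at the
disc wall and end caps, signal = mean `cos(q . displacement)`) validates
the series everywhere it is used: agreement within `max(3 SE, 0.02)` over
the full (b, θ) preset grid. Steps longer than `rho/5` are rejected as
invalid boundary handling.

**Mixtures and noise.** Crossing phantoms are weight-1 sums of cylinder
signals; the default two-fiber phantom places the axes at ±angle/2 about z
in the x–z plane (an optional rotation probes orientation sensitivity,
which moves measured errors by a few degrees, consistent with mesh and
model bias). Noise adds independent `N(0, sigma^2)` to the real and
imaginary channel of every volume — including the interleaved zero-weighted
volumes (`NG/12 + 1` of them) — and takes magnitudes, giving Rician data
with `sigma = S0 / SNR`. Attenuations are re-normalized by the mean of the
noisy b0 volumes, as a real pipeline would.

**Gradient schemes.** Antipodally symmetric electrostatic repulsion
(`sum 1/|gi-gj| + 1/|gi+gj|`) minimized by L-BFGS with an analytic
gradient from a seeded random start; deterministic per seed. The design
matrix of a 72-direction scheme at lmax = 8 has condition number < 100.

## Reconstructions

* **Q-ball**: `psi_lm = 2 pi P_l(0) s_lm` (Funk–Hecke eigenvalues of the
  Funk–Radon transform applied to the SH fit of E). Cross-checked against
  720-point great-circle quadrature of the SH-interpolated signal (relative
  gap < 1e-3).
* **ADC**: `D(g) = -ln E(g) / b`, with E clamped to
  `[exp(-b * 5e-3), 1 - 1e-6]` before the log (Rician noise produces
  E >= 1 at low attenuation); clamped counts are reported. `1/D` is fitted
  directly per direction — not via inversion of the fitted D — because the
  analytical DOT-ODF consumes SH coefficients of the reciprocal.
* **DOT shell**: `I_l(u', R0) = (1/2 pi^2) Int q^2 exp(-q^2 t D(u')) j_l(q R0) dq`
  by 400-node Gauss–Legendre on `[0, 8/sqrt(t D_min)]`; sphere projection by
  vertex-area weights on an order-4 icosahedral mesh (2562 vertices).
  Isotropic shells reproduce the Gaussian propagator to < 1e-6 relative.
* **Numerical DOT-ODF / mODF**: trapezoidal sum of shells over
  `R0 in [0, R0max]`, default `R0max = 4 sqrt(6 t D_max)` (four times the
  rms displacement; a warning fires below twice), 64 steps (doubling
  changes results by < 0.1%). The mODF sphere-integral equals 1 within 1%.
* **Analytical DOT-ODF**: `psi_lm = (-1)^{l/2} (I_l / t) c_lm` with
  `I_l = |P_l(0)|/(8 pi)`; the table of coefficients is verified both in
  closed form and through `(1/4 pi^2) Int_0^inf j_l(x) dx` (oscillatory
  tail averaged over half-periods; agreement 1e-6). Analytical and
  numerical DOT-ODF agree to < 1% sup-norm on noiseless crossings across
  b = 1000–3000.

No min–max normalization is applied inside reconstruction; it is a
peak-extraction concern.

## Peak extraction and statistics

Maxima are vertices that dominate their one-ring on the evaluation mesh,
thresholded at 0.5 of the min–max-normalized amplitude (the profile's
minimum over the sphere maps to 0, its maximum to 1), and merged over
antipodes within 2.5× the mesh resolution. The default evaluation mesh is
order 7 (163,842 vertices; measured maximum nearest-vertex distance 0.34°,
bounded by 0.5°); routine tests use orders 4–5 with correspondingly looser
error floors (order-k resolution ≈ 37.4°/2^k).

Matching to the two true axes is greedy nearest-assignment under
`arccos |<u, v>|`, ties to the higher-amplitude peak; success requires
distinct peaks for both axes; spurious extra peaks are counted but not
fatal. Over realizations: `mu` and `s` are computed over successes only
(`p` reports the success fraction separately, so failures are not silently
mixed into the error scale); zero successes yield NaN markers; exact
repetitions yield `s = 0` exactly.

The 0.5 threshold is the one genuinely free parameter in the peak stage: no
spurious-peak criterion is canonical, and 0.5 suppresses noise-induced
maxima at high b / low NG while keeping genuine 60° lobes. It is exposed
everywhere and its sensitivity is part of the test surface (success is
monotone non-increasing in the threshold).

## Sweeps and study conditions

Sweeps are full factorials with per-cell counter-based seeds
(`SeedSequence(master, spawn_key=(cell,))`), 100 noise realizations per
cell by default, and cells infeasible for the band limit (NG < R) skipped
with a log entry. The selection rule keeps cells within 5° of the best mean
error and returns the smallest b, then the smallest l. The difference-method
SNR estimator `mean(B0 + B0') / (sqrt(2) std(B0 - B0'))` recovers nominal
SNR 20 within 5% on synthetic volume pairs and is applied as the median
over temporally adjacent b0 pairs.

Measured behavior under the default study conditions (60° crossing,
b = 2000, NG = 72, l = 6, order-7 mesh): noiseless error ~6°, mean error
~7° at SNR 20 (95% detection), ~8–9° at SNR 10, with failure blow-up
(> 10°) below SNR ≈ 8. The crossing of the 10° line sits at a somewhat
lower SNR than the qualitative expectation for this experiment family;
the location of that crossing is sensitive to the (unpublished) direction
tables, the absolute fiber orientation, and the spurious-peak criterion,
none of which are canonical — the conditions above were fixed a priori and
not adjusted.

## What the simulator does and does not emulate

It emulates: restricted diffusion in two crossing impermeable cylinders,
single-shell sampling with realistic pulse timings, interleaved b0 volumes,
and Rician magnitude noise at b0-referenced SNR. It does not emulate:
finite gradient pulses (narrow-pulse formulas are used with `t = Delta -
delta/3` even though `delta ≈ Delta`), exchange or multi-compartment
(hindered + restricted) tissue, T2/TE effects, partial-volume mixtures of
more than two populations, eddy currents or motion. Passing tests therefore
demonstrate correctness of the transforms and the protocol trade-off logic
under this idealized forward model, not in vivo fidelity.

## Other limitations

* bvecs are taken in the image frame; no affine reorientation is applied on
  load.
* Only even SH orders up to 8 and NG >= R are supported; the interleave
  rule requires NG divisible by 12.
* The DOT assumes mono-exponential decay per direction; multi-shell,
  multi-exponential extensions are out of scope.
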