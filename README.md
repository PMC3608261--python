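# hardiopt

Tools for studying **short-time HARDI acquisition protocols**: how many
diffusion gradient directions, what b-value, and which spherical-harmonic
order does a clinically feasible (< 10 min) diffusion-weighted MRI scan need
before crossing white-matter fiber bundles can be resolved reliably?

The package provides, end to end:

* **Analytical Q-ball imaging** — the Funk–Radon transform of the single-shell
  signal, diagonal in a real symmetric spherical-harmonic (SH) basis:
  `psi_lm = 2 pi P_l(0) s_lm`, where `s_lm` is the unregularized
  least-squares SH fit of the normalized attenuation `E(g)`.
* **The diffusion orientation transform (DOT)** — under the mono-exponential
  model `E(q u) = exp(-q^2 t D(u))` the displacement propagator on a shell of
  radius `R0` follows from the Rayleigh plane-wave expansion; numerically
  integrating `p(R0 u)` over `R0` gives the DOT-ODF (and the `R0^2`-weighted
  marginal DOT-mODF).
* **An analytical DOT-ODF** — carrying the radial integral through in closed
  form collapses the transform to

      psi_lm = (-1)^(l/2) * (I_l / t) * c_lm,
      I_l = |P_l(0)| / (8 pi)  =  1/8pi, 1/16pi, 3/64pi, 5/128pi, 35/1024pi
                                  for l = 0, 2, 4, 6, 8,

  where `c_lm` are the SH coefficients of the reciprocal diffusivity
  `1/D(u)`. The isotropic limit is `psi = 1 / (8 pi t D)`, the exact radial
  integral of a Gaussian propagator.
* **A restricted-diffusion crossing-fiber simulator** — Söderman-style
  narrow-pulse attenuation for impermeable cylinders (length 5 mm, radius
  5 µm, free diffusivity 2.02e-3 mm²/s), electrostatic-repulsion gradient
  schemes with interleaved zero-weighted volumes, and complex-Gaussian
  (Rician-magnitude) noise at a prescribed SNR — plus a random-walk Monte
  Carlo oracle that cross-validates the eigenmode series.
* **Peak extraction and protocol sweeps** — ODF maxima on an order-7
  icosahedral mesh (163,842 vertices, every direction within 0.5° of a
  vertex), angular-error statistics `(mu, s, p)` over noise realizations,
  full-factorial sweeps over angle × b × NG × l × SNR, and the smallest-b
  optimal-protocol selection rule.
* **Voxel-wise reconstruction** of real or simulated 4-D NIfTI volumes with
  FSL-style `bval`/`bvec` tables.

## Worked example

```python
import numpy as np
from hardiopt import (
    generate_gradient_scheme, protocol_for_b, two_fiber_phantom,
    crossing_signal, qball_odf, find_maxima, angular_error,
    tessellate_icosahedron, run_trial,
)

scheme = generate_gradient_scheme(72, seed=42)          # static repulsion
protocol = protocol_for_b(2000)                         # Delta/delta presets
print(f"b = {protocol.b:g} s/mm^2, t = {protocol.t_ms:.1f} ms, q = {protocol.q:.1f} /mm")

phantom = two_fiber_phantom(60.0)                       # two cylinders at 60 deg
axes = np.array([f.axis for f in phantom])
mesh = tessellate_icosahedron(7)                        # 163,842 vertices

odf = qball_odf(crossing_signal(phantom, scheme, protocol), scheme, lmax=6)
peaks = find_maxima(odf.sample(mesh), mesh, rel_threshold=0.5)
match = angular_error(axes, peaks)
print(f"noiseless Q-ball: {len(peaks)} peaks, angular error {match.error_deg:.2f} deg")

for snr in (20.0, 10.0):
    trial = run_trial("qball", 60.0, 2000.0, scheme, 6, snr, 100,
                      np.random.SeedSequence(1, spawn_key=(int(snr),)))
    print(f"SNR {snr:g}: mu = {trial.mean_error_deg:.2f} deg, "
          f"s = {trial.std_error_deg:.2f} deg, p = {trial.success_fraction:.2f}")
```

Output:

```
b = 2000 s/mm^2, t = 28.5 ms, q = 265.0 /mm
noiseless Q-ball: 2 peaks, angular error 6.36 deg
SNR 20: mu = 7.05 deg, s = 3.34 deg, p = 0.95
SNR 10: mu = 8.37 deg, s = 4.69 deg, p = 0.83
```

Reading: with 72 directions at b = 2000 s/mm² and SH order 6, a noiseless
60° crossing is recovered with ~6° error (model bias of the analytical
decomposition at this b); at SNR 20 the mean error over 100 Rician noise
realizations is ~7° with both fibers detected in 95% of trials, and the
error and failure rate grow as SNR drops.

A command-line layer wraps the sweep, selection, SNR-estimation and dataset
simulation steps:

```sh
hardiopt sweep run --config sweep.yaml --out results.csv
hardiopt sweep select --records results.csv --tolerance 5
hardiopt snr --nifti dwi.nii.gz --bval dwi.bval --bvec dwi.bvec
hardiopt simulate --config phantom.yaml --out-prefix sim
```

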