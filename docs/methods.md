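# Methods

## Imaging model

A row-column (RC) scanner observes

```
g(x,y,z) = M(x,y,z) · [ (f ∗ h)(x,y,z) · u_m(x,y,z) + u_a(x,y,z) ]
```

with f the tissue reflectivity on a regular lattice (voxel-center
convention, z = depth), h the depth-dependent PSF, u_m multiplicative
speckle, u_a additive sensor noise, and M the sampling function of the
finite set of transmit beams.  Beam-space samples (r, θ, φ) map to
Cartesian coordinates through x = r sinθ cosφ, y = r sinθ sinφ,
z = r cosθ.  Additive noise is far below the speckle floor and defaults to
zero.  Unobserved voxels carry NaN throughout the pipeline — never zero,
since a zero would be read as a genuine black echo by the data term.

**Speckle.**  The linear-domain speckle amplitude is generalized-gamma,
GG(ν, a, p) with density ∝ x^{pν−1} exp(−(x/a)^p).  The defaults ν = 1,
p = 2 give Rayleigh speckle; the scale defaults to the value that makes the
mean exactly 1, so the noise is mean-preserving.  The log-compressed
amplitude I = ln u then follows the Fisher–Tippett (Gumbel-type) law

```
p(I) = 2 exp[(2I − ln 2σ²) − exp(2I − ln 2σ²)],   σ = a/√2 ,
```

which is verified distributionally in the tests (KS distance < 0.01 at 10⁶
draws).  This identity is the bridge between the generator and the
reconstruction's data term.

**PSF.**  The spatial impulse response of a rectangular-element aperture is
computed by subdividing each element into sub-apertures ≤ λ/2 on a side
(halving the size changes the −6 dB width by < 1%) and accumulating
1/(2πR)-weighted, area-weighted arrival times into the sampled trace with
linear two-bin interpolation.  Transmit (columns, azimuth-focused) and
receive (rows, elevation-focused) responses are convolved with a
Gaussian-modulated pulse at the center frequency (60% fractional bandwidth
by default; the complex in-phase/quadrature pair is carried so envelope
detection is a plain magnitude).  The two-way pattern is the envelope peak
over time per lateral position; medium density drops out under the peak = 1
normalization.  Discrete kernels are the lateral pattern resampled at the
lattice spacing, multiplied by the axial envelope of the on-axis two-way
pulse (z = ct/2), truncated at −40 dB support and normalized to unit sum.

A **PSF bank** tiles the depth range with uniform bands, one kernel per
band center.  The system operator blends bands with hat-function weights
that form a partition of unity in depth: H f = Σ_b conv(λ_b(z)·f, K_b)
with zero-padded convolution, so H is exactly linear and its adjoint
Hᵀ g = Σ_b λ_b(z)·corr(g, K_b) satisfies ⟨Hf, g⟩ = ⟨f, Hᵀg⟩ to machine
precision (kernels are zero-padded to odd side lengths to keep the
convolve/correlate pair exactly adjoint).  An analytic separable-Gaussian
bank is provided for tests that need an exactly known, cheap depth-varying
operator; the simulated bank is exercised by the PSF characterization
tests.

**Measurement conventions.**  The −6 dB spot size is the full width of the
connected region around the pattern peak at −6 dB (amplitude 0.5), measured
along the wider of the two grid axes through the peak, with sub-grid
linear interpolation of the dB crossing.  The peak side-lobe level is the
highest local maximum outside the main lobe, where the main lobe is the
connected −6 dB (resolution) region around the peak: a broadband pulse
fills the nulls between the main lobe and the first side lobe (the saddle
sits near −18 dB here), so a main lobe defined by a −20 dB contour would
swallow the first side lobe and report none at all.  A pattern with no
secondary local maximum reports −∞.

For the 5 mm × 5 mm, 32 × 32 aperture at 5.9 MHz this simulation yields
−6 dB spot sizes of ≈ 0.37 mm at 5 mm and ≈ 1.35 mm at 20 mm depth and a
peak side lobe of ≈ −16 dB at the 5 mm focus (the figures
`scripts/acceptance.py` reports).  These follow the expected physics: the
focused-axis width scales like λz/D, and the first side lobe is the
one-way −13.3 dB sinc lobe of a uniform aperture, lowered slightly by the
orthogonal natural-focus roll-off.  One-way-per-dimension focusing cannot
produce two-way (sinc²-like) side-lobe suppression; that would require
focusing or apodizing both ways in the same dimension.

## Reconstruction

Working in the log domain (where the speckle is additive Fisher–Tippett),
the MAP estimate minimizes E = α·Σψ_u + β·Σψ_p.

* **Unary.**  At observed voxels, ψ_u = e^u − u with
  u = 2d − ln 2σ², d = log G − log H(e^F); constants of the NLL are
  dropped.  At voxels with Cr = 1 the term is exactly zero.  The gradient
  is analytic through H's adjoint:
  ∇ψ_u = −e^F ⊙ Hᵀ[ M · 2(e^u − 1) / H(e^F) ].
* **Pairwise.**  Within each sliding 11 × 11 window, every (center, other)
  pair contributes |fᵢ − fⱼ| · w_sp · w_fov.  Distances are in voxel units
  (σ_sp = 5 is unitless).  σ_fov = 0.03 is interpreted on the observed log
  image min-max normalized to [0, 1] (a displayed-dynamic-range fraction);
  the raw natural-log scale would make any plausible σ_fov either inert or
  all-pass.  Where either endpoint is unobserved w_fov falls back to 1, so
  only spatial proximity drives inpainting.  Boundary policy is *clip*:
  only pairs with both endpoints inside the slice count.  The subgradient
  uses sign(0) = 0 and matches central finite differences to 10⁻⁵.
* **Solver.**  Gradient descent with backtracking (halve the step until the
  energy does not increase; grow it by √2 after success), initialized from
  the bilinear-interpolation baseline — which is also the uncompensated-RC
  comparator, making the head-to-head comparison sharp.  Stops on relative
  energy change < `energy_tol` or when no descent step exists at machine
  scale.  A non-finite energy or gradient raises with the trace attached.
  Slices along the elevation axis are reconstructed independently; the PSF
  bank remains indexed by true voxel depth.
* **σ estimation.**  Unless fixed, σ is the closed-form MLE
  σ̂ = sqrt(mean(e^{2I})/2) over the observed-voxel residuals at
  initialization (the stationarity condition of the Fisher–Tippett NLL).
  When those residuals are degenerate (identity H with a data-consistent
  warm start) the centered value 1/√2 — which puts the density mode at
  d = 0 — is used.
* **Linear rendering.**  The linear image is e^F times a flux gain chosen
  so the re-blurred estimate matches the observed linear flux over the
  observed voxels.  Mode-matching and log-domain averaging each bias e^F
  low by a speckle-dependent factor (between the distribution's
  mode-to-mean ratio √2σ and e^{γ/2}); because the speckle is
  mean-preserving, the observed readings are an unbiased flux reference and
  the single gain removes the bias without touching ground truth.  For
  noise-free, fully observed data the gain is 1.

Default parameter sets: α = 0.3, β = 1.0 (simulated preset) and α = 0.7,
β = 0.3 (real preset); σ_sp = 5, σ_fov = 0.03, 11 × 11 cliques, η₀ = 0.1,
backtrack factor 0.5, energy_tol = 10⁻⁶, max 500 iterations, log floor
10⁻⁶ of the volume maximum.

## Synthetic data

`generate_scatterers` draws a Poisson number of uniform scatterer positions
at the configured density with Normal(0, sd) amplitudes; amplitudes inside
a cyst or wire are multiplied by its ratio (default 10), and wire cylinders
are densified 10× so sub-resolution wires remain visible.  The
piecewise-constant echogenicity map (background 1, features × ratio) is the
ground-truth reference that reconstructions are scored against.  Default
fan geometry: 32 azimuth events over ±20° (one per column of a 32-column
array), nearest-voxel ray stamping at a 0.1 mm radial step.

What the generator deliberately does **not** model: attenuation and
dispersion, element cross-talk, motion, reverberation, and
electronic/quantization noise.  Speckle is injected as an i.i.d.
multiplicative field after the PSF (the model's own factorization) rather
than emerging from coherent sub-resolution scatterer interference, so
speckle is spatially white where a fully coherent simulation would
correlate it at the PSF scale.  Passing tests therefore demonstrate
correctness of the stated model and estimator, not performance on any
particular physical scanner.

The RF path (`simulate_rf` + `das_beamform`) provides the higher-fidelity
cross-check: linear superposition of pulse-echo impulse responses per
receive row, dynamic-receive delay-and-sum, Hilbert envelope.  It is
validated by round-trip-delay localization (within one depth sample) and
the N-element coherent array gain (within 5% of N).

## Test problem sizes

Simulation sizes in the suite are chosen to exercise each property at the
smallest scale where it is meaningful: distributional checks at 10⁶ draws,
gradient checks on 8 × 8 slices, the exhaustive 3¹⁶ discrete oracle on a
4 × 4 slice (via an exact meet-in-the-middle factorization), the
reconstruction-ordering comparison on a single 128 × 128 slice with three
6 mm cysts 10 mm apart, 2-band PSF (0.5/0.9 mm lateral FWHM), Rayleigh
speckle and a 72-beam fan (≈50% coverage), and PSF characterization at
λ/4–λ/10 lateral steps.

## Known limitations

* Slice-independent optimization only; no full 3-D joint solve.
* The clique structure and FOV penalty operate in-slice; depth coupling
  enters only through the PSF bank.
* ENL/SNR use population (1/n) variance; SNR (μ/σ²) is not scale-invariant
  and is reported on the normalized intensity scale when a ground truth is
  available.
* The discrete/continuous minimizer agreement holds when the data term is
  strong enough that rounding the continuous solution is meaningful; with a
  dominant pairwise term the discrete optimum collapses to a constant field
  while the continuous one compromises.
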