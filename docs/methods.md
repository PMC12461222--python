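# Methods

This note records the models implemented in `cbctlab`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic
experiments can and cannot show about real dental CBCT data.

## Forward model

The measurement model is energy-integrated Beer-Lambert projection: for
a discrete spectrum with weights `w_k` at energies `E_k`,

    P = -ln( sum_k w_k exp(-F u_{E_k}) ),

where `F` is the discrete X-ray transform and `u_E` the attenuation
image derived from a material-label phantom at energy `E`.  The
continuous spectral integral is discretised as a finite weighted sum;
the bichromatic worked example does exactly this, and two to three bins
already produce the qualitative beam-hardening phenomenology (streaks,
subadditivity, sinogram inconsistency).  Attenuation tables are
interpolated log-linearly in energy, the standard convention for
attenuation curves, which is exact on two-point tables.

Units: attenuation values are per unit length with the pixel side as the
unit (the toy model's values 64 and 5 are per pixel traversal).  All
shipped phantoms use `pixel_size = 1`.

The mismatch of the linear model relative to a monochromatic reference
image `u_ref` is `zeta_u = P_poly - F u_ref`; the identity
`P_poly = F u_ref + zeta_u` holds to machine precision by construction
and is asserted in the tests.

### Noise

The components of `zeta_n` are named but not given a distributional form
in the CT-physics literature convention we follow, so the package
concretises them with standard energy-integrating detector statistics:
per ray and energy bin, photon counts are Poisson with mean
`I_in w_k exp(-l_k)`; bins are summed; zero-mean Gaussian electronic
noise of configurable standard deviation is added; the total is clamped
at one count before the log.  Photon starvation beyond the clamp and
Compton scatter are deliberately not modelled.

### Motion

Motion is rigid in-plane translation of the phantom along y, constant
within a view and piecewise constant across a contiguous window of views
(default envelope: displacements up to ±5 length units within views
80–140 of 400, matching the scan-time window in which head motion
typically occurs).  Sub-pixel shifts resample the material-derived
attenuation images bilinearly; labels are never interpolated.  Views
with zero displacement reuse the static images, so they are bitwise
identical to the static scan.

## Geometry and projectors

Images are centred at the origin with row 1 at the top; a parallel ray
at view angle `phi` travels along `(-sin phi, cos phi)`, so `phi = 0`
sums columns and `phi = pi/2` sums rows, matching the 3x3 worked
example's equation layout.  System matrices store exact Siddon
pixel-intersection lengths (numba-compiled), ties at pixel corners
resolved by the half-open cell convention `[lo, hi)`.  The adjoint is
the sparse transpose, so the inner-product identity holds to solver
precision for every geometry.  The toy geometry is special-cased as the
printed 9x9 binary incidence matrix: its diagonal rays use unit weights
(not sqrt 2) because the worked example sums pixel values with unit
coefficients.

Fan beams are handled natively and via rebinning to parallel geometry
(bilinear interpolation in `(beta, u)`, periodic in `beta`); cone-beam
support is restricted to small circular-orbit grids.  The fan/cone
source and detector radii have no canonical values and are plain
configuration parameters.

## Classical reconstruction

* **FBP**: frequency-domain ramp filter (Ram-Lak, Shepp-Logan or cosine
  windows), zero-padded to the next power of two, with optional
  replicate-edge extension before filtering to temper truncation ringing
  (a dialect flag, on by default); voxel-driven backprojection with
  linear detector interpolation.
* **FDK**: cosine weighting, row-wise ramp filtering in isocentre
  coordinates, inverse-square distance weighting, intended for grids up
  to roughly 200 x 200 x 30.
* **Least squares**: rank-revealing dense solve on small systems (the
  exact minimum-norm representative, which is the canonical
  deterministic choice on rank-deficient systems such as the 3x3 toy);
  LSMR from a zero start on large systems.
* **TV**: monotone FISTA with adaptive restart on the Huber-smoothed
  isotropic TV objective (smoothing eps = 1e-3), step `1/L` with `L`
  from 20 power iterations plus the smoothed-TV curvature bound;
  objective trace recorded and non-increasing by construction; optional
  nonnegativity projection.
* **MAR baseline**: the metal trace is the set of rays whose forward
  projection of the mask is nonzero; per view, trace values are replaced
  by 1-D linear interpolation from the nearest non-trace neighbours; a
  fully covered view falls back to its mean and is flagged.

The printed reconstruction of the 3x3 worked example does not satisfy
the normal equations of the printed system (its normal-equation residual
is ~20), so whatever solver produced it is not identifiable; the package
therefore reports it side by side with the min-norm solution and never
asserts equality.

## Range-space analysis

The decomposition `P = P_range + P_perp` is computed by least squares on
the explicit sparse matrix, not by FBP composition, so orthogonality
holds to solver tolerance rather than discretisation error.  The
restricted-isometry probe samples image pairs from the phantom generator
and reports the extremes of `||A(u - u')|| / ||u - u'||`; it is an
empirical diagnostic of the sampled image family, never a certificate.

### Truncation degradation experiment

The interior-problem setup drives the degradation-with-iterations
phenomenon: the detector is truncated to its central half, and the
reconstruction grid covers only the resulting field of view (48 px of a
64 px phantom), so every lateral ray carries attenuation from tissue
outside the grid and the data are inconsistent with *any* interior
image.  Iterations start from the FBP image of the truncated data — the
conventional-pipeline initialisation — and the region-of-interest RMSE
grows from iteration 10 to 200 with no or weak TV.  With moderate or
strong TV weights the same growth appears later (by iteration 500 in our
setting); the test suite asserts both regimes.  Problem size (64 px
phantom, 180 views, central-half detector) keeps this experiment at
seconds of runtime.

## INR reconstruction

The coordinate network is a Fourier-feature encoding (64 Gaussian
frequencies, scale 4 on the [-1,1] normalised domain) followed by a
tanh MLP trunk with two softplus heads, so both the image `u(x)` and the
energy-dependence field `sigma(x)` are nonnegative — the corrector
`zeta_hat(L) = ln(sinh L / L)` requires `L >= 0`.  The loss is the mean
*absolute* per-ray residual, exactly the L1 physics objective; ray
integrals use stratified sampling (N = 64 bins per ray, one uniform
point per bin), which is unbiased and is verified as such by a
statistical test.

No automatic-differentiation framework is used: the MLP forward and
backward passes and the Adam optimiser are written directly in numpy
(float32 parameters and activations; integrals accumulated in float64),
which keeps training bit-reproducible from a single seed and fast enough
for desk-scale experiments.

Numerical evaluation of the corrector switches between a series
(`ln(1 + L^2/6 + L^4/120)` below 1e-3), the direct formula, and a
log-domain form (`L - ln 2L + ln(1 - e^-2L)` above 20); it agrees with
200-digit reference evaluations to 1e-9 relative across [1e-12, 700].
Its derivative is the Langevin function `coth L - 1/L`.

### Head attribution

The split between the two heads is underdetermined ray-by-ray: the image
head can absorb the range-consistent part of the beam-hardening
mismatch.  Because the energy-dependent component physically lives in
dense materials, the nonlinear head carries a density-gated penalty: at
every sample point, `sigma` is penalised with weight proportional to
`1/(u + 0.02)^2`, with the image head treated as a fixed gate (no
gradient through it).  The default weight (1e-3) concentrates `sigma`
on metal (two orders of magnitude contrast between metal and soft
tissue in the fitted fields) without degrading the image head.  The
corrector head is initialised at a small positive level so its ray
integrals start where the Langevin derivative is not vanishing;
learning follows a cosine decay from 2e-3.

The linear head absorbs the constant offset between the corrector's
nonnegative output and the signed mismatch relative to the chosen
reference energy; the reference for evaluation is the high-energy
(hardened-beam) image, against which the mismatch on metal rays is
positive.

### Scale of the experiments

The flagship experiment is 2D at desk scale: a 64 px bichromatic dental
phantom with two metal disks, 90 parallel views, three network seeds
(~3 minutes per seed on one CPU core).  Training is stochastic and
mildly seed-sensitive, so the acceptance protocol requires success in at
least two of three seeds, for the image comparison and for the
corrector-mismatch rank correlation alike.  The corresponding 3D
cone-beam experiment (200 x 200 x 30, 200 views, about an hour) is not
run in the test suite; the operator/corrector property tests plus the 2D
surrogate stand in for it.

## What the synthetic data do and do not show

The phantom generator produces a soft-tissue head ellipse with a bone
rim, a lower-jaw arch and tooth disks; tissue attenuation varies only
mildly with energy while metal varies strongly, so metal dominates beam
hardening (configurable).  This reproduces the *mechanisms* —
inconsistency, streak formation, interaction nonlinearity, truncation
divergence, motion blur — but not clinical morphology, scatter,
detector lag, HU calibration, or realistic spectra.  Passing tests
demonstrate correctness of the operators and the qualitative artefact
physics, not clinical performance.

## Known limitations

* Scatter and photon starvation are unmodelled; `zeta_u` covers beam
  hardening only.
* The sinh corrector is implemented exactly as the closed form above;
  its adequacy for a given spectrum is measured (loss ablation,
  rank-correlation tests), not assumed.
* Fan-to-parallel rebinning assumes a full 2pi scan; no short-scan
  (Parker) weighting.
* The empirical RIP probe depends entirely on the phantom family
  sampled.
* 3D INR training is supported by the code path but impractical on a
  single CPU; all INR defaults target 2D grids of 64-128 px.
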