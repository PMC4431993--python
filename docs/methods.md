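# Methods

This note records the models, conventions and numerical choices behind
each module — the decisions a maintainer would otherwise have to reverse
engineer from the code.

## Height-map conventions

A `HeightMap` is a rows × cols grid of heights in nm with a physical
pixel pitch in nm/px.  Row 0 is the top of the image and z is positive
away from the substrate; all modules inherit this single convention so
that valley/peak statistics and skewness never flip sign between stages.
Rectangular pixels are carried through I/O, but the fractal and
Minkowski estimators assume isotropic sampling and refuse maps whose
pixel sizes differ by more than 1 part in 10⁶.

The ASCII dialect is whitespace-separated with `.` decimals and optional
`#`-prefixed header lines (`width_nm`, `height_nm`, `label`); no locale
handling.  TIFF stores float32 samples with the calibration in a JSON
image description, so float32-valued maps round-trip bit-exactly and
float64 maps round-trip at float32 precision; the ASCII writer prints 10
significant digits (≤ 1e-6 nm round-trip error at AFM height scales).
Proprietary instrument formats and raw-scan leveling are out of scope.

## Roughness statistics

The reference height for every deviation statistic is Z̄ = mean(|Z_i|),
and skewness/kurtosis use absolute central moments, |Z_i − Z̄|³ and
|Z_i − Z̄|⁴ — the convention of the AFM texture literature this package
follows.  Both choices coincide with the ordinary mean and differ from
the signed moments only in sign behaviour when maps are non-negative,
which zero-referencing (shift so min = 0, the pipeline default) ensures.
The standard signed skewness/kurtosis are reported alongside, clearly
labelled, for comparability with common AFM practice.  Consequences
worth knowing:

* the absolute-moment skewness is non-negative by construction
  (≈ 2√(2/π) ≈ 1.596 for a Gaussian surface, not 0);
* for an all-negative constant surface the verbatim formulas give
  R_a = R_q = 2|c| rather than 0 — the zero-roughness identity for
  constants is a property of non-negative maps.

R_t = R_mvd + R_mph holds identically because deviations from Z̄ always
bracket zero (the mean deviation is ≤ 0).  When R_q = 0 the four moment
ratios are flagged undefined (`None`) instead of propagating NaN.

The mode Z_mp is the center of the fullest histogram bin (256 bins by
default, matching 512² sampling; ties break toward the lowest bin),
since no standard estimator exists.  The unimodality check smooths the
density with a Gaussian of σ = n_bins/32 bins, ignores maxima below 10 %
of the global peak (sampling noise, not modes), and takes its mode from
the smoothed density; it passes when |mean − median| and
|median − mode| are both within 0.5·R_q and a single significant
maximum remains.  On default particle scenes this holds in roughly 8 of
10 seeds — the mean/median/mode near-coincidence expected of unimodal
AFM height distributions.

## Synthetic surfaces

The fractional-Brownian background is synthesized spectrally: Gaussian
white noise is shaped in Fourier space by the radial amplitude law
f^(−(H+1)) — i.e. a 2D power spectral density ∝ f^(−2(H+1)), the
*surface* convention under which D_f = 3 − H; conventions differing by
one between profile and surface definitions are a classic source of
off-by-one-half dimension errors, hence the explicit statement.  The
zero-frequency component is removed (mean-free surface) and the field is
rescaled so the sample RMS equals `rms_target` exactly.  Grid sizes are
powers of two ≥ 16 for the FFT.  Identical `SceneSpec`s (including the
seed) produce bit-identical surfaces.

Defaults emulate the study conditions this package was built around:
512 × 512 px over a 2 μm field (≈ 3.9 nm/px), background R_q = 20 nm
(mid-range between healthy ≈ 10–43 nm and atheromatous ≈ 10–39 nm
tissue scales), H = 0.7.  Deposited particles are spherical caps with
truncated-normal radii (clipped at 1 px and ±3σ; defaults 40 ± 10 nm,
cap height 0.6·r, 200 caps), seated on the background height beneath
their center and combined by pointwise maximum — non-interpenetrating
solids, so deposition never lowers a pixel and Z̄, R_mph are
non-decreasing in particle count.  Each particle draws from its own RNG
stream spawned at a fixed index, so increasing the count adds particles
without moving earlier ones.  No size distribution is known for real
dendrimer aggregates on tissue; the defaults reproduce tissue-scale
roughness, not literal particle counts, and the "heavy aggregation"
scene used in validation (25 caps of mean radius 80 nm, cap height
0.8·r, on an R_q = 10 nm background) is chosen so aggregates tower over
the background — the regime in which the Minkowski volume curve visibly
loses its point symmetry.

What the generator does *not* emulate: particle mechanics and charge
effects, tissue biomechanics, scanner drift/line artifacts, and
measurement noise.  Passing tests therefore demonstrate correctness of
the estimators on ideal self-affine-plus-caps topographies, not
robustness to instrument artifacts.

## Fractal estimators

All six estimators build a (log scale, log statistic) point set over a
dyadic ladder l = 2, 4, …, size/4 px and fit an ordinary least-squares
slope.  Mappings (slopes taken against log *scale*):

| method             | statistic                                   | D_f          |
|--------------------|---------------------------------------------|--------------|
| cube_counting      | 3D box count N(l)                           | −slope       |
| triangulation      | triangulated area A(l)                      | 2 − slope    |
| variance           | mean within-box variance σ²(l)              | 3 − slope/2  |
| power_spectrum     | averaged 1D periodograms, scale = 1/f       | (7 − slope)/2|
| structure_function | mean squared increment S(τ)                 | 3 − slope/2  |
| variation          | mean (max − min) in ε-windows               | 3 − slope    |

Every mapping is validated against the D = 3 − H ground truth rather
than trusted: the acceptance battery recovers D_f within ±0.15 (±0.2
for the power spectrum) as the mean over 10 seeds at 1024² for
H ∈ {0.3, 0.5, 0.7}.

Numerical choices, each calibrated on that oracle before the test
thresholds were frozen:

* **Height normalization.**  Cube counting and triangulation operate on
  a copy whose height range is rescaled to a fixed multiple of the
  lateral extent in pixel units, making both unit-free and exactly
  invariant under height scaling (variance, structure function and
  variation are scale-free by construction; the power spectrum keeps
  the amplitude in its intercept).  Cube counting uses factor 8 so the
  counting boxes never saturate at one box per column at the top of the
  ladder.
* **Fit ranges.**  The auto range excludes any zero statistic and the
  largest-scale octave (few boxes, poor statistics) — except for cube
  counting, which keeps the top of the ladder and instead drops scales
  below 16 px (relaxing only when fewer than 4 points would remain):
  block range statistics over a handful of samples systematically
  underestimate the within-block oscillation of a band-limited field,
  biasing the small-scale slope toward smooth.  The variation ladder
  similarly starts at ε = 4 px when long enough.  The power-spectrum
  auto range additionally trims the near-Nyquist octave, where grid
  anisotropy bends the 1D periodogram.  Explicit `(i0, i1)` ranges
  override all of this.
* **Degenerate inputs.**  Flat surfaces (including tilted planes) are
  analytically D = 2 for cube counting, triangulation and variation;
  variance, structure function and power spectrum raise a
  degenerate-surface error on zero-variance input, which the pipeline
  records as a flagged stage rather than a number.
* **Out-of-range estimates** (D ∉ [2, 3]) set a warning flag and are
  never clamped — the power-spectrum method legitimately drops below 2
  on over-smoothed, non-fractal inputs, and that is diagnostic.
* **B-spline resampling** (cubic, `scipy.ndimage.zoom`) is off by
  default (factor 1): interpolation smooths the field and shifts D_f by
  up to ≈ 0.1–0.3 depending on method, so enabling it is an explicit
  choice (`--bspline-factor`).  Boundary conditions perturb a resampled
  plane near the edges only; the ripple decays geometrically inward.

Known limitations: estimates at 256² carry single-seed scatter of
±0.02–0.05 and small-size bias; the variation and cube-counting
estimators remain the most biased at low H (≈ −0.12 at H = 0.3 even at
1024²).  Box-counting families underestimate high dimensions on
band-limited synthetic fields — a property of the estimators, not a
code defect, and the reason acceptance tolerances are stated on means
over seeds.

## Minkowski functionals

Thresholds sweep [Z_min, Z_max] with both endpoints, 256 steps by
default.  White is `height ≥ z`: this pins V(Z_min) = 1 exactly while
V vanishes for any threshold above Z_max.  (A strict `>` binarization
would instead leave V(Z_min) < 1 by the argmin pixels; the two
conventions differ only on exact-tie pixels.)  White components are
counted 8-connected and black 4-connected — the Jordan pairing that
avoids the digital-topology paradox of a diagonal line both connecting
itself and disconnecting its background.  Components touching the
border count as components; this breaks exact complement duality at
borders, so the duality cross-check in the tests uses black-framed
images, where χ·N = euler₈(white) − 1 = −euler₄(black) holds exactly.
A phase covering the whole image is conventionally structureless
(χ = 0 at the sweep extremes rather than ±1/N).  χ and S are reported
per pixel so curves from 1 μm and 5 μm scans are comparable; raw counts
are stored alongside.

Landmarks: thresholds of global χ minimum/maximum, S maximum, the
interpolated first V ≤ 0.5 crossing, the vanishing threshold (first z
after the χ maximum with |χ| ≤ 1/N by default), and χ plateau runs.
On an all-zero χ curve the χ landmarks are flagged undefined.  The
volume-symmetry score is 1 − mean|V(z½+δ) + V(z½−δ) − 1| over offsets δ
spanning the wider half of the range, V extended by 1/0 outside; a
Gaussian surface scores ≥ 0.95, and heavy deposition lowers the score
by skewing mass into the high tail.

## Tip correction

The tip model is the upper envelope of a 12 nm-radius spherical apex cap
and a four-sided pyramid rotated 45° in-plane, sampled on an odd grid
with the apex pinned to 0 at the center.  The sidewall half-angle
defaults to 17.5°, typical of silicon probes, and is exposed because
tip specifications rarely state it precisely.  Imaging is grayscale
dilation `out(x) = max_u [surface(x−u) + tip(u)]`; reconstruction is
erosion by the reflected tip, `rec(x) = min_u [image(x+u) − tip(u)]`,
an upper bound on the true surface.  The certainty map marks pixels that
were the *unique* contact point for some apex position — at such pixels
the reconstruction is exact (the touch-set argument: the true contact
always lies in the touch set, so a singleton touch set identifies it).
Touch detection uses a relative tolerance of 1e-9 of the height scale.

Borders are handled by edge replication, preserving the 512² size; a
conservative alternative (cropping by the tip half-extent) amounts to
discarding the border band of the output.  In the pipeline,
reconstruction runs *before* fractal analysis (correct-then-measure)
and is skipped for roughness and Minkowski stages, which operate on the
zero-referenced input; both stages are shift-invariant apart from Z̄
itself, which is meant to describe the as-measured map.

## Pipeline determinism and problem sizes

Reports embed their config, an input hash and the software version, and
floats are rounded to 10 digits before serialization, so identical
config + input yields byte-identical JSON.  The validation battery uses
1024² surfaces (10 seeds per H) for fractal recovery, 512² for noise
limits, 256² for paired directional comparisons, and 128² for the
morphology laws — sizes at which the estimators' asymptotic behaviour
is already stable while the full suite completes in about a minute.
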