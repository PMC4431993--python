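# nanotex

Surface-texture analysis of atomic-force-microscopy (AFM) height maps,
built for quantifying how nanoparticles aggregate on soft biological
surfaces — e.g. dendrimer nanocarriers deposited on healthy versus
atheromatous carotid tissue, where the tissue type changes both the
roughness amplitude and the multiscale complexity of the imaged surface.

Given a height map z(x, y) on a regular grid (nm heights, nm pixel
pitch), the package computes:

* **Amplitude roughness statistics** over the N pixel heights Z_i, using
  the absolute-moment conventions of the AFM texture literature:
  Z̄ = (1/N)Σ|Z_i|, R_a = (1/N)Σ|Z_i − Z̄|, R_q = √((1/N)Σ(Z_i − Z̄)²),
  R_t = |Z_max − Z_min|, maximum valley depth R_mvd and peak height
  R_mph, R_sk = (1/(N R_q³))Σ|Z_i − Z̄|³ and R_ku = (1/(N R_q⁴))Σ|Z_i − Z̄|⁴,
  together with the height probability density f(Z), its median Z_1/2 and
  mode Z_mp, and the standard signed skewness/kurtosis for comparison.
* **Fractal dimension D_f ∈ [2, 3]** by six estimators — variance, cube
  counting, triangulation, power spectrum, structure function and
  variation — each reducing to a least-squares slope of a log-log
  statistic-versus-scale curve.  For a self-affine surface with Hurst
  exponent H, every estimator targets D_f = 3 − H.
* **Minkowski functionals** of the thresholded map: covered volume
  fraction V(z), boundary density S(z) and the Euler–Poincaré
  connectivity χ(z) = (8-connected white components − 4-connected black
  components)/N, swept over the full height range, plus landmark
  thresholds (χ extrema, V = 0.5 crossing) and a point-symmetry score of
  the volume curve.
* **Tip-artifact correction**: the AFM image is modelled as the grayscale
  morphological dilation of the surface by the tip (default: 12 nm apex
  sphere on a four-sided pyramid rotated 45°); erosion by the reflected
  tip yields an upper-bound surface reconstruction with a certainty map
  marking exactly recovered pixels.

Because real tissue scans are rarely shareable, a synthetic-surface
module generates the validation ground truth: spectrally synthesized
fractional-Brownian backgrounds (P(f) ∝ f^(−2(H+1)), so D_f = 3 − H
exactly), deposited spherical-cap particle fields, and exact geometric
fixtures.

## Worked example

Simulate a scene of large aggregates (25 caps, mean radius 80 nm, cap
height 0.8·r) on a smooth self-affine background (H = 0.7, R_q = 10 nm),
then analyze it:

```sh
nanotex simulate particles --size-px 256 --count 25 --radius-mean-nm 80 \
    --height-scale 0.8 --rms-nm 10 --hurst 0.7 --seed 7 --out scene.tif
nanotex analyze scene.tif --out report.json
```

The report (abridged) reads:

```
roughness:  Zbar 44.56 nm   Ra 24.17 nm   Rq 32.19 nm
            Rsk_abs 2.086   Rku_abs 5.684   unimodal false
fractal:    variance 2.154  cube_counting 2.191  triangulation 2.113
            power_spectrum 2.084  structure_function 2.267  variation 2.279
minkowski:  volume_symmetry_score 0.920   z_half_volume 33.4 nm
            z_min_chi 27.1 nm   z_max_chi 45.3 nm
tip:        certainty fraction 0.510
```

Reading: deposition inflated the amplitude statistics far beyond the
10 nm background (R_q ≈ 32 nm) and skewed the height distribution to the
right (absolute skewness ≈ 2.1, bimodal), the smooth caps pulled every
fractal estimate toward the smooth limit 2, the Minkowski volume curve
lost its point symmetry (score 0.92 versus ≈ 0.99 for the bare
background), and about half the pixels were reliably recovered by tip
correction — the narrow valleys between aggregates are where the pyramid
tip cannot reach.

`nanotex compare a.json b.json --table cmp.csv` tabulates two or more
reports as long-format (sample, metric, value) rows with pairwise
differences — deliberately descriptive, with no hypothesis testing,
since each scan is a single observation.

## Library use

```python
from nanotex import (SceneSpec, ParticleFieldSpec, generate_fbm_surface,
                     analyze_sample, AnalysisConfig)

scene = SceneSpec(size_px=512, hurst=0.7, rms_target=20.0, seed=1,
                  particles=ParticleFieldSpec(count=200))
surface = generate_fbm_surface(scene)
report = analyze_sample(surface, AnalysisConfig())
print(report.to_json())
```

See `docs/methods.md` for the models, conventions and numerical choices.
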