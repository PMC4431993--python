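"""Synthetic surfaces with known ground truth.

Real AFM scans of tissue are rarely shareable, so every estimator in this
package is validated on synthetic scenes instead: isotropic self-affine
fractional-Brownian (fBm) backgrounds with a prescribed Hurst exponent H
(for which the surface fractal dimension is exactly D = 3 - H), deposited
spherical-cap particle fields emulating nanoparticle aggregates, and exact
geometric fixtures (planes, steps, disk fields, checkerboards) whose
roughness and Minkowski functionals are known in closed form.

The fBm background is synthesized spectrally: a Gaussian white field is
shaped in Fourier space by the radial power law ``P(f) ~ f^(-2(H+1))``
(the 2D surface convention that makes D = 3 - H hold), the zero-frequency
component is removed, and the result is rescaled so its sample RMS
roughness equals ``rms_target`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from nanotex.errors import FixtureError, ParameterError
from nanotex.surface_io import HeightMap


@dataclass
class ParticleFieldSpec:
    """Spherical-cap particle field deposited on a background.

    Radii are drawn from a normal distribution truncated at 1 px and at
    3 standard deviations; each cap of lateral radius r has apex height
    ``height_scale * r`` and is seated on the background height under its
    center, combined by pointwise maximum (non-interpenetrating solids).

    ``placement='clustered'`` draws ``cluster_count`` cluster centers
    uniformly and scatters particles around them with Gaussian ``spread``
    (nm); ``'uniform'`` scatters particles independently.
    """

    count: int = 200
    radius_mean: float = 40.0
    radius_sd: float = 10.0
    height_scale: float = 0.6
    placement: str = "uniform"
    cluster_count: int = 8
    spread: float = 150.0

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ParameterError(f"count must be >= 0, got {self.count}")
        if self.radius_mean <= 0:
            raise ParameterError(f"radius_mean must be > 0, got {self.radius_mean}")
        if not (0 < self.height_scale <= 1):
            raise ParameterError(
                f"height_scale must be in (0, 1], got {self.height_scale}"
            )
        if self.placement not in ("uniform", "clustered"):
            raise ParameterError(f"unknown placement {self.placement!r}")


@dataclass
class SceneSpec:
    """Parameters of a synthetic AFM scene.

    Defaults mirror the scan geometry of the study conditions this package
    emulates: 512 x 512 px maps over a 2 um field (3.90625 nm/px) with an
    RMS background roughness of 20 nm, mid-range between healthy and
    atheromatous tissue scales.
    """

    size_px: int = 512
    pixel_size: float = 2000.0 / 512
    hurst: float = 0.7
    rms_target: float = 20.0
    particles: Optional[ParticleFieldSpec] = None
    seed: int = 0
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.hurst < 1):
            raise ParameterError(f"hurst must be in (0, 1), got {self.hurst}")
        if self.rms_target < 0:
            raise ParameterError(f"rms_target must be >= 0, got {self.rms_target}")
        n = self.size_px
        if n < 16 or (n & (n - 1)) != 0:
            raise ParameterError(
                f"size_px must be a power of two >= 16 (FFT synthesis), got {n}"
            )
        if self.pixel_size <= 0:
            raise ParameterError(f"pixel_size must be > 0, got {self.pixel_size}")


def generate_fbm_surface(spec: SceneSpec) -> HeightMap:
    """Generate an isotropic self-affine surface by spectral synthesis.

    The output is mean-free with sample RMS exactly ``spec.rms_target``
    (rescaling is exact by construction) and is bit-identical for
    identical specs, including the seed.  If ``spec.particles`` is set the
    particle field is deposited on the background (see
    :func:`deposit_particles`).
    """
    n = spec.size_px
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    white = rng.standard_normal((n, n))
    spectrum = np.fft.fft2(white)
    fx = np.fft.fftfreq(n, d=spec.pixel_size)
    fy = np.fft.fftfreq(n, d=spec.pixel_size)
    f = np.hypot(fy[:, None], fx[None, :])
    amp = np.zeros_like(f)
    nz = f > 0
    # amplitude ~ f^-(H+1)  <=>  PSD ~ f^-2(H+1)
    amp[nz] = f[nz] ** (-(spec.hurst + 1.0))
    surf = np.fft.ifft2(spectrum * amp).real
    surf -= surf.mean()
    rms = np.sqrt(np.mean(surf**2))
    if rms > 0 and spec.rms_target > 0:
        surf *= spec.rms_target / rms
    elif spec.rms_target == 0:
        surf[:] = 0.0
    out = HeightMap(
        surf,
        spec.pixel_size,
        spec.pixel_size,
        label=spec.label or f"fbm(H={spec.hurst}, Rq={spec.rms_target}nm)",
        meta={"hurst": str(spec.hurst), "seed": str(spec.seed), **spec.meta},
    )
    if spec.particles is not None:
        out = deposit_particles(out, spec.particles, spec.seed)
    return out


def _cap_profile(rho2: np.ndarray, radius: float, height: float) -> np.ndarray:
    """Height of a spherical cap with lateral radius `radius` and apex
    height `height`, as a function of squared lateral distance."""
    sphere_r = (radius**2 + height**2) / (2.0 * height)
    z = height - sphere_r + np.sqrt(np.maximum(sphere_r**2 - rho2, 0.0))
    return np.where(rho2 <= radius**2, z, 0.0)


def deposit_particles(
    base: HeightMap, particles: ParticleFieldSpec, seed: int
) -> HeightMap:
    """Deposit spherical-cap particles on a surface by pointwise maximum.

    Each particle has its own RNG stream spawned from ``seed`` at a fixed
    index, so increasing ``count`` adds particles without moving the ones
    already placed.  Deposition never lowers a pixel, so mean height and
    maximum peak height are non-decreasing in ``count``.
    """
    ps = base.require_square_pixels()
    heights = base.heights.copy()
    rows, cols = heights.shape
    root = np.random.SeedSequence(seed)
    # one child per particle plus one for cluster centers, prefix-stable
    children = root.spawn(particles.count + 1)
    centers = None
    if particles.placement == "clustered" and particles.count > 0:
        crng = np.random.default_rng(children[-1])
        centers = crng.uniform(
            low=[0, 0],
            high=[rows * ps, cols * ps],
            size=(max(particles.cluster_count, 1), 2),
        )
    for i in range(particles.count):
        prng = np.random.default_rng(children[i])
        r = prng.normal(particles.radius_mean, particles.radius_sd)
        r = float(np.clip(r, max(ps, particles.radius_mean - 3 * particles.radius_sd),
                          particles.radius_mean + 3 * particles.radius_sd))
        if centers is None:
            cy = prng.uniform(0, rows * ps)
            cx = prng.uniform(0, cols * ps)
        else:
            cy0, cx0 = centers[prng.integers(len(centers))]
            cy = cy0 + prng.normal(0, particles.spread)
            cx = cx0 + prng.normal(0, particles.spread)
            cy %= rows * ps
            cx %= cols * ps
        apex = particles.height_scale * r
        # bounding window in pixels
        r_px = int(np.ceil(r / ps)) + 1
        iy, ix = int(round(cy / ps)), int(round(cx / ps))
        y0, y1 = max(iy - r_px, 0), min(iy + r_px + 1, rows)
        x0, x1 = max(ix - r_px, 0), min(ix + r_px + 1, cols)
        if y0 >= y1 or x0 >= x1:
            continue
        yy = (np.arange(y0, y1) * ps - cy)[:, None]
        xx = (np.arange(x0, x1) * ps - cx)[None, :]
        rho2 = yy**2 + xx**2
        pedestal = heights[min(max(iy, 0), rows - 1), min(max(ix, 0), cols - 1)]
        cap = _cap_profile(rho2, r, apex)
        patch = np.where(rho2 <= r**2, pedestal + cap, -np.inf)
        heights[y0:y1, x0:x1] = np.maximum(heights[y0:y1, x0:x1], patch)
    return base.copy_with(heights, label=(base.label + "+particles").strip("+"))


def make_fixture(
    kind: str,
    size_px: int = 256,
    pixel_size: float = 2000.0 / 512,
    **params,
) -> HeightMap:
    """Exact geometric fixtures with closed-form texture measures.

    Parameters
    ----------
    kind : {'plane', 'step', 'disk_field', 'checkerboard'}
        * ``plane`` — constant height ``h0`` (default 0), optional
          ``slope_x``/``slope_y`` in nm/px for an inclined plane.
        * ``step`` — left half ``h0``, right half ``h1``.
        * ``disk_field`` — ``k`` disjoint disks of radius ``r`` px at
          height ``h1`` over a background ``h0``; raises if the requested
          disks cannot be placed without overlap.
        * ``checkerboard`` — alternating single pixels ``h0``/``h1``.
    """
    h0 = float(params.get("h0", 0.0))
    h1 = float(params.get("h1", 100.0))
    n = size_px
    if kind == "plane":
        z = np.full((n, n), h0)
        sx = float(params.get("slope_x", 0.0))
        sy = float(params.get("slope_y", 0.0))
        if sx or sy:
            z = z + sy * np.arange(n)[:, None] + sx * np.arange(n)[None, :]
    elif kind == "step":
        z = np.full((n, n), h0)
        z[:, n // 2 :] = h1
    elif kind == "disk_field":
        k = int(params.get("k", 3))
        r = int(params.get("r", max(4, n // 16)))
        z = np.full((n, n), h0)
        margin = r + 2
        spacing = 2 * r + 3
        per_row = max((n - 2 * margin) // spacing + 1, 0)
        if per_row == 0 or k > per_row * per_row:
            raise FixtureError(
                f"cannot place {k} disjoint disks of radius {r} px in a "
                f"{n}x{n} grid"
            )
        yy, xx = np.mgrid[0:n, 0:n]
        placed = 0
        for gy in range(per_row):
            for gx in range(per_row):
                if placed >= k:
                    break
                cy = margin + gy * spacing
                cx = margin + gx * spacing
                z[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = h1
                placed += 1
        explicit = params.get("centers")
        if explicit is not None:
            # caller-specified centers must be pairwise disjoint
            centers = [tuple(c) for c in explicit]
            for i, (ay, ax) in enumerate(centers):
                for by, bx in centers[i + 1 :]:
                    if (ay - by) ** 2 + (ax - bx) ** 2 <= (2 * r) ** 2:
                        raise FixtureError("requested disks overlap")
            z = np.full((n, n), h0)
            for cy, cx in centers:
                z[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = h1
    elif kind == "checkerboard":
        yy, xx = np.mgrid[0:n, 0:n]
        z = np.where((yy + xx) % 2 == 0, h1, h0).astype(np.float64)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return HeightMap(z, pixel_size, pixel_size, label=f"fixture:{kind}")
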