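"""Fractal dimension of self-affine surfaces by six multiscale estimators.

For an isotropic self-affine surface with Hurst exponent H in (0, 1) the
fractal dimension is D = 3 - H, between 2 (smooth) and 3 (extremely
rough).  Each estimator builds a log-log point set — a statistic versus a
scale — and converts the least-squares slope into D by a fixed mapping:

================== ============================== =====================
method             statistic vs scale             slope -> D
================== ============================== =====================
cube_counting      3D box count N(l), dyadic l    D = -slope
triangulation      triangulated area A(l)         D = 2 - slope
variance           within-box height variance     D = 3 - slope/2
power_spectrum     averaged 1D row periodograms   D = (7 + slope)/2
structure_function mean squared increment S(tau)  D = 3 - slope/2
variation          mean eps-oscillation (max-min) D = 3 - slope
================== ============================== =====================

Cube counting and triangulation operate on a height-normalized copy of
the map (height range rescaled to the lateral extent in pixel units) so
that both are invariant under height scaling; variance, structure
function and variation are scale-free by construction.  The power
spectrum is the only estimator whose intercept carries the amplitude; its
D can legitimately fall below 2 on non-fractal inputs, which is flagged,
never clamped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import maximum_filter, minimum_filter, zoom

from nanotex.errors import DegenerateSurfaceError, FitError, ParameterError
from nanotex.surface_io import HeightMap

METHODS = (
    "variance",
    "cube_counting",
    "triangulation",
    "power_spectrum",
    "structure_function",
    "variation",
)


@dataclass
class FitConfig:
    """Controls the log-log fit and optional resampling.

    ``fit_range='auto'`` drops the largest-scale octave (poor statistics)
    and any point whose statistic is zero; ``(i0, i1)`` selects an
    explicit index slice of the point set.  ``bspline_factor`` > 1
    resamples the map on a finer grid with cubic B-splines before
    estimation.
    """

    fit_range: str | tuple[int, int] = "auto"
    bspline_factor: int = 1
    psd_trim_high_octave: bool = True


@dataclass
class FractalEstimate:
    """One estimator's log-log point set, fit, and derived dimension."""

    method: str
    d_f: float
    slope: float
    intercept: float
    r_squared: float
    points: list[tuple[float, float]]
    fit_range: tuple[int, int]
    out_of_range: bool = False
    degenerate: bool = False
    warnings: list[str] = field(default_factory=list)


def fit_loglog(
    points: Sequence[tuple[float, float]],
    fit_range: str | tuple[int, int] = "auto",
) -> tuple[float, float, float, tuple[int, int]]:
    """Ordinary least squares on a (log scale, log statistic) point set.

    Points must be ordered by increasing scale.  The auto range excludes
    the largest-scale octave and any point whose statistic is zero (its
    log is undefined).  Returns (slope, intercept, r_squared, (i0, i1)).

    Raises
    ------
    FitError
        Fewer than 4 usable points, or duplicated x values.
    """
    pts = list(points)
    if fit_range == "auto":
        usable = [i for i, (lx, ly) in enumerate(pts) if np.isfinite(ly)]
        if not usable:
            raise FitError("no usable points (all statistics zero)")
        log_scales = [pts[i][0] for i in usable]
        top = max(log_scales)
        cut = top - np.log(2.0) + 1e-12
        keep = [i for i in usable if pts[i][0] < cut]
        if len(keep) < 4:  # tiny ladders: keep everything usable
            keep = usable
        i0, i1 = min(keep), max(keep) + 1
        idx = [i for i in range(i0, i1) if i in set(keep)]
    else:
        i0, i1 = fit_range  # type: ignore[misc]
        if i0 < 0 or i1 > len(pts) or i1 - i0 < 4:
            raise FitError(f"explicit fit range ({i0}, {i1}) out of bounds or too short")
        idx = [i for i in range(i0, i1) if np.isfinite(pts[i][1])]
    if len(idx) < 4:
        raise FitError(f"only {len(idx)} usable points in fit range; need >= 4")
    x = np.array([pts[i][0] for i in idx])
    y = np.array([pts[i][1] for i in idx])
    if np.ptp(x) == 0 or len(np.unique(x)) < len(x):
        raise FitError("duplicated scale values make the fit degenerate")
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), r2, (min(idx), max(idx) + 1)


def bspline_resample(map: HeightMap, factor: int = 1) -> HeightMap:
    """Resample a height field on a ``factor``-times finer grid with cubic
    B-splines.  ``factor=1`` returns the input unchanged; planes are
    reproduced exactly (splines are exact on polynomials up to degree 3).
    """
    if factor < 1:
        raise ParameterError(f"factor must be >= 1, got {factor}")
    if factor == 1:
        return map
    fine = zoom(map.heights, factor, order=3, grid_mode=True, mode="nearest")
    out = HeightMap(
        fine,
        map.pixel_size_x / factor,
        map.pixel_size_y / factor,
        label=map.label,
        meta=dict(map.meta),
    )
    return out


def _dyadic_scales(n: int) -> list[int]:
    """Scale ladder l = 2^k px from 2 up to n / 4."""
    scales = []
    l = 2
    while l <= n // 4:
        scales.append(l)
        l *= 2
    return scales


def _normalize_heights(z: np.ndarray, factor: float = 1.0) -> np.ndarray:
    """Rescale heights so the full range spans ``factor`` times the
    lateral extent in px.

    Makes cube counting and triangulation unit-free: their statistics
    then depend only on the surface's shape, not on the nm-per-px aspect.
    Cube counting uses ``factor=8`` so that even the largest counting
    boxes stay well below the vertical span of their cell and the count
    never saturates at one box per column.
    """
    rng = np.ptp(z)
    if rng == 0:
        return np.zeros_like(z)
    return (z - z.min()) * (factor * max(z.shape) / rng)


def _points_cube_counting(z: np.ndarray) -> list[tuple[float, float]]:
    zn = _normalize_heights(z, factor=8.0)
    n = min(z.shape)
    pts = []
    for l in _dyadic_scales(n):
        ny, nx = z.shape[0] // l, z.shape[1] // l
        blocks = zn[: ny * l, : nx * l].reshape(ny, l, nx, l)
        zmax = blocks.max(axis=(1, 3))
        zmin = blocks.min(axis=(1, 3))
        counts = np.floor(zmax / l) - np.floor(zmin / l) + 1
        pts.append((np.log(l), np.log(float(counts.sum()))))
    return pts


def _points_triangulation(z: np.ndarray) -> list[tuple[float, float]]:
    zn = _normalize_heights(z)
    n = min(z.shape)
    pts = []
    for l in _dyadic_scales(n):
        sub = zn[::l, ::l]
        if sub.shape[0] < 2 or sub.shape[1] < 2:
            break
        a = sub[:-1, :-1]
        b = sub[:-1, 1:]
        c = sub[1:, :-1]
        d = sub[1:, 1:]
        # two triangles per cell: (a, b, c) and (b, d, c); lateral step l px
        # cross-product area for triangle with corners at grid spacing l
        area1 = 0.5 * np.sqrt((l * (a - b)) ** 2 + (l * (a - c)) ** 2 + l**4)
        area2 = 0.5 * np.sqrt((l * (d - b)) ** 2 + (l * (d - c)) ** 2 + l**4)
        total = float((area1 + area2).sum())
        # normalize by covered lateral area so truncation at non-multiples
        # of l does not bend the curve
        covered = (sub.shape[0] - 1) * (sub.shape[1] - 1) * l * l
        pts.append((np.log(l), np.log(total / covered * (z.shape[0] * z.shape[1]))))
    return pts


def _points_variance(z: np.ndarray) -> list[tuple[float, float]]:
    n = min(z.shape)
    pts = []
    for l in _dyadic_scales(n):
        ny, nx = z.shape[0] // l, z.shape[1] // l
        blocks = z[: ny * l, : nx * l].reshape(ny, l, nx, l)
        var = blocks.var(axis=(1, 3)).mean()
        pts.append((np.log(l), np.log(var) if var > 0 else -np.inf))
    return pts


def _points_power_spectrum(z: np.ndarray, pixel_size: float) -> list[tuple[float, float]]:
    n = z.shape[1]
    m = z.shape[0]
    # row-wise periodograms along both axes, averaged
    fr = np.fft.rfft(z, axis=1)
    p_rows = (np.abs(fr) ** 2).mean(axis=0) / n
    fc = np.fft.rfft(z.T, axis=1)
    p_cols = (np.abs(fc) ** 2).mean(axis=0) / m
    k = min(len(p_rows), len(p_cols))
    power = 0.5 * (p_rows[:k] + p_cols[:k])
    freqs = np.arange(k) / (n * pixel_size)
    pts = []
    for f, p in zip(freqs[1:], power[1:]):
        pts.append((np.log(1.0 / f), np.log(p) if p > 0 else -np.inf))
    # order by increasing scale (decreasing frequency)
    return pts[::-1]


def _points_structure_function(z: np.ndarray) -> list[tuple[float, float]]:
    n = min(z.shape)
    pts = []
    for tau in _dyadic_scales(n):
        dx = z[:, tau:] - z[:, :-tau]
        dy = z[tau:, :] - z[:-tau, :]
        s = 0.5 * (np.mean(dx**2) + np.mean(dy**2))
        pts.append((np.log(tau), np.log(s) if s > 0 else -np.inf))
    return pts


def _points_variation(z: np.ndarray) -> list[tuple[float, float]]:
    n = min(z.shape)
    scales = _dyadic_scales(n)
    if len(scales) >= 6:
        # the eps = 2 px window sees too few samples for a reliable
        # oscillation estimate; drop it when the ladder is long enough
        scales = scales[1:]
    pts = []
    for eps in scales:
        size = 2 * eps + 1
        osc = maximum_filter(z, size=size, mode="nearest") - minimum_filter(
            z, size=size, mode="nearest"
        )
        v = float(osc.mean())
        pts.append((np.log(eps), np.log(v) if v > 0 else -np.inf))
    return pts


# Slopes are fitted against log(scale); for the power spectrum the scale
# is 1/f, so its vs-frequency slope -(1+2H) appears here as +(1+2H) and
# the textbook mapping D = (7 + slope_f)/2 becomes (7 - slope)/2.
_SLOPE_TO_D = {
    "cube_counting": lambda s: -s,
    "triangulation": lambda s: 2.0 - s,
    "variance": lambda s: 3.0 - s / 2.0,
    "power_spectrum": lambda s: (7.0 - s) / 2.0,
    "structure_function": lambda s: 3.0 - s / 2.0,
    "variation": lambda s: 3.0 - s,
}


def fractal_dimension(
    map: HeightMap,
    method: str,
    config: FitConfig | None = None,
) -> FractalEstimate:
    """Estimate the fractal dimension of a height map by one method.

    Requires square pixels and a side length of at least 16 px.  A
    zero-variance (flat) surface is analytically D = 2 for cube counting,
    triangulation and variation, and raises
    :class:`DegenerateSurfaceError` for variance, structure function and
    power spectrum, whose statistics vanish identically.

    An estimate outside [2, 3] sets ``out_of_range`` — a warning, never a
    silent clamp: the power-spectrum method in particular can produce
    D < 2 on non-fractal inputs, which is diagnostic in itself.
    """
    if method not in METHODS:
        raise ParameterError(f"unknown method {method!r}; choose from {METHODS}")
    config = config or FitConfig()
    ps = map.require_square_pixels()
    if min(map.heights.shape) < 16:
        raise ParameterError("map side must be >= 16 px for fractal estimation")
    if config.bspline_factor > 1:
        map = bspline_resample(map, config.bspline_factor)
        ps = map.pixel_size_x
    z = map.heights
    if np.ptp(z) == 0 or _is_plane(z):
        if method in ("cube_counting", "triangulation", "variation"):
            return FractalEstimate(
                method=method,
                d_f=2.0,
                slope={"cube_counting": -2.0, "triangulation": 0.0, "variation": 1.0}[
                    method
                ],
                intercept=0.0,
                r_squared=1.0,
                points=[],
                fit_range=(0, 0),
                degenerate=True,
                warnings=["flat surface: D = 2 analytically"],
            )
        if np.ptp(z) == 0:
            raise DegenerateSurfaceError(
                f"{method} undefined on a zero-variance surface (log of zero)"
            )

    if method == "cube_counting":
        pts = _points_cube_counting(z)
    elif method == "triangulation":
        pts = _points_triangulation(z)
    elif method == "variance":
        pts = _points_variance(z)
    elif method == "power_spectrum":
        pts = _points_power_spectrum(z, ps)
    elif method == "structure_function":
        pts = _points_structure_function(z)
    else:
        pts = _points_variation(z)

    fit_range = config.fit_range
    if method == "cube_counting" and fit_range == "auto":
        # Range statistics over sampled blocks are biased at the smallest
        # scales (a handful of samples underestimates the within-block
        # oscillation), so the auto range keeps the top of the ladder and
        # instead drops scales below 16 px, relaxing downward only when
        # fewer than 4 points would remain.
        l_min = 16.0
        while l_min > 2.0:
            kept = [p for p in pts if np.exp(p[0]) >= l_min - 1e-9 and np.isfinite(p[1])]
            if len(kept) >= 4:
                break
            l_min /= 2.0
        kept = [p for p in pts if np.exp(p[0]) >= l_min - 1e-9 and np.isfinite(p[1])]
        if len(kept) >= 4:
            pts_fit = kept
        else:
            pts_fit = pts
        slope, intercept, r2, _ = fit_loglog(pts_fit, (0, len(pts_fit)))
        first = pts.index(pts_fit[0])
        used = (first, first + len(pts_fit))
        d = float(_SLOPE_TO_D[method](slope))
        out = not (2.0 <= d <= 3.0)
        warnings = (
            [f"D_f = {d:.3f} outside [2, 3]; the {method} estimate is kept unclamped"]
            if out
            else []
        )
        return FractalEstimate(
            method=method,
            d_f=d,
            slope=slope,
            intercept=intercept,
            r_squared=r2,
            points=pts,
            fit_range=used,
            out_of_range=out,
            warnings=warnings,
        )
    if method == "power_spectrum" and fit_range == "auto" and config.psd_trim_high_octave:
        # drop the smallest-scale (near-Nyquist) octave as well: grid
        # anisotropy bends the 1D periodogram there
        scales = np.array([p[0] for p in pts])
        lo = scales.min()
        keep = [(lx, ly) for lx, ly in pts if lx > lo + np.log(2.0) - 1e-12]
        if len([p for p in keep if np.isfinite(p[1])]) >= 8:
            pts = keep

    slope, intercept, r2, used = fit_loglog(pts, fit_range)
    d = float(_SLOPE_TO_D[method](slope))
    warnings = []
    out = not (2.0 <= d <= 3.0)
    if out:
        warnings.append(
            f"D_f = {d:.3f} outside [2, 3]; the {method} estimate is kept "
            "unclamped (diagnostic for non-fractal input)"
        )
    return FractalEstimate(
        method=method,
        d_f=d,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        points=pts,
        fit_range=used,
        out_of_range=out,
        warnings=warnings,
    )


def _plane_fit(z: np.ndarray) -> np.ndarray:
    """Least-squares plane through the height field (mean removed)."""
    ny, nx = z.shape
    y, x = np.mgrid[0:ny, 0:nx]
    x = x - x.mean()
    y = y - y.mean()
    gx = float((z * x).sum() / (x**2).sum())
    gy = float((z * y).sum() / (y**2).sum())
    return gx * x + gy * y


def _is_plane(z: np.ndarray) -> bool:
    resid = z - z.mean() - _plane_fit(z)
    return float(np.abs(resid).max()) <= 1e-9 * max(float(np.ptp(z)), 1.0)


def fractal_suite(
    map: HeightMap,
    methods: Sequence[str] = METHODS,
    config: FitConfig | None = None,
) -> dict[str, FractalEstimate]:
    """Run several estimators on one map; degenerate-surface errors are
    recorded as estimates with ``degenerate=True`` and ``d_f=nan``."""
    out: dict[str, FractalEstimate] = {}
    for m in methods:
        try:
            out[m] = fractal_dimension(map, m, config)
        except DegenerateSurfaceError as e:
            out[m] = FractalEstimate(
                method=m,
                d_f=float("nan"),
                slope=float("nan"),
                intercept=float("nan"),
                r_squared=float("nan"),
                points=[],
                fit_range=(0, 0),
                degenerate=True,
                warnings=[str(e)],
            )
    return out
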