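"""AFM tip modelling and morphological image correction.

An AFM image is, to first order, the grayscale morphological dilation of
the true surface by the tip shape: at every lateral position the recorded
height is set by the lowest point of the tip that touches the sample.
Erosion of the image by the reflected tip yields an upper-bound
reconstruction of the true surface, together with a certainty map marking
pixels where the reconstruction is exact (the tip apex was the unique
touching point).

The tip model is the upper envelope of a spherical apex cap and a
four-sided pyramid: heights are <= 0 with the apex pinned at 0 in the
center pixel, the convention used throughout this package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from nanotex.errors import CalibrationError, GeometryError, ParameterError
from nanotex.surface_io import HeightMap


@dataclass
class TipModel:
    """A sampled AFM tip.

    ``sampled`` is an odd-sided grid of tip surface heights in nm, apex at
    the center pixel with value 0, the body negative going outward, at the
    pixel pitch of the maps it will be applied to.
    """

    shape: str
    apex_radius: float
    rotation_deg: float
    half_angle_deg: float
    pixel_size: float
    sampled: np.ndarray

    @property
    def extent_px(self) -> int:
        return self.sampled.shape[0]


def _pyramid_depth(x: np.ndarray, y: np.ndarray, rotation_deg: float,
                   half_angle_deg: float) -> np.ndarray:
    """Depth (<= 0) of a 4-sided pyramid with apex at the origin.

    The half-angle is measured between a facet and the tip axis, so a
    facet drops by ``d / tan(half_angle)`` at distance d along its
    outward normal.
    """
    tan_a = np.tan(np.radians(half_angle_deg))
    depth = np.full(np.broadcast(x, y).shape, -np.inf)
    for k in range(4):
        phi = np.radians(rotation_deg + 90.0 * k)
        d = x * np.cos(phi) + y * np.sin(phi)
        depth = np.maximum(depth, d)  # distance along each facet normal
    return -np.maximum(depth, 0.0) / tan_a


def tip_envelope(x: np.ndarray, y: np.ndarray, apex_radius: float,
                 rotation_deg: float, half_angle_deg: float) -> np.ndarray:
    """Closed-form tip surface height (<= 0) at lateral offsets (x, y).

    Upper envelope of the apex sphere (radius ``apex_radius``, tangent to
    0 at the origin) and the rotated pyramid.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    rho2 = x**2 + y**2
    with np.errstate(invalid="ignore"):
        sphere = -apex_radius + np.sqrt(np.maximum(apex_radius**2 - rho2, 0.0))
    sphere = np.where(rho2 <= apex_radius**2, sphere, -np.inf)
    pyramid = _pyramid_depth(x, y, rotation_deg, half_angle_deg)
    return np.maximum(sphere, pyramid)


def build_tip(
    apex_radius: float = 12.0,
    rotation_deg: float = 45.0,
    half_angle_deg: float = 17.5,
    pixel_size: float = 2000.0 / 512,
    extent_px: int = 15,
) -> TipModel:
    """Sample a pyramidal tip with a spherical apex on a pixel grid.

    Defaults model the contact-mode reconstruction tip used for carotid
    scan correction: 12 nm apex radius, pyramid rotated by 45 degrees.
    The sidewall half-angle is configurable (17.5 degrees by default,
    typical for silicon tapping probes).

    Raises
    ------
    GeometryError
        If ``extent_px`` cannot contain the spherical apex cap (the
        sphere-to-pyramid transition circle must fit inside the grid).
    """
    if extent_px < 3 or extent_px % 2 == 0:
        raise ParameterError(f"extent_px must be odd and >= 3, got {extent_px}")
    if pixel_size <= 0:
        raise ParameterError(f"pixel_size must be > 0, got {pixel_size}")
    if apex_radius <= 0:
        raise ParameterError(f"apex_radius must be > 0, got {apex_radius}")
    if not (0 < half_angle_deg < 90):
        raise ParameterError(
            f"half_angle_deg must be in (0, 90), got {half_angle_deg}"
        )
    half = extent_px // 2
    # lateral radius of the sphere/pyramid tangency circle
    transition = apex_radius * np.cos(np.radians(half_angle_deg))
    if half * pixel_size < transition:
        raise GeometryError(
            f"extent {extent_px} px at {pixel_size:.3g} nm/px cannot contain "
            f"the {apex_radius} nm apex cap (needs >= {transition:.3g} nm "
            "half-extent)"
        )
    coords = (np.arange(extent_px) - half) * pixel_size
    x = coords[None, :]
    y = coords[:, None]
    sampled = tip_envelope(x, y, apex_radius, rotation_deg, half_angle_deg)
    sampled[half, half] = 0.0
    return TipModel(
        shape="pyramid",
        apex_radius=apex_radius,
        rotation_deg=rotation_deg,
        half_angle_deg=half_angle_deg,
        pixel_size=pixel_size,
        sampled=sampled,
    )


def _check_calibration(map: HeightMap, tip: TipModel) -> None:
    ps = map.require_square_pixels()
    if abs(ps - tip.pixel_size) > 1e-6 * ps:
        raise CalibrationError(
            f"tip sampled at {tip.pixel_size} nm/px but map has {ps} nm/px"
        )


def _shifted_view(padded: np.ndarray, dy: int, dx: int, shape: tuple) -> np.ndarray:
    """View of the edge-padded array shifted by (dy, dx)."""
    half_y = (padded.shape[0] - shape[0]) // 2
    half_x = (padded.shape[1] - shape[1]) // 2
    y0 = half_y + dy
    x0 = half_x + dx
    return padded[y0 : y0 + shape[0], x0 : x0 + shape[1]]


def dilate_surface(true_surface: HeightMap, tip: TipModel) -> HeightMap:
    """Forward imaging model: grayscale dilation of the surface by the tip.

    ``out(x) = max_u [ surface(x - u) + tip(u) ]`` over the tip support,
    with edge replication at the borders.  Dilation is monotone: raising
    any input pixel never lowers any output pixel.
    """
    _check_calibration(true_surface, tip)
    z = true_surface.heights
    half = tip.extent_px // 2
    padded = np.pad(z, half, mode="edge")
    out = np.full_like(z, -np.inf)
    for uy in range(-half, half + 1):
        for ux in range(-half, half + 1):
            t = tip.sampled[uy + half, ux + half]
            if not np.isfinite(t):
                continue
            np.maximum(out, _shifted_view(padded, -uy, -ux, z.shape) + t, out=out)
    return true_surface.copy_with(out, label=true_surface.label + " [dilated]")


def reconstruct_surface(
    image: HeightMap, tip: TipModel, tol: float = 1e-9
) -> tuple[HeightMap, np.ndarray]:
    """Erosion by the reflected tip: upper-bound surface reconstruction.

    ``rec(x) = min_u [ image(x + u) - tip(u) ]``.  When the image is the
    dilation of a true surface by the same tip, ``rec >= true`` pointwise
    and equality holds wherever the certainty map is True — the standard
    criterion marking surface pixels that were the unique tip-sample
    contact point for some image pixel.

    Returns
    -------
    (HeightMap, ndarray of bool)
        The reconstruction and its certainty map.
    """
    _check_calibration(image, tip)
    z = image.heights
    half = tip.extent_px // 2
    padded = np.pad(z, half, mode="edge")
    rec = np.full_like(z, np.inf)
    for uy in range(-half, half + 1):
        for ux in range(-half, half + 1):
            t = tip.sampled[uy + half, ux + half]
            if not np.isfinite(t):
                continue
            np.minimum(rec, _shifted_view(padded, uy, ux, z.shape) - t, out=rec)
    # Certainty: position the tip apex over every image pixel p at height
    # image(p); it touches the reconstruction at
    # {p - w : rec(p - w) + tip(w) = image(p)}  (dilation contributions,
    # which satisfy rec(p - w) + tip(w) <= image(p) everywhere).  The true
    # contact point is always in the touch set, so when the set is a
    # single pixel that reconstructed pixel equals the true surface.
    rec_padded = np.pad(rec, half, mode="edge")
    atol = tol * np.maximum(np.abs(z).max(), 1.0)
    touch_count = np.zeros(z.shape, dtype=np.int32)
    for wy in range(-half, half + 1):
        for wx in range(-half, half + 1):
            t = tip.sampled[wy + half, wx + half]
            if not np.isfinite(t):
                continue
            val = _shifted_view(rec_padded, -wy, -wx, z.shape) + t
            touch_count += np.abs(val - z) <= atol
    unique = touch_count == 1
    cert_padded = np.zeros((z.shape[0] + 2 * half, z.shape[1] + 2 * half), dtype=bool)
    for wy in range(-half, half + 1):
        for wx in range(-half, half + 1):
            t = tip.sampled[wy + half, wx + half]
            if not np.isfinite(t):
                continue
            val = _shifted_view(rec_padded, -wy, -wx, z.shape) + t
            sel = (np.abs(val - z) <= atol) & unique
            if sel.any():
                ys, xs = np.nonzero(sel)
                cert_padded[ys - wy + half, xs - wx + half] = True
    certainty = cert_padded[half:-half, half:-half]
    return (
        image.copy_with(rec, label=image.label + " [reconstructed]"),
        certainty,
    )
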