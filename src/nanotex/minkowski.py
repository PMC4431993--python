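"""Discrete 2D Minkowski functionals over a sweeping height threshold.

At each threshold z the map is binarized into white (height >= z, the
"rough" phase) and black pixels, and three morphological measures are
recorded:

* volume ``V`` — white-pixel fraction, monotonically non-increasing from
  1 (at Z_min) to 0 (above Z_max);
* boundary ``S`` — 4-neighbor white/black pixel pairs per pixel, zero at
  both extremes and maximal at intermediate thresholds;
* connectivity ``chi`` — the Euler-Poincare characteristic per pixel,
  (number of 8-connected white components minus number of 4-connected
  black components) / N.  chi is negative when many disconnected flat
  (black) regions dominate, positive when disconnected rough (white)
  islands dominate, and near zero for highly connected structure.

The 8/4 connectivity pairing for white/black avoids the digital-topology
paradox (a diagonal white line must not simultaneously connect itself and
disconnect the background).  Components touching the image border are
counted as components; chi and S are reported per pixel so curves from
different scan sizes are comparable, with raw counts also stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from nanotex.errors import ParameterError
from nanotex.surface_io import HeightMap

_STRUCT8 = np.ones((3, 3), dtype=int)
_STRUCT4 = ndimage.generate_binary_structure(2, 1)


def binary_functionals(white: np.ndarray) -> tuple[float, int, int, int]:
    """(V, boundary pair count, white components, black components) of a
    binary image; white uses 8-connectivity, black 4-connectivity."""
    white = np.asarray(white, dtype=bool)
    v = float(white.mean())
    horiz = int((white[:, 1:] != white[:, :-1]).sum())
    vert = int((white[1:, :] != white[:-1, :]).sum())
    _, c_white = ndimage.label(white, structure=_STRUCT8)
    _, c_black = ndimage.label(~white, structure=_STRUCT4)
    return v, horiz + vert, c_white, c_black


@dataclass
class MinkowskiCurves:
    """Threshold-swept functionals of one height map.

    ``V``, ``S`` and ``chi`` are per-pixel densities; ``boundary_count``,
    ``white_components`` and ``black_components`` keep the raw counts.
    """

    thresholds: np.ndarray
    V: np.ndarray
    S: np.ndarray
    chi: np.ndarray
    boundary_count: np.ndarray
    white_components: np.ndarray
    black_components: np.ndarray
    n_pixels: int

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "z_nm": self.thresholds,
                "V": self.V,
                "S": self.S,
                "chi": self.chi,
            }
        )


def minkowski_curves(map: HeightMap, n_thresholds: int = 256) -> MinkowskiCurves:
    """Sweep ``n_thresholds`` evenly spaced thresholds over [Z_min, Z_max]
    (both endpoints included) and record V, S and chi at each.

    White is ``height >= z``, which pins V(Z_min) = 1 exactly and V = 0
    for any threshold above Z_max.  A phase covering the whole image is
    conventionally structureless, so chi is exactly 0 at both sweep
    extremes.  A constant surface yields the documented degenerate
    output: V = 1 at every threshold of its single-point range with
    S = chi = 0 throughout.
    """
    if n_thresholds < 3:
        raise ParameterError(f"n_thresholds must be >= 3, got {n_thresholds}")
    map.require_square_pixels()
    z = map.heights
    zmin, zmax = float(z.min()), float(z.max())
    thresholds = np.linspace(zmin, zmax, n_thresholds)
    n = z.size
    V = np.empty(n_thresholds)
    bc = np.empty(n_thresholds, dtype=int)
    cw = np.empty(n_thresholds, dtype=int)
    cb = np.empty(n_thresholds, dtype=int)
    for i, t in enumerate(thresholds):
        v, pairs, c_white, c_black = binary_functionals(z >= t)
        V[i] = v
        bc[i] = pairs
        cw[i] = c_white
        cb[i] = c_black
    chi = (cw - cb) / n
    # single all-white / all-black convention: a phase spanning the whole
    # image carries no disconnected structure, so chi is 0 at the sweep
    # extremes rather than +-1/N
    chi[(V == 1.0) | (V == 0.0)] = 0.0
    return MinkowskiCurves(
        thresholds=thresholds,
        V=V,
        S=bc / n,
        chi=chi,
        boundary_count=bc,
        white_components=cw,
        black_components=cb,
        n_pixels=n,
    )


@dataclass
class ConnectivityLandmarks:
    """Characteristic thresholds extracted from Minkowski curves."""

    z_min_chi: Optional[float]
    z_max_chi: Optional[float]
    z_max_S: Optional[float]
    z_half_volume: Optional[float]
    z_chi_vanishing: Optional[float]
    plateaus: list[tuple[float, float]] = field(default_factory=list)
    defined: bool = True

    def as_dict(self) -> dict:
        return {
            "z_min_chi_nm": self.z_min_chi,
            "z_max_chi_nm": self.z_max_chi,
            "z_max_S_nm": self.z_max_S,
            "z_half_volume_nm": self.z_half_volume,
            "z_chi_vanishing_nm": self.z_chi_vanishing,
            "plateaus": [list(p) for p in self.plateaus],
            "defined": self.defined,
        }


def _v_half_crossing(thresholds: np.ndarray, V: np.ndarray) -> Optional[float]:
    """Linear interpolation of the first V <= 0.5 crossing."""
    above = V > 0.5
    if above.all() or not (~above).any():
        return None
    i = int(np.nonzero(~above)[0][0])
    if i == 0:
        return float(thresholds[0])
    z0, z1 = thresholds[i - 1], thresholds[i]
    v0, v1 = V[i - 1], V[i]
    if v0 == v1:
        return float(z0)
    return float(z0 + (v0 - 0.5) / (v0 - v1) * (z1 - z0))


def connectivity_landmarks(
    curves: MinkowskiCurves,
    chi_tolerance: float | None = None,
    plateau_min_len: int = 5,
) -> ConnectivityLandmarks:
    """Extract the characteristic thresholds of the chi, S and V curves.

    Returns the thresholds of the global chi minimum and maximum, the S
    maximum, the interpolated V = 0.5 crossing, and the vanishing
    threshold — the first z after the chi maximum where |chi| drops below
    ``chi_tolerance`` (default 1/N, i.e. less than one net component).
    Plateau runs of chi (maximal stretches whose deviation from the run
    mean stays within tolerance) are reported as (start_z, length_z)
    pairs.  When chi is identically zero the chi landmarks are undefined
    and ``defined`` is False.
    """
    t = curves.thresholds
    chi = curves.chi
    tol = chi_tolerance if chi_tolerance is not None else 1.0 / curves.n_pixels
    z_half = _v_half_crossing(t, curves.V)
    z_max_S = float(t[int(np.argmax(curves.S))]) if curves.S.any() else None
    if not np.any(np.abs(chi) > 0):
        return ConnectivityLandmarks(
            z_min_chi=None,
            z_max_chi=None,
            z_max_S=z_max_S,
            z_half_volume=z_half,
            z_chi_vanishing=None,
            defined=False,
        )
    i_min = int(np.argmin(chi))
    i_max = int(np.argmax(chi))
    z_vanish = None
    for i in range(i_max + 1, len(t)):
        if abs(chi[i]) <= tol:
            z_vanish = float(t[i])
            break
    plateaus: list[tuple[float, float]] = []
    start = 0
    for i in range(1, len(t) + 1):
        run = chi[start:i]
        if i < len(t) and np.all(np.abs(chi[start : i + 1] - np.mean(chi[start : i + 1])) <= tol):
            continue
        if i - start >= plateau_min_len:
            plateaus.append((float(t[start]), float(t[i - 1] - t[start])))
        start = i
    return ConnectivityLandmarks(
        z_min_chi=float(t[i_min]),
        z_max_chi=float(t[i_max]),
        z_max_S=z_max_S,
        z_half_volume=z_half,
        z_chi_vanishing=z_vanish,
        plateaus=plateaus,
    )


def volume_symmetry_score(curves: MinkowskiCurves) -> float:
    """Point-symmetry of the volume curve about its V = 0.5 crossing.

    ``score = 1 - mean_delta |V(z_half + delta) + V(z_half - delta) - 1|``
    over offsets delta spanning the wider half of the threshold range,
    with V extended by 1 below Z_min and 0 above Z_max.  A perfectly
    point-symmetric curve (e.g. a Gaussian surface) scores 1; deposition
    that skews the height distribution toward high outliers pushes the
    score down.
    """
    t = curves.thresholds
    V = curves.V
    z_half = _v_half_crossing(t, V)
    if z_half is None:
        return 0.0
    half_width = max(z_half - t[0], t[-1] - z_half)
    if half_width <= 0:
        return 1.0
    deltas = np.linspace(0.0, half_width, 512)
    v_plus = np.interp(z_half + deltas, t, V, left=1.0, right=0.0)
    v_minus = np.interp(z_half - deltas, t, V, left=1.0, right=0.0)
    asym = float(np.mean(np.abs(v_plus + v_minus - 1.0)))
    return 1.0 - asym
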