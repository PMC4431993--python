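"""Height-map container and readers/writers for generic AFM exports.

The :class:`HeightMap` is the universal input of every analysis module: a
regular 2D grid of surface heights in nanometres with a physical pixel
pitch.  Row 0 is the top of the image and z is positive away from the
substrate.  Three interchange formats are supported: whitespace-separated
ASCII matrices with ``#`` headers, XYZ triplet text, and single-channel
32-bit float TIFF.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from nanotex.errors import (
    CalibrationError,
    GridError,
    ParseError,
    ShapeError,
    ValidationError,
)

_HEADER_KEYS = ("width_nm", "height_nm", "label")


@dataclass
class HeightMap:
    """A calibrated 2D grid of surface heights.

    Parameters
    ----------
    heights : ndarray, shape (rows, cols)
        Surface heights in nm.  Row 0 is the top of the image.
    pixel_size_x, pixel_size_y : float
        Physical pixel pitch in nm/px along columns and rows.
    label : str
        Free-text sample name.
    meta : dict
        Optional string metadata (scan size, instrument, ...).
    """

    heights: np.ndarray
    pixel_size_x: float
    pixel_size_y: float
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=np.float64)
        if self.heights.ndim != 2:
            raise ValidationError(f"heights must be 2D, got ndim={self.heights.ndim}")
        rows, cols = self.heights.shape
        if rows < 2 or cols < 2:
            raise ValidationError(f"grid must be at least 2x2, got {rows}x{cols}")
        bad = ~np.isfinite(self.heights)
        if bad.any():
            raise ValidationError(f"{int(bad.sum())} non-finite height value(s)")
        if not (self.pixel_size_x > 0 and self.pixel_size_y > 0):
            raise ValidationError(
                f"pixel sizes must be positive, got "
                f"({self.pixel_size_x}, {self.pixel_size_y})"
            )

    @property
    def rows(self) -> int:
        return self.heights.shape[0]

    @property
    def cols(self) -> int:
        return self.heights.shape[1]

    @property
    def extent_nm(self) -> tuple[float, float]:
        """Physical scan extent (width, height) in nm."""
        return (self.cols * self.pixel_size_x, self.rows * self.pixel_size_y)

    @property
    def n_points(self) -> int:
        return self.heights.size

    def require_square_pixels(self, rtol: float = 1e-6) -> float:
        """Return the common pixel size, or raise for anisotropic sampling.

        Fractal and Minkowski estimators assume isotropic sampling.
        """
        if abs(self.pixel_size_x - self.pixel_size_y) > rtol * self.pixel_size_x:
            raise CalibrationError(
                f"operation requires square pixels; got "
                f"{self.pixel_size_x} x {self.pixel_size_y} nm/px"
            )
        return self.pixel_size_x

    def copy_with(self, heights: np.ndarray, label: str | None = None) -> "HeightMap":
        """A new map with the same calibration and different heights."""
        return HeightMap(
            heights=np.asarray(heights, dtype=np.float64),
            pixel_size_x=self.pixel_size_x,
            pixel_size_y=self.pixel_size_y,
            label=self.label if label is None else label,
            meta=dict(self.meta),
        )


def _parse_ascii(path: Path, pixel_size: float | None) -> HeightMap:
    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    with open(path, "r") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].strip().split(None, 1)
                if len(parts) == 2 and parts[0] in _HEADER_KEYS:
                    meta[parts[0]] = parts[1]
                elif len(parts) == 2:
                    meta[parts[0]] = parts[1]
                continue
            vals = []
            for col, tok in enumerate(line.split()):
                try:
                    vals.append(float(tok))
                except ValueError:
                    raise ParseError(
                        f"{path}: malformed numeric cell at line {lineno}, "
                        f"column {col + 1}: {tok!r}"
                    ) from None
            rows.append(vals)
    if not rows:
        raise ParseError(f"{path}: no data rows")
    ncols = len(rows[0])
    for i, r in enumerate(rows):
        if len(r) != ncols:
            raise ShapeError(
                f"{path}: ragged rows — row {i + 1} has {len(r)} values, "
                f"expected {ncols}"
            )
    heights = np.array(rows, dtype=np.float64)
    psx = psy = pixel_size
    if "width_nm" in meta:
        psx = float(meta["width_nm"]) / heights.shape[1]
    if "height_nm" in meta:
        psy = float(meta["height_nm"]) / heights.shape[0]
    if psx is None or psy is None:
        raise CalibrationError(
            f"{path}: no pixel size in header; pass pixel_size explicitly"
        )
    return HeightMap(heights, psx, psy, label=meta.get("label", ""), meta=meta)


def _parse_xyz(path: Path, pixel_size: float | None) -> HeightMap:
    pts = []
    with open(path, "r") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            toks = line.split()
            if len(toks) != 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected 3 columns, got {len(toks)}"
                )
            try:
                pts.append([float(t) for t in toks])
            except ValueError:
                raise ParseError(
                    f"{path}: malformed numeric value at line {lineno}"
                ) from None
    if not pts:
        raise ParseError(f"{path}: no data points")
    arr = np.array(pts, dtype=np.float64)
    xs = np.unique(arr[:, 0])
    ys = np.unique(arr[:, 1])
    nx, ny = len(xs), len(ys)
    if nx < 2 or ny < 2 or nx * ny != len(arr):
        raise GridError(
            f"{path}: {len(arr)} points do not fill a {nx}x{ny} regular grid"
        )
    for axis, name in ((xs, "x"), (ys, "y")):
        steps = np.diff(axis)
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise GridError(f"{path}: non-uniform {name} spacing")
    psx = float(xs[1] - xs[0])
    psy = float(ys[1] - ys[0])
    grid = np.full((ny, nx), np.nan)
    ix = np.searchsorted(xs, arr[:, 0])
    iy = np.searchsorted(ys, arr[:, 1])
    grid[iy, ix] = arr[:, 2]
    if np.isnan(grid).any():
        raise GridError(f"{path}: duplicate points leave grid cells unfilled")
    return HeightMap(grid, psx, psy)


def _parse_tiff(path: Path, pixel_size: float | None) -> HeightMap:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        heights = page.asarray().astype(np.float64)
        label = ""
        psx = psy = pixel_size
        desc = page.tags.get("ImageDescription")
        if desc is not None:
            try:
                d = json.loads(desc.value)
                psx = float(d.get("pixel_size_x_nm", psx))
                psy = float(d.get("pixel_size_y_nm", psy))
                label = d.get("label", "")
            except (ValueError, TypeError):
                pass
    if psx is None or psy is None:
        raise CalibrationError(
            f"{path}: TIFF carries no calibration; pass pixel_size explicitly"
        )
    if heights.ndim != 2:
        raise ShapeError(f"{path}: expected single-channel image, got {heights.shape}")
    bad = ~np.isfinite(heights)
    if bad.any():
        raise ValidationError(f"{path}: {int(bad.sum())} non-finite height value(s)")
    return HeightMap(heights, psx, psy, label=label)


def read_heightmap(
    path: str | Path,
    format: str = "auto",
    pixel_size: float | None = None,
) -> HeightMap:
    """Read a height map from ASCII matrix, XYZ text, or 32-bit float TIFF.

    Parameters
    ----------
    path : path
        Input file.
    format : {'ascii_matrix', 'xyz', 'tiff32', 'auto'}
        ``auto`` chooses by extension (.tif/.tiff -> tiff32, .xyz -> xyz,
        otherwise ascii_matrix).
    pixel_size : float, optional
        Pixel pitch in nm/px, required for files without embedded
        calibration.  Applied to both axes.

    Returns
    -------
    HeightMap
        Validated map; loading rejects any non-finite value.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        suffix = path.suffix.lower()
        if suffix in (".tif", ".tiff"):
            format = "tiff32"
        elif suffix == ".xyz":
            format = "xyz"
        else:
            format = "ascii_matrix"
    if format == "ascii_matrix":
        return _parse_ascii(path, pixel_size)
    if format == "xyz":
        return _parse_xyz(path, pixel_size)
    if format == "tiff32":
        return _parse_tiff(path, pixel_size)
    raise ValueError(f"unknown format {format!r}")


def write_heightmap(map: HeightMap, path: str | Path, format: str = "auto") -> None:
    """Write a height map as ASCII matrix or 32-bit float TIFF.

    The ASCII dialect emits ``#``-prefixed ``width_nm``, ``height_nm`` and
    ``label`` header lines followed by whitespace-separated rows; values
    are printed with 10 significant digits (round-trip error below 1e-6 nm
    for heights in the AFM range).  TIFF stores float32 samples with the
    calibration in a JSON image description, so a float32-valued map
    round-trips bit-exactly.
    """
    path = Path(path)
    if format == "auto":
        format = "tiff32" if path.suffix.lower() in (".tif", ".tiff") else "ascii_matrix"
    if format == "ascii_matrix":
        w, h = map.extent_nm
        lines = [f"# width_nm {w:.10g}", f"# height_nm {h:.10g}"]
        if map.label:
            lines.append(f"# label {map.label}")
        for row in map.heights:
            lines.append(" ".join(f"{v:.10g}" for v in row))
        path.write_text("\n".join(lines) + "\n")
    elif format == "tiff32":
        desc = json.dumps(
            {
                "pixel_size_x_nm": map.pixel_size_x,
                "pixel_size_y_nm": map.pixel_size_y,
                "label": map.label,
            }
        )
        tifffile.imwrite(
            path,
            map.heights.astype(np.float32),
            description=desc,
            photometric="minisblack",
        )
    else:
        raise ValueError(f"unknown format {format!r}")
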