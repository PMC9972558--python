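"""Height-map I/O and rendering.

Height maps travel as a small self-documented ASCII dialect::

    # nx ny
    # dx_nm dy_nm
    # x0_nm y0_nm
    <ny rows of nx tab-separated heights in nm, row 0 = smallest y>

Experimental AFM exports are commonly plain matrices; a headerless matrix
plus an explicit pixel size is accepted too.  Rendering maps heights through
a monotone matplotlib colormap (default ``afmhot``, the conventional
dark-to-bright AFM gradient).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from matplotlib import colormaps
from scipy.interpolate import RegularGridInterpolator

from .scanner import HeightMap, ScanGrid


class HeightMapFormatError(ValueError):
    """Raised for malformed ASCII height-map files."""


@dataclass
class ImageRender:
    """Rendered topography: RGBA pixels in image convention (row 0 = largest y)."""

    pixels: np.ndarray  # (ny, nx, 4) uint8
    colormap: str
    zrange: tuple[float, float]


def write_afm_ascii(hm: HeightMap, path: str | Path) -> None:
    """Write a height map in the package's ASCII dialect (lossless to <1e-6 nm)."""
    g = hm.grid
    header = (
        f"# {g.nx} {g.ny}\n"
        f"# {g.spacing!r} {g.spacing!r}\n"
        f"# {g.x0!r} {g.y0!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for row in hm.heights:
            fh.write("\t".join(f"{v:.9g}" for v in row) + "\n")


def read_afm_ascii(
    path: str | Path,
    *,
    spacing: float | None = None,
    origin: tuple[float, float] = (0.0, 0.0),
    zero_floor: bool = False,
) -> HeightMap:
    """Read a height map written by :func:`write_afm_ascii` or a bare matrix.

    A bare (headerless) matrix requires an explicit ``spacing``.  Negative
    values are permitted (experimental baselines); pass ``zero_floor=True``
    to clip them to 0 on read.  The result is tagged ``source="external"``.
    """
    path = Path(path)
    header: list[str] = []
    data_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.lstrip().startswith("#"):
                header.append(line.lstrip().lstrip("#").strip())
            else:
                data_lines.append(line)
    if not data_lines:
        raise HeightMapFormatError(f"no data rows in {path}")
    rows = [line.split() for line in data_lines]
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise HeightMapFormatError(f"ragged rows in {path}")
    try:
        heights = np.array(rows, dtype=float)
    except ValueError as exc:
        raise HeightMapFormatError(f"non-numeric value in {path}: {exc}") from exc

    if len(header) >= 3:
        try:
            nx, ny = (int(v) for v in header[0].split())
            dx, dy = (float(v) for v in header[1].split())
            x0, y0 = (float(v) for v in header[2].split())
        except ValueError as exc:
            raise HeightMapFormatError(f"bad header in {path}: {exc}") from exc
        if not np.isclose(dx, dy):
            raise HeightMapFormatError("anisotropic pixels are not supported")
        if heights.shape != (ny, nx):
            raise HeightMapFormatError(
                f"header says {ny}x{nx} but found {heights.shape}"
            )
        grid = ScanGrid(x0=x0, y0=y0, spacing=dx, nx=nx, ny=ny)
    else:
        if spacing is None:
            raise HeightMapFormatError(
                "headerless matrix requires an explicit pixel size"
            )
        ny, nx = heights.shape
        grid = ScanGrid(x0=origin[0], y0=origin[1], spacing=spacing, nx=nx, ny=ny)
    if zero_floor:
        np.maximum(heights, 0.0, out=heights)
    return HeightMap(grid, heights, {"source": "external", "path": str(path)})


def resample(hm: HeightMap, target: ScanGrid) -> HeightMap:
    """Bilinearly interpolate a height map onto another grid.

    Target cells outside the source extent become 0.  The grids must overlap.
    """
    sx0, sx1, sy0, sy1 = hm.grid.extent()
    tx0, tx1, ty0, ty1 = target.extent()
    if tx1 < sx0 or tx0 > sx1 or ty1 < sy0 or ty0 > sy1:
        raise ValueError("target grid does not overlap the source grid")
    interp = RegularGridInterpolator(
        (hm.grid.y_centers(), hm.grid.x_centers()),
        hm.heights,
        method="linear",
        bounds_error=False,
        fill_value=0.0,
    )
    yy, xx = np.meshgrid(target.y_centers(), target.x_centers(), indexing="ij")
    heights = interp(np.stack([yy.ravel(), xx.ravel()], axis=1)).reshape(target.shape)
    return HeightMap(target, heights, dict(hm.metadata))


def render(
    hm: HeightMap,
    colormap: str = "afmhot",
    zrange: tuple[float, float] | None = None,
) -> ImageRender:
    """Map heights through a color gradient.

    ``zrange`` defaults to ``(0, max height)`` of this map (an all-flat map
    renders as the uniform lowest color).  An explicit ``zrange`` with
    ``zmax <= zmin`` is an error.
    """
    if zrange is not None:
        zmin, zmax = zrange
        if zmax <= zmin:
            raise ValueError(f"zrange max must exceed min, got {zrange}")
    else:
        zmin, zmax = 0.0, hm.max_height
        if zmax <= zmin:
            zmax = zmin + 1.0  # flat map: any span gives the uniform low color
    cmap = colormaps[colormap]
    normalized = np.clip((hm.heights - zmin) / (zmax - zmin), 0.0, 1.0)
    rgba = cmap(normalized, bytes=True)
    return ImageRender(pixels=rgba[::-1], colormap=colormap, zrange=(zmin, zmax))


def save_png(
    hm: HeightMap,
    path: str | Path,
    colormap: str = "afmhot",
    zrange: tuple[float, float] | None = None,
) -> ImageRender:
    """Render a height map and save it as PNG; returns the render."""
    import imageio.v2 as iio

    image = render(hm, colormap=colormap, zrange=zrange)
    iio.imwrite(str(path), image.pixels)
    return image
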