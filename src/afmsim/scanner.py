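"""Simulated AFM scanning of a rigid hard-sphere molecule.

The probe is the standard AFM tip idealization: a cone of half-angle
``theta`` terminated by a tangent spherical cap of radius ``R`` (the apex).
Scanning emulates a non-elastic collision experiment: for every cell of a
rectangular grid the tip is lowered along the vertical axis through the cell
centre until its surface first touches any atom sphere; the apex height at
first contact is the recorded topography value.  The substrate is a hard
plane at ``z = 0``, so heights are floored at zero.

Geometry.  Put the tip apex (lowest point) at height ``h`` over a cell.  The
cap centre is then at ``h + R`` on the axis, and cap and cone join smoothly
on the circle at lateral distance ``R cos(theta)`` and height
``h + R (1 - sin(theta))``.  For an atom sphere of radius ``r`` at lateral
distance ``d`` from the axis and centre height ``z``, first contact occurs at

* ``h = z - R + sqrt((R + r)^2 - d^2)``                       (cap regime,
  ``d <= (R + r) cos(theta)``), or
* ``h = z - R (1 - sin(theta)) - ((d - R cos(theta)) cos(theta) - r) / sin(theta)``
  (cone-flank regime, larger ``d``).

The two expressions agree on the regime boundary by tangency.  A
brute-force descent oracle (:func:`scan_oracle`) validates the closed forms
numerically and is deliberately independent of them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .structure_io import AtomModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TipParameters:
    """Rigid sphere-capped conical tip.

    ``radius_nm`` is the apex (cap) radius; ``half_angle_deg`` the cone
    half-angle, strictly between 0 and 90 degrees.
    """

    radius_nm: float
    half_angle_deg: float

    def __post_init__(self) -> None:
        if not self.radius_nm > 0:
            raise ValueError(f"apex radius must be positive, got {self.radius_nm}")
        if not 0 < self.half_angle_deg < 90:
            raise ValueError(
                f"half-angle must lie in (0, 90) degrees, got {self.half_angle_deg}"
            )

    @property
    def sin_theta(self) -> float:
        return math.sin(math.radians(self.half_angle_deg))

    @property
    def cos_theta(self) -> float:
        return math.cos(math.radians(self.half_angle_deg))


@dataclass(frozen=True)
class ScanGrid:
    """Square-pixel scan raster: cell centres at ``(x0 + i*spacing, y0 + j*spacing)``."""

    x0: float
    y0: float
    spacing: float
    nx: int
    ny: int

    def __post_init__(self) -> None:
        if not self.spacing > 0:
            raise ValueError("grid spacing must be positive")
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid must have at least one cell per axis")

    def x_centers(self) -> np.ndarray:
        return self.x0 + self.spacing * np.arange(self.nx)

    def y_centers(self) -> np.ndarray:
        return self.y0 + self.spacing * np.arange(self.ny)

    @property
    def shape(self) -> tuple[int, int]:
        """Array shape of a height map on this grid, ``(ny, nx)``."""
        return (self.ny, self.nx)

    def extent(self) -> tuple[float, float, float, float]:
        """``(xmin, xmax, ymin, ymax)`` of the cell-centre lattice."""
        return (
            self.x0,
            self.x0 + self.spacing * (self.nx - 1),
            self.y0,
            self.y0 + self.spacing * (self.ny - 1),
        )


@dataclass
class HeightMap:
    """Topographic image: one height (nm) per grid cell, row 0 = smallest y."""

    grid: ScanGrid
    heights: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.shape != self.grid.shape:
            raise ValueError(
                f"heights shape {self.heights.shape} does not match grid {self.grid.shape}"
            )

    @property
    def max_height(self) -> float:
        return float(self.heights.max()) if self.heights.size else 0.0

    def copy(self) -> "HeightMap":
        return HeightMap(self.grid, self.heights.copy(), dict(self.metadata))


def auto_grid(
    model: AtomModel,
    spacing: float | None = None,
    *,
    margin: float = 2.0,
    max_cells: int = 512,
    center: tuple[float, float] = (0.0, 0.0),
) -> ScanGrid:
    """Build a scan grid covering the grounded model's footprint plus a margin.

    The grid is symmetric about ``center`` with an odd cell count per axis, so
    one cell centre coincides with the model's lateral centroid; this keeps
    sub-pixel registration consistent between maps scanned at the same
    spacing.  If ``spacing`` is omitted it is chosen so the longer axis has at
    most ``max_cells`` cells (capped at 512 per axis either way).
    """
    if model.n_atoms == 0:
        raise ValueError("cannot derive a grid from an empty model")
    x, y = model.positions[:, 0], model.positions[:, 1]
    r = model.radii
    half_x = float(np.max(np.abs(x - center[0]) + r)) + margin
    half_y = float(np.max(np.abs(y - center[1]) + r)) + margin
    if spacing is None:
        spacing = 2.0 * max(half_x, half_y) / (max_cells - 1)
    n_half_x = int(math.ceil(half_x / spacing))
    n_half_y = int(math.ceil(half_y / spacing))
    nx, ny = 2 * n_half_x + 1, 2 * n_half_y + 1
    if max(nx, ny) > max_cells:
        raise ValueError(
            f"grid of {nx}x{ny} cells exceeds max_cells={max_cells}; "
            "increase spacing or max_cells"
        )
    return ScanGrid(
        x0=center[0] - n_half_x * spacing,
        y0=center[1] - n_half_y * spacing,
        spacing=spacing,
        nx=nx,
        ny=ny,
    )


# ---------------------------------------------------------------------------
# Contact-height closed forms
# ---------------------------------------------------------------------------


def tip_contact_height(
    atom_center: np.ndarray,
    atom_radius: float,
    lateral_pos: tuple[float, float],
    tip: TipParameters,
) -> float | None:
    """Apex height at which the descending tip first touches one atom sphere.

    Returns ``None`` when the tip would reach the substrate (height 0) before
    touching the sphere, i.e. the atom does not obstruct the descent at this
    lateral position.
    """
    if atom_radius <= 0:
        raise ValueError("atom radius must be positive")
    xc, yc, z = (float(v) for v in np.asarray(atom_center, dtype=float))
    d = math.hypot(lateral_pos[0] - xc, lateral_pos[1] - yc)
    R, s, c = tip.radius_nm, tip.sin_theta, tip.cos_theta
    rr = R + atom_radius
    if d <= rr * c:
        h = z - R + math.sqrt(rr * rr - d * d)
    else:
        h = z - R * (1.0 - s) - ((d - R * c) * c - atom_radius) / s
    return h if h > 0.0 else None


def _atom_heights_on_window(
    xs: np.ndarray,
    ys: np.ndarray,
    xa: float,
    ya: float,
    za: float,
    ra: float,
    tip: TipParameters,
) -> np.ndarray:
    """Vectorized contact heights of one atom over a sub-grid (may be <= 0)."""
    R, s, c = tip.radius_nm, tip.sin_theta, tip.cos_theta
    rr = R + ra
    d2 = (xs[None, :] - xa) ** 2 + (ys[:, None] - ya) ** 2
    d = np.sqrt(d2)
    cap = d <= rr * c
    h = za - R * (1.0 - s) - ((d - R * c) * c - ra) / s
    if np.any(cap):
        h[cap] = za - R + np.sqrt(rr * rr - d2[cap])
    return h


def _atom_reach(za: float, ra: float, tip: TipParameters) -> float:
    """Lateral distance beyond which the atom cannot raise the tip above 0."""
    R, s, c = tip.radius_nm, tip.sin_theta, tip.cos_theta
    cone_reach = R * c + (ra + (za - R * (1.0 - s)) * s) / c
    return max(cone_reach, (R + ra))


def scan(
    model: AtomModel,
    tip: TipParameters,
    grid: ScanGrid,
    *,
    method: str = "windowed",
) -> HeightMap:
    """Simulated AFM image: per-cell max contact height over atoms, floored at 0.

    ``method="windowed"`` restricts each atom to the cells it can reach
    (near-linear in atom count); ``method="full"`` evaluates every atom on
    every cell and exists as the plain reference path.  Both give identical
    results.
    """
    if method not in ("windowed", "full"):
        raise ValueError(f"unknown scan method {method!r}")
    heights = np.zeros(grid.shape)
    if model.n_atoms == 0:
        logger.info("scanning an empty model: returning an all-zero height map")
        return HeightMap(grid, heights, _scan_metadata(tip, "simulated"))
    xs, ys = grid.x_centers(), grid.y_centers()
    for (xa, ya, za), ra in zip(model.positions, model.radii):
        if method == "windowed":
            reach = _atom_reach(za, ra, tip) + grid.spacing
            i0 = int(np.searchsorted(xs, xa - reach, side="left"))
            i1 = int(np.searchsorted(xs, xa + reach, side="right"))
            j0 = int(np.searchsorted(ys, ya - reach, side="left"))
            j1 = int(np.searchsorted(ys, ya + reach, side="right"))
            if i0 >= i1 or j0 >= j1:
                continue
        else:
            i0, i1, j0, j1 = 0, grid.nx, 0, grid.ny
        h = _atom_heights_on_window(xs[i0:i1], ys[j0:j1], xa, ya, za, ra, tip)
        np.maximum(heights[j0:j1, i0:i1], h, out=heights[j0:j1, i0:i1])
    np.maximum(heights, 0.0, out=heights)
    return HeightMap(grid, heights, _scan_metadata(tip, "simulated"))


def _scan_metadata(tip: TipParameters | None, source: str) -> dict[str, Any]:
    meta: dict[str, Any] = {"source": source}
    if tip is not None:
        meta["tip_radius_nm"] = tip.radius_nm
        meta["tip_half_angle_deg"] = tip.half_angle_deg
    return meta


# ---------------------------------------------------------------------------
# Brute-force descent oracle
# ---------------------------------------------------------------------------


def _tip_surface_distance(
    d: np.ndarray, z: np.ndarray, h: np.ndarray, tip: TipParameters
) -> np.ndarray:
    """Signed distance from points to the tip solid's surface (negative inside).

    ``d``/``z`` are point coordinates (lateral distance to the axis, height);
    ``h`` is the apex height.  The solid is the union of the spherical cap and
    the cone; for each point the governing surface patch is selected by the
    along-flank coordinate measured from the cap-cone junction.
    """
    R, s, c = tip.radius_nm, tip.sin_theta, tip.cos_theta
    z_rel = z - (h + R * (1.0 - s))
    along_flank = (d - R * c) * s + z_rel * c
    flank_dist = (d - R * c) * c - z_rel * s
    cap_dist = np.sqrt(d * d + (z - (h + R)) ** 2) - R
    return np.where(along_flank >= 0.0, flank_dist, cap_dist)


def scan_oracle(
    model: AtomModel,
    tip: TipParameters,
    grid: ScanGrid,
    dz: float = 1e-4,
) -> HeightMap:
    """Numerical reference scan: lower the tip in steps ``dz`` until overlap.

    For each cell the apex is stepped down from above the molecule; at every
    step the tip solid is tested for overlap with each atom sphere via a
    point-to-surface distance, and the last non-overlapping apex height is
    recorded (floored at 0).  Independent of the closed-form contact
    expressions, hence usable to validate them.
    """
    if dz <= 0:
        raise ValueError("descent step dz must be positive")
    heights = np.zeros(grid.shape)
    if model.n_atoms == 0:
        return HeightMap(grid, heights, _scan_metadata(tip, "oracle"))
    h_start = model.top_height() + 10 * dz
    steps = np.arange(h_start, -dz / 2, -dz)  # descending, ends at/below 0
    xs, ys = grid.x_centers(), grid.y_centers()
    pos, radii = model.positions, model.radii
    for j, y in enumerate(ys):
        for i, x in enumerate(xs):
            d = np.hypot(pos[:, 0] - x, pos[:, 1] - y)
            dist = _tip_surface_distance(
                d[:, None], pos[:, 2][:, None], steps[None, :], tip
            )
            overlap = np.any(dist < radii[:, None], axis=0)
            if overlap.any():
                k = int(np.argmax(overlap))
                heights[j, i] = max(steps[k - 1] if k > 0 else h_start, 0.0)
            else:
                heights[j, i] = 0.0
    return HeightMap(grid, heights, _scan_metadata(tip, "oracle"))


# ---------------------------------------------------------------------------
# Zero-tip limit
# ---------------------------------------------------------------------------


def vdw_envelope(model: AtomModel, grid: ScanGrid) -> HeightMap:
    """Upper envelope of the atom spheres themselves (the zero-size-tip limit).

    ``h(x, y) = max_i (z_i + sqrt(r_i^2 - d_i^2))`` over atoms whose lateral
    distance ``d_i`` is at most ``r_i``; 0 elsewhere.  Any finite-tip scan is
    pointwise >= this envelope (tip dilation).
    """
    heights = np.zeros(grid.shape)
    xs, ys = grid.x_centers(), grid.y_centers()
    for (xa, ya, za), ra in zip(model.positions, model.radii):
        i0 = int(np.searchsorted(xs, xa - ra, side="left"))
        i1 = int(np.searchsorted(xs, xa + ra, side="right"))
        j0 = int(np.searchsorted(ys, ya - ra, side="left"))
        j1 = int(np.searchsorted(ys, ya + ra, side="right"))
        if i0 >= i1 or j0 >= j1:
            continue
        d2 = (xs[None, i0:i1] - xa) ** 2 + (ys[j0:j1, None] - ya) ** 2
        inside = d2 <= ra * ra
        h = np.zeros_like(d2)
        h[inside] = za + np.sqrt(ra * ra - d2[inside])
        np.maximum(heights[j0:j1, i0:i1], h, out=heights[j0:j1, i0:i1])
    np.maximum(heights, 0.0, out=heights)
    return HeightMap(grid, heights, {"source": "envelope"})
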