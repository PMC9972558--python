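"""Quantitative topography analysis: profiles, difference maps, periodicity.

These tools compare simulated and measured height maps.  The central
geometric fact they quantify is tip dilation: a finite tip contacts the
molecule away from its apex, so simulated (and measured) topographies are
pointwise upper bounds on the molecular sphere envelope and absolute heights
are systematically inflated, while relative heights and lateral periodicity
are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.signal import find_peaks

from .scanner import HeightMap


@dataclass
class Profile:
    """Heights sampled along a polyline: arc-length positions (nm) + heights (nm)."""

    positions: np.ndarray
    heights: np.ndarray
    vertices: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.positions.shape != self.heights.shape:
            raise ValueError("positions and heights must have equal length")
        if len(self.positions) and (
            self.positions[0] != 0.0 or np.any(np.diff(self.positions) <= 0)
        ):
            raise ValueError("positions must increase strictly from 0")

    @property
    def step(self) -> float:
        return float(self.positions[1] - self.positions[0])


def height_profile(
    hm: HeightMap, polyline: Sequence[Sequence[float]], step: float
) -> Profile:
    """Sample bilinear-interpolated heights every ``step`` nm along a polyline.

    All vertices must lie inside the grid's cell-centre extent.
    """
    vertices = np.asarray(polyline, dtype=float).reshape(-1, 2)
    if len(vertices) < 2:
        raise ValueError("polyline needs at least 2 vertices")
    if step <= 0:
        raise ValueError("step must be positive")
    xmin, xmax, ymin, ymax = hm.grid.extent()
    if (
        np.any(vertices[:, 0] < xmin)
        or np.any(vertices[:, 0] > xmax)
        or np.any(vertices[:, 1] < ymin)
        or np.any(vertices[:, 1] > ymax)
    ):
        raise ValueError("polyline extends outside the height-map extent")
    seg = np.diff(vertices, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    if total <= 0:
        raise ValueError("polyline has zero length")
    positions = np.arange(0.0, total + step / 2, step)
    positions = positions[positions <= total + 1e-12]
    # map arc length to xy
    xy = np.empty((len(positions), 2))
    for k, t in enumerate(positions):
        j = min(int(np.searchsorted(cum, t, side="right")) - 1, len(seg) - 1)
        frac = 0.0 if seg_len[j] == 0 else (t - cum[j]) / seg_len[j]
        xy[k] = vertices[j] + frac * seg[j]
    interp = RegularGridInterpolator(
        (hm.grid.y_centers(), hm.grid.x_centers()),
        hm.heights,
        method="linear",
        bounds_error=False,
        fill_value=0.0,
    )
    heights = interp(xy[:, ::-1])
    return Profile(positions=positions, heights=heights, vertices=vertices)


def difference_map(a: HeightMap, b: HeightMap) -> tuple[HeightMap, dict[str, float]]:
    """Signed per-cell difference ``a - b`` plus summary statistics.

    The maps must live on the same grid (use :func:`afmsim.imaging.resample`
    first otherwise).  Returns the signed map and a dict with the mean signed
    difference and the RMS difference (both nm).
    """
    if a.grid != b.grid:
        raise ValueError("grids differ; resample to a common grid first")
    diff = a.heights - b.heights
    stats = {
        "mean_signed_nm": float(diff.mean()),
        "rms_nm": float(np.sqrt(np.mean(diff**2))),
    }
    return HeightMap(a.grid, diff, {"source": "difference"}), stats


def estimate_pitch(
    profile: Profile, *, prominence_frac: float = 0.2
) -> float | None:
    """Dominant repeat distance of a height profile, in nm.

    Computes the autocorrelation of the mean-subtracted heights (normalized
    by its zero-lag value) and returns the lag of the first local maximum
    that clears ``prominence_frac`` both in correlation value and in peak
    prominence, refined to sub-sample precision by a parabolic fit.  The
    prominence requirement rejects fine surface ripple riding on a slowly
    decaying correlation; the value requirement rejects the spurious peaks
    of aperiodic (noise-like) profiles.  Returns ``None`` when no qualifying
    peak exists.  The caller should supply a profile covering at least two
    expected periods.
    """
    h = profile.heights - profile.heights.mean()
    n = len(h)
    if n < 4:
        return None
    ac = np.correlate(h, h, mode="full")[n - 1 :]
    if ac[0] <= 0:
        return None
    ac = ac / ac[0]
    peaks, _ = find_peaks(ac, height=prominence_frac, prominence=prominence_frac)
    if len(peaks) == 0:
        return None
    k = int(peaks[0])
    # parabolic sub-sample refinement around the discrete peak
    if 0 < k < n - 1:
        a, b, c = ac[k - 1], ac[k], ac[k + 1]
        denom = a - 2 * b + c
        delta = 0.0 if denom == 0 else 0.5 * (a - c) / denom
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    return (k + delta) * profile.step


def summary_stats(hm: HeightMap) -> dict[str, float]:
    """Scalar descriptors of a topography.

    ``max_height_nm``; ``mean_nonzero_nm`` (mean over cells above the
    substrate); ``footprint_area_nm2`` (nonzero-cell count times the cell
    area); ``volume_nm3`` (cell-sum quadrature of the heights).
    """
    cell_area = hm.grid.spacing**2
    nonzero = hm.heights > 0
    return {
        "max_height_nm": float(hm.heights.max()) if hm.heights.size else 0.0,
        "mean_nonzero_nm": float(hm.heights[nonzero].mean()) if nonzero.any() else 0.0,
        "footprint_area_nm2": float(nonzero.sum() * cell_area),
        "volume_nm3": float(hm.heights.sum() * cell_area),
    }
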