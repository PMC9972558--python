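"""Automatized rigid-body fitting of a structure to a target AFM image.

The image similarity score is the Pearson correlation between the simulated
and target height maps, maximized over integer lateral translations (pixels
that are zero in *both* maps — substrate background — are excluded).
Correlation is insensitive to a global height scale and offset, which suits
AFM comparisons where absolute simulated heights systematically exceed
measured ones while relative heights agree.

The search over molecular orientations is two-layered:

1. *Global sampling* — a deterministic quasi-uniform library of orientations
   (spherical Fibonacci lattice of tip-approach directions crossed with
   equally spaced in-plane spins), each scanned and scored.
2. *Iterative refinement* — derivative-free hill climbing from the best
   global candidates: axis-wise rotation perturbations with geometric step
   shrinkage, monotone in the score.

Everything is deterministic for fixed inputs; the full candidate table is
retained so the score landscape can be audited.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .scanner import HeightMap, TipParameters, auto_grid, scan
from .structure_io import AtomModel, Orientation, orient_and_ground

_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))
_AXES = (np.array([1.0, 0, 0]), np.array([0, 1.0, 0]), np.array([0, 0, 1.0]))


class SimilarityError(ValueError):
    """Raised when two maps share fewer than 2 usable pixels at every shift."""


@dataclass(frozen=True)
class SimilarityScore:
    """Registered image similarity: score value, pixels used, best translation.

    ``translation = (dx, dy)`` is the integer cell shift applied to the
    simulated map that best overlays it on the target.
    """

    value: float
    n_pixels: int
    translation: tuple[int, int]


@dataclass
class FitResult:
    """Outcome of the two-layered orientation search."""

    best_orientation: Orientation
    best_score: SimilarityScore
    candidates: pd.DataFrame
    refinement_traces: list[list[tuple[int, float, float]]]
    refined: list[tuple[Orientation, SimilarityScore]]
    degenerate_orientations: list[tuple[Orientation, SimilarityScore]]

    def to_dict(self) -> dict:
        qx, qy, qz, qw = self.best_orientation.as_quat()
        alpha, beta, gamma = self.best_orientation.as_zyz_deg()
        return {
            "best_orientation": {
                "quaternion_xyzw": [qx, qy, qz, qw],
                "zyz_deg": [alpha, beta, gamma],
            },
            "best_score": self.best_score.value,
            "n_pixels": self.best_score.n_pixels,
            "translation_cells": list(self.best_score.translation),
            "n_candidates": int(len(self.candidates)),
            "n_degenerate": len(self.degenerate_orientations),
        }

    def save(self, path: str | Path, *, candidates_csv: str | Path | None = None) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
        if candidates_csv is not None:
            self.candidates.drop(columns=["orientation"]).to_csv(
                candidates_csv, index=False
            )


# ---------------------------------------------------------------------------
# Similarity score
# ---------------------------------------------------------------------------


def _shifted_sim(x: np.ndarray, y: np.ndarray, oy: int, ox: int) -> np.ndarray:
    """Sim ``y`` shifted by (oy, ox) onto the target's domain, zero-extended.

    The simulated surface is bare substrate (height 0) outside its own grid,
    so target pixels the shifted sim array does not reach compare against 0.
    """
    Hy, Hx = x.shape
    hy, hx = y.shape
    y_eff = np.zeros_like(x)
    i0, i1 = max(0, oy), min(Hy, hy + oy)
    j0, j1 = max(0, ox), min(Hx, hx + ox)
    if i0 < i1 and j0 < j1:
        y_eff[i0:i1, j0:j1] = y[i0 - oy : i1 - oy, j0 - ox : j1 - ox]
    return y_eff


def _pearson_at_offset(
    x: np.ndarray, y: np.ndarray, oy: int, ox: int, exclude_background: bool
) -> tuple[float, int] | None:
    """Exact Pearson r over the target domain at one shift; None if undefined."""
    y_eff = _shifted_sim(x, y, oy, ox)
    if exclude_background:
        mask = ~((x == 0.0) & (y_eff == 0.0))
        xv, yv = x[mask], y_eff[mask]
    else:
        xv, yv = x.ravel(), y_eff.ravel()
    n = xv.size
    if n < 2:
        return None
    sx, sy = xv.sum(), yv.sum()
    vx = (xv * xv).sum() - sx * sx / n
    vy = (yv * yv).sum() - sy * sy / n
    cov = (xv * yv).sum() - sx * sy / n
    den = math.sqrt(vx * vy) if vx > 0 and vy > 0 else 0.0
    if den == 0.0:
        return None
    return float(min(1.0, max(-1.0, cov / den))), n


def _rms_at_offset(
    x: np.ndarray, y: np.ndarray, oy: int, ox: int, exclude_background: bool
) -> tuple[float, int] | None:
    y_eff = _shifted_sim(x, y, oy, ox)
    if exclude_background:
        mask = ~((x == 0.0) & (y_eff == 0.0))
        xv, yv = x[mask], y_eff[mask]
    else:
        xv, yv = x.ravel(), y_eff.ravel()
    if xv.size < 2:
        return None
    return -float(np.sqrt(np.mean((xv - yv) ** 2))), xv.size


def similarity(
    sim: HeightMap,
    target: HeightMap,
    *,
    max_shift: tuple[int, int] | None = None,
    exclude_background: bool = True,
    score: str = "pearson",
) -> SimilarityScore:
    """Translation-registered similarity between a simulated and a target map.

    Both maps must share the pixel size.  The score is maximized over all
    integer translations with ``|dx| <= max_shift[0]`` and ``|dy| <=
    max_shift[1]`` (default: half the target size per axis).  With
    ``score="pearson"`` (default) the value is the correlation coefficient in
    ``[-1, 1]``; ``score="rmsd"`` returns the negated root-mean-square height
    difference instead (still "larger is better").

    At every shift the comparison domain is the full target image, with the
    simulated map treated as bare substrate (height 0) outside its own grid;
    target features the candidate fails to reproduce therefore always count
    against it.  Pixels where both surfaces are exactly 0 are substrate
    background and are excluded from the statistics.
    """
    if score not in ("pearson", "rmsd"):
        raise ValueError(f"unknown score {score!r}")
    if not np.isclose(sim.grid.spacing, target.grid.spacing, rtol=1e-9):
        raise ValueError(
            "maps must share a pixel size before scoring; resample() one first"
        )
    x = np.asarray(target.heights, dtype=float)
    y = np.asarray(sim.heights, dtype=float)
    Hy, Hx = x.shape
    hy, hx = y.shape
    if max_shift is None:
        max_shift = (Hx // 2, Hy // 2)
    mx, my = int(max_shift[0]), int(max_shift[1])

    # Sliding sums over the full target domain (sim zero-extended) for every
    # shift via FFT.  Sums of x and x^2 are shift-independent; sums of y,
    # y^2 and x*y only collect sim pixels that land inside the target, and —
    # because excluded (both-zero) pixels contribute nothing to any sum —
    # only the pixel count n depends on the background mask.
    yf = y[::-1, ::-1]
    ones_y = np.ones_like(y)
    ones_x = np.ones_like(x)
    sxy = fftconvolve(x, yf)
    sy = fftconvolve(ones_x, yf)
    syy = fftconvolve(ones_x, (y * y)[::-1, ::-1])
    sx = x.sum()
    sxx = (x * x).sum()
    n_pix = float(x.size)
    if exclude_background:
        # n = #domain - #(x==0 & y_eff==0); y_eff is nonzero only where a
        # nonzero sim pixel lands, so count those landing on zero target.
        x_zero = (x == 0.0).astype(float)
        nz_on_zero = np.round(fftconvolve(x_zero, (y != 0.0)[::-1, ::-1].astype(float)))
        n = n_pix - x_zero.sum() + nz_on_zero
    else:
        n = np.full(sxy.shape, n_pix)

    with np.errstate(divide="ignore", invalid="ignore"):
        cov = sxy - sx * sy / n
        vx = sxx - sx * sx / n
        vy = syy - sy * sy / n
        if score == "pearson":
            values = cov / np.sqrt(vx * vy)
            valid = (n >= 2) & (vx > 1e-12) & (vy > 1e-12)
        else:
            values = -np.sqrt(np.maximum(sxx - 2.0 * sxy + syy, 0.0) / n)
            valid = n >= 2
    values = np.where(valid, values, -np.inf)

    # offset (oy, ox) lives at array index (oy + hy - 1, ox + hx - 1)
    oy_lo, oy_hi = max(-my, -(hy - 1)), min(my, Hy - 1)
    ox_lo, ox_hi = max(-mx, -(hx - 1)), min(mx, Hx - 1)
    if oy_lo > oy_hi or ox_lo > ox_hi:
        raise SimilarityError("translation search window is empty")
    window = values[
        oy_lo + hy - 1 : oy_hi + hy, ox_lo + hx - 1 : ox_hi + hx
    ]
    if not np.any(np.isfinite(window)):
        raise SimilarityError(
            "fewer than 2 usable (non-background) pixels at every translation"
        )
    # take the best shift, recomputed exactly (no FFT rounding); fall back to
    # the next-best shift if FFT noise marked a degenerate one as valid
    eval_fn = _pearson_at_offset if score == "pearson" else _rms_at_offset
    window = window.copy()
    while np.any(np.isfinite(window)):
        flat = int(np.argmax(window))  # first maximum: deterministic tie-break
        oy = oy_lo + flat // window.shape[1]
        ox = ox_lo + flat % window.shape[1]
        exact = eval_fn(x, y, oy, ox, exclude_background)
        if exact is not None:
            value, n_pixels = exact
            return SimilarityScore(
                value=value, n_pixels=n_pixels, translation=(ox, oy)
            )
        window.flat[flat] = -np.inf
    raise SimilarityError(
        "fewer than 2 usable (non-background) pixels at every translation"
    )


# ---------------------------------------------------------------------------
# Orientation sampling
# ---------------------------------------------------------------------------


def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` quasi-uniform unit vectors (spherical Fibonacci lattice).

    The lattice includes both poles, so ``n = 1`` yields the +z direction.
    """
    if n < 1:
        raise ValueError("need at least one direction")
    if n == 1:
        return np.array([[0.0, 0.0, 1.0]])
    k = np.arange(n)
    z = 1.0 - 2.0 * k / (n - 1)
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    phi = k * _GOLDEN_ANGLE
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _align_z_to(direction: np.ndarray) -> Orientation:
    """Rotation taking +z to ``direction`` about the mutual perpendicular."""
    d = direction / np.linalg.norm(direction)
    cosang = float(np.clip(d[2], -1.0, 1.0))
    axis = np.cross([0.0, 0.0, 1.0], d)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        if cosang > 0:
            return Orientation.identity()
        return Orientation.from_axis_angle_deg([1.0, 0.0, 0.0], 180.0)
    return Orientation.from_axis_angle_deg(axis / norm, math.degrees(math.acos(cosang)))


def sample_orientations(n_tip_directions: int, n_spins: int) -> list[Orientation]:
    """Deterministic quasi-uniform orientation library for the global search.

    Crosses a spherical Fibonacci lattice of ``n_tip_directions`` approach
    directions with ``n_spins`` equally spaced in-plane rotations.
    ``sample_orientations(1, 1)`` is the identity.
    """
    if n_tip_directions < 1 or n_spins < 1:
        raise ValueError("counts must be >= 1")
    spins = 360.0 * np.arange(n_spins) / n_spins
    orientations: list[Orientation] = []
    for direction in fibonacci_sphere(n_tip_directions):
        tilt = _align_z_to(direction)
        for spin in spins:
            orientations.append(
                tilt.compose(Orientation.from_axis_angle_deg([0, 0, 1.0], spin))
            )
    return orientations


# ---------------------------------------------------------------------------
# Two-layered search
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitConfig:
    """Tunable parameters of the two-layered search (angles in degrees)."""

    n_tip_directions: int = 200
    n_spins: int = 18
    top_k: int = 5
    initial_step_deg: float = 10.0
    shrink: float = 0.5
    tol_deg: float = 0.1
    margin_nm: float = 1.0
    degeneracy_tol: float = 1e-3
    distinct_angle_deg: float = 10.0
    score: str = "pearson"


def score_orientation(
    model: AtomModel,
    orientation: Orientation,
    tip: TipParameters,
    target: HeightMap,
    *,
    margin: float = 1.0,
    score: str = "pearson",
) -> SimilarityScore:
    """Ground the model in ``orientation``, scan at the target's pixel size, score."""
    grounded = orient_and_ground(model, orientation)
    grid = auto_grid(grounded, spacing=target.grid.spacing, margin=margin)
    sim = scan(grounded, tip, grid)
    return similarity(sim, target, score=score)


def global_search(
    model: AtomModel,
    target: HeightMap,
    tip: TipParameters,
    orientations: Sequence[Orientation],
    *,
    margin: float = 1.0,
    score: str = "pearson",
) -> pd.DataFrame:
    """Score every orientation of the library against the target.

    Returns the candidate table sorted by descending score (stable, so ties
    keep sample order).  Columns include the :class:`Orientation` object, its
    quaternion and ZYZ angles, the score and the registered translation.
    """
    if len(orientations) == 0:
        raise ValueError("orientation library is empty")
    records = []
    for idx, orientation in enumerate(orientations):
        s = score_orientation(
            model, orientation, tip, target, margin=margin, score=score
        )
        qx, qy, qz, qw = orientation.as_quat()
        alpha, beta, gamma = orientation.as_zyz_deg()
        records.append(
            {
                "sample_index": idx,
                "score": s.value,
                "n_pixels": s.n_pixels,
                "dx_cells": s.translation[0],
                "dy_cells": s.translation[1],
                "qx": qx,
                "qy": qy,
                "qz": qz,
                "qw": qw,
                "zyz_alpha_deg": alpha,
                "zyz_beta_deg": beta,
                "zyz_gamma_deg": gamma,
                "orientation": orientation,
            }
        )
    table = pd.DataFrame.from_records(records)
    return table.sort_values(
        "score", ascending=False, kind="stable", ignore_index=True
    )


def refine(
    model: AtomModel,
    target: HeightMap,
    tip: TipParameters,
    start: Orientation,
    *,
    initial_step_deg: float = 8.0,
    shrink: float = 0.5,
    tol_deg: float = 0.1,
    margin: float = 1.0,
    score: str = "pearson",
) -> tuple[Orientation, SimilarityScore, list[tuple[int, float, float]]]:
    """Monotone hill climbing over orientations from ``start``.

    At each iteration the six neighbours obtained by rotating +/- the current
    step about the x, y and z axes are scored; the best neighbour is accepted
    if it improves the score, otherwise the step is multiplied by ``shrink``.
    Terminates when the step falls below ``tol_deg``.  The trace records
    ``(iteration, step, best score)`` and is non-decreasing in the score.
    """
    if not initial_step_deg > tol_deg > 0:
        raise ValueError("require initial_step_deg > tol_deg > 0")
    if not 0 < shrink < 1:
        raise ValueError("shrink must lie in (0, 1)")
    current = start
    best = score_orientation(model, current, tip, target, margin=margin, score=score)
    step = initial_step_deg
    trace = [(0, step, best.value)]
    iteration = 0
    while step >= tol_deg:
        iteration += 1
        best_neighbor: Orientation | None = None
        best_neighbor_score: SimilarityScore | None = None
        for axis in _AXES:
            for sign in (1.0, -1.0):
                candidate = Orientation.from_axis_angle_deg(axis, sign * step).compose(
                    current
                )
                s = score_orientation(
                    model, candidate, tip, target, margin=margin, score=score
                )
                if best_neighbor_score is None or s.value > best_neighbor_score.value:
                    best_neighbor, best_neighbor_score = candidate, s
        if best_neighbor_score is not None and best_neighbor_score.value > best.value:
            current, best = best_neighbor, best_neighbor_score
        else:
            step *= shrink
        trace.append((iteration, step, best.value))
    return current, best, trace


def fit(
    model: AtomModel,
    target: HeightMap,
    tip: TipParameters,
    config: FitConfig = FitConfig(),
) -> FitResult:
    """Two-layered rigid-body fit: global library search, then refinement.

    The top ``config.top_k`` global candidates are each refined; the overall
    best refined orientation wins (ties go to the better-ranked candidate).
    Refined orientations whose score comes within ``config.degeneracy_tol``
    of the best and which differ by more than ``config.distinct_angle_deg``
    are reported as degenerate solutions (molecular symmetry).
    """
    orientations = sample_orientations(config.n_tip_directions, config.n_spins)
    candidates = global_search(
        model, target, tip, orientations, margin=config.margin_nm, score=config.score
    )
    refined: list[tuple[Orientation, SimilarityScore]] = []
    traces: list[list[tuple[int, float, float]]] = []
    for _, row in candidates.head(config.top_k).iterrows():
        orientation, best, trace = refine(
            model,
            target,
            tip,
            row["orientation"],
            initial_step_deg=config.initial_step_deg,
            shrink=config.shrink,
            tol_deg=config.tol_deg,
            margin=config.margin_nm,
            score=config.score,
        )
        refined.append((orientation, best))
        traces.append(trace)
    best_idx = max(range(len(refined)), key=lambda i: (refined[i][1].value, -i))
    best_orientation, best_score = refined[best_idx]

    degenerate = [(best_orientation, best_score)]
    for orientation, s in refined:
        if s.value < best_score.value - config.degeneracy_tol:
            continue
        if all(
            orientation.angle_to(other) > config.distinct_angle_deg
            for other, _ in degenerate
        ):
            degenerate.append((orientation, s))

    return FitResult(
        best_orientation=best_orientation,
        best_score=best_score,
        candidates=candidates,
        refinement_traces=traces,
        refined=refined,
        degenerate_orientations=degenerate,
    )
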