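"""Simulated AFM experiments on conformational trajectories.

A trajectory (multi-MODEL PDB) is scanned frame by frame with one shared
molecular rotation, one shared grid and — for rendering — one shared height
color range, so frames are directly comparable, emulating how a molecular
movie would appear under the scanning tip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .imaging import render
from .scanner import HeightMap, ScanGrid, TipParameters, auto_grid, scan
from .structure_io import (
    AtomModel,
    Orientation,
    _model_from_gemmi,
    orient_and_ground,
)


class TrajectoryFormatError(ValueError):
    """Raised when trajectory frames are mutually inconsistent."""


@dataclass
class Trajectory:
    """Ordered conformations of one molecule (equal atom count and elements)."""

    frames: list[AtomModel]
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise TrajectoryFormatError("a trajectory needs at least one frame")
        first = self.frames[0]
        for k, frame in enumerate(self.frames):
            if frame.n_atoms != first.n_atoms:
                raise TrajectoryFormatError(
                    f"frame {k} has {frame.n_atoms} atoms, frame 0 has {first.n_atoms}"
                )
            if frame.elements != first.elements:
                raise TrajectoryFormatError(f"frame {k} element sequence differs")
        if self.times is None:
            self.times = np.arange(len(self.frames), dtype=float)

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def read_trajectory_pdb(path: str | Path) -> Trajectory:
    """Read a multi-MODEL PDB as a trajectory (one frame per MODEL block)."""
    import gemmi

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    structure = gemmi.read_structure(str(path))
    frames = [
        _model_from_gemmi(model, keep_waters=False, altlocs=("A",), frame_id=k)
        for k, model in enumerate(structure)
    ]
    return Trajectory(frames=frames)


def scan_trajectory(
    trajectory: Trajectory,
    orientation: Orientation,
    tip: TipParameters,
    grid: ScanGrid | None = None,
    *,
    spacing: float | None = None,
    margin: float = 2.0,
) -> list[HeightMap]:
    """Scan every frame with the same rotation on one shared grid.

    Each frame is re-grounded individually (every conformation rests on the
    substrate, as an adsorbed molecule would).  If no grid is given, one is
    derived from the union of the grounded frames' footprints so that all
    frames fit.
    """
    grounded = [orient_and_ground(frame, orientation) for frame in trajectory.frames]
    if grid is None:
        widest = max(
            grounded,
            key=lambda m: float(np.max(np.hypot(m.positions[:, 0], m.positions[:, 1]) + m.radii)),
        )
        grid = auto_grid(widest, spacing=spacing, margin=margin)
    maps = [scan(frame, tip, grid) for frame in grounded]
    for k, hm in enumerate(maps):
        hm.metadata["frame_id"] = k
    return maps


def export_movie(
    maps: list[HeightMap],
    path: str | Path,
    *,
    fps: float = 5.0,
    frames_dir: str | Path | None = None,
    colormap: str = "afmhot",
) -> tuple[float, float]:
    """Export height maps as an animated GIF (plus optional per-frame PNGs).

    All frames share one z color range, ``(0, global max height)``, so pixel
    values are comparable across the movie.  Returns the shared z-range.
    """
    import imageio.v2 as iio

    if not maps:
        raise ValueError("no frames to export")
    zmax = max(hm.max_height for hm in maps)
    zrange = (0.0, zmax if zmax > 0 else 1.0)
    rendered = [render(hm, colormap=colormap, zrange=zrange).pixels for hm in maps]
    iio.mimsave(str(path), rendered, duration=1000.0 / fps, loop=0)
    if frames_dir is not None:
        frames_dir = Path(frames_dir)
        frames_dir.mkdir(parents=True, exist_ok=True)
        for k, pixels in enumerate(rendered):
            iio.imwrite(str(frames_dir / f"frame_{k:04d}.png"), pixels)
    return zrange
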