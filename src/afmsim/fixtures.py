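"""Deterministic synthetic structures for exercising every scanning code path.

Real AFM samples (filaments, multi-domain proteins, conformational movies)
are emulated by pseudo-atom constructions with inflated radii (0.3 - 2 nm):
grids stay small and tests stay fast while the geometry exercised —
hard-sphere envelopes, tip dilation, helical periodicity, rotational
(a)symmetry, hinge motions — is exactly that of real structures.  Every
generator is bitwise-deterministic for a given seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .movie import Trajectory
from .structure_io import AtomModel


def _pseudo_model(positions: np.ndarray, radii: np.ndarray, frame_id: int | None = None) -> AtomModel:
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    radii = np.asarray(radii, dtype=float).reshape(-1)
    return AtomModel(
        positions=positions,
        elements=["C"] * len(positions),
        radii=radii,
        frame_id=frame_id,
    )


def make_random_cloud(
    n: int, box: float = 4.0, radius: float = 0.3, seed: int = 0
) -> AtomModel:
    """``n`` equal spheres uniformly placed in a cube of edge ``box`` nm."""
    if n < 1:
        raise ValueError("need at least one atom")
    rng = np.random.default_rng(seed)
    positions = rng.uniform(0.0, box, size=(n, 3))
    return _pseudo_model(positions, np.full(n, radius))


def make_helix_filament(
    n_monomers: int,
    monomer_radius: float = 1.0,
    helix_radius: float = 1.5,
    half_pitch: float = 36.0,
    monomers_per_half_turn: int = 13,
    seed: int = 0,
    jitter: float = 0.0,
) -> AtomModel:
    """Two-start helical pseudo-filament with its axis along x.

    Monomers alternate between two strands offset by 180 degrees (the
    actin-like arrangement), so the topographic repeat along the axis equals
    ``half_pitch`` — the axial distance per half turn.  The axial rise per
    strand step is ``half_pitch / monomers_per_half_turn``.  ``jitter > 0``
    adds seeded Gaussian positional noise of that sigma (nm).
    """
    if n_monomers < 4:
        raise ValueError("need at least 4 monomers")
    rise = half_pitch / monomers_per_half_turn
    k = np.arange(n_monomers)
    strand = k % 2
    step = k // 2
    phi = math.pi * step / monomers_per_half_turn + math.pi * strand
    x = step * rise
    y = helix_radius * np.sin(phi)
    z = helix_radius * np.cos(phi)
    positions = np.column_stack([x, y, z]).astype(float)
    if jitter > 0:
        positions += np.random.default_rng(seed).normal(0.0, jitter, positions.shape)
    return _pseudo_model(positions, np.full(n_monomers, monomer_radius))


def make_multi_blob(n_blobs: int, asymmetric: bool = True, seed: int = 0) -> AtomModel:
    """Multi-domain blob model for orientation-fitting tests.

    ``asymmetric=True`` builds blobs of strictly increasing size and height
    at irregular lateral angles, so the model has no nontrivial rotational
    self-similarity and a simulated image pins down the orientation.
    ``asymmetric=False`` builds ``n_blobs`` identical copies of one blob
    rotated by exact multiples of ``360/n_blobs`` degrees about z — a
    C\\ :sub:`n`-symmetric model whose fits are degenerate by construction.
    """
    if n_blobs < 2:
        raise ValueError("need at least 2 blobs")
    rng = np.random.default_rng(seed)
    positions: list[np.ndarray] = []
    radii: list[np.ndarray] = []
    if asymmetric:
        # Chiral propeller: elongated domains of unequal length and height
        # radiating at irregular azimuths, each tilted out of the substrate
        # plane.  No rotation maps the model near itself, and flipped views
        # show the opposite handedness, so a simulated image pins down the
        # orientation sharply.
        angles = np.cumsum(1.1 + 0.8 * np.arange(n_blobs))
        for i in range(n_blobs):
            blob_r = 0.75 + 0.2 * i
            n_atoms = 4 + i
            t = 1.0 + 1.2 * np.arange(n_atoms)
            direction = np.array(
                [math.cos(angles[i]), math.sin(angles[i]), 0.22 + 0.08 * i]
            )
            pts = t[:, None] * direction[None, :] + np.array([0.0, 0.0, 0.9 * i])
            pts += rng.normal(0.0, 0.12, size=pts.shape)
            positions.append(pts)
            radii.append(np.full(n_atoms, blob_r))
        # off-centre cap on the first arm's tip: occluded from below
        tip_atom = positions[0][-1]
        positions.append(tip_atom[None, :] + np.array([[0.4, -0.4, 0.9]]))
        radii.append(np.array([0.55]))
    else:
        n_atoms = 6
        base = np.array([3.0, 0.0, 0.0]) + rng.normal(0.0, 0.5, size=(n_atoms, 3))
        for i in range(n_blobs):
            theta = 2.0 * math.pi * i / n_blobs
            rot = np.array(
                [
                    [math.cos(theta), -math.sin(theta), 0.0],
                    [math.sin(theta), math.cos(theta), 0.0],
                    [0.0, 0.0, 1.0],
                ]
            )
            positions.append(base @ rot.T)
            radii.append(np.full(n_atoms, 1.0))
    return _pseudo_model(np.concatenate(positions), np.concatenate(radii))


def make_open_close_trajectory(
    n_frames: int,
    amplitude: float = 3.0,
    arm_length: float = 6.0,
    atom_radius: float = 0.8,
    seed: int = 0,
) -> Trajectory:
    """Two-domain hinge toy: a fixed base plus an arm opening sinusoidally.

    The arm (length ``arm_length`` nm) hinges about the y axis; the opening
    angle follows ``alpha_max * (1 - cos(2*pi*t/(n-1))) / 2`` so frame 0 is
    the closed state and the motion returns to closed at the last frame.
    ``alpha_max`` is chosen so the arm tip rises by ``amplitude`` nm when
    fully open; :func:`open_close_expected_max_heights` gives the resulting
    per-frame envelope maximum in closed form.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    base_xy = np.array(
        [[i * 1.5 - 3.0, j * 1.5 - 1.5, 0.0] for i in range(5) for j in range(3)]
    )
    n_arm = 5
    arm_local = np.column_stack(
        [np.linspace(arm_length / n_arm, arm_length, n_arm), np.zeros(n_arm), np.zeros(n_arm)]
    )
    alpha_max = math.asin(min(1.0, amplitude / arm_length))
    frames = []
    for t in range(n_frames):
        alpha = alpha_max * (1.0 - math.cos(2.0 * math.pi * t / (n_frames - 1))) / 2.0
        # hinge at the origin: rotate the arm about y so its tip rises to +z
        rot = np.array(
            [
                [math.cos(alpha), 0.0, -math.sin(alpha)],
                [0.0, 1.0, 0.0],
                [math.sin(alpha), 0.0, math.cos(alpha)],
            ]
        )
        arm = arm_local @ rot.T
        positions = np.vstack([base_xy, arm])
        frames.append(
            _pseudo_model(positions, np.full(len(positions), atom_radius), frame_id=t)
        )
    return Trajectory(frames=frames)


def open_close_expected_max_heights(
    n_frames: int,
    amplitude: float = 3.0,
    arm_length: float = 6.0,
    atom_radius: float = 0.8,
) -> np.ndarray:
    """Closed-form per-frame envelope maximum of the hinge toy, after grounding.

    All atoms share one radius, so grounding lifts centres to ``z = r`` and
    the envelope maximum is ``2 r + L sin(alpha_t)``.
    """
    alpha_max = math.asin(min(1.0, amplitude / arm_length))
    t = np.arange(n_frames)
    alpha = alpha_max * (1.0 - np.cos(2.0 * np.pi * t / (n_frames - 1))) / 2.0
    return 2.0 * atom_radius + arm_length * np.sin(alpha)


# ---------------------------------------------------------------------------
# Declarative fixture specs (CLI entry point)
# ---------------------------------------------------------------------------

_KINDS = {
    "single_atom",
    "random_cloud",
    "helix_filament",
    "multi_blob",
    "open_close_trajectory",
}


@dataclass(frozen=True)
class FixtureSpec:
    """Named synthetic-structure recipe: kind, parameters and seed."""

    kind: str
    parameters: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; one of {sorted(_KINDS)}")


def make_fixture(spec: FixtureSpec) -> AtomModel | Trajectory:
    """Materialize a :class:`FixtureSpec` (deterministic per kind+params+seed)."""
    params = dict(spec.parameters)
    if spec.kind == "single_atom":
        radius = params.pop("radius", 0.3)
        if params:
            raise ValueError(f"unused parameters: {params}")
        return _pseudo_model(np.zeros((1, 3)), np.array([radius]))
    if spec.kind == "random_cloud":
        return make_random_cloud(seed=spec.seed, **params)
    if spec.kind == "helix_filament":
        return make_helix_filament(seed=spec.seed, **params)
    if spec.kind == "multi_blob":
        return make_multi_blob(seed=spec.seed, **params)
    if spec.kind == "open_close_trajectory":
        return make_open_close_trajectory(seed=spec.seed, **params)
    raise AssertionError("unreachable")
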