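"""Atomic structure I/O and rigid placement on the AFM substrate.

Molecules are represented as hard ("van der Waals") spheres centred at the
atom positions.  All coordinates inside the package are in nanometres; PDB
files, which store angstroms, are converted on read and write.  The substrate
is the plane ``z = 0`` and a *grounded* model is one whose lowest sphere
point touches that plane.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

logger = logging.getLogger(__name__)

#: Default hard-sphere radii per element, in nm (Bondi-style values).
VDW_RADII_NM: dict[str, float] = {
    "H": 0.110,
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
    "S": 0.180,
    "P": 0.180,
}

#: Radius used for elements missing from the table (carbon-like), nm.
FALLBACK_RADIUS_NM = 0.170

ANGSTROM_PER_NM = 10.0


class EmptyModelError(ValueError):
    """Raised when an operation requires at least one atom."""


@dataclass
class AtomModel:
    """A rigid molecule as spheres on (or above) the substrate plane.

    Parameters
    ----------
    positions:
        ``(n, 3)`` array of atom centres in nm.
    elements:
        Element symbols, one per atom.
    radii:
        Hard-sphere radii in nm, one per atom (must be positive).
    labels:
        Optional per-atom chain/residue identifiers.
    frame_id:
        Optional trajectory frame index.
    """

    positions: np.ndarray
    elements: list[str]
    radii: np.ndarray
    labels: list[str] | None = None
    frame_id: int | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=float).reshape(-1)
        self.elements = list(self.elements)
        n = len(self.positions)
        if len(self.elements) != n or len(self.radii) != n:
            raise ValueError(
                f"inconsistent atom counts: {n} positions, "
                f"{len(self.elements)} elements, {len(self.radii)} radii"
            )
        if self.labels is not None and len(self.labels) != n:
            raise ValueError("labels length does not match atom count")
        if n and np.any(self.radii <= 0):
            raise ValueError("all radii must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    def centroid(self) -> np.ndarray:
        if self.n_atoms == 0:
            raise EmptyModelError("centroid of an empty model is undefined")
        return self.positions.mean(axis=0)

    def top_height(self) -> float:
        """Highest point of the sphere envelope, ``max(z_i + r_i)``, nm."""
        if self.n_atoms == 0:
            return 0.0
        return float(np.max(self.positions[:, 2] + self.radii))

    def with_positions(self, positions: np.ndarray) -> "AtomModel":
        return replace(self, positions=np.asarray(positions, dtype=float))

    def copy(self) -> "AtomModel":
        return replace(
            self,
            positions=self.positions.copy(),
            elements=list(self.elements),
            radii=self.radii.copy(),
            labels=None if self.labels is None else list(self.labels),
        )


class Orientation:
    """A proper rotation of 3-space (molecular orientation on the substrate).

    Thin wrapper around :class:`scipy.spatial.transform.Rotation` with the
    conventions used throughout the package: intrinsic ZYZ Euler angles in
    degrees, quaternions in scalar-last ``(x, y, z, w)`` order.
    """

    __slots__ = ("_rot",)

    def __init__(self, rotation: Rotation):
        if rotation.single is False:
            raise ValueError("Orientation wraps a single rotation")
        self._rot = rotation

    # -- constructors ------------------------------------------------
    @classmethod
    def identity(cls) -> "Orientation":
        return cls(Rotation.identity())

    @classmethod
    def from_zyz_deg(cls, alpha: float, beta: float, gamma: float) -> "Orientation":
        return cls(Rotation.from_euler("ZYZ", [alpha, beta, gamma], degrees=True))

    @classmethod
    def from_quat(cls, quat: Sequence[float]) -> "Orientation":
        return cls(Rotation.from_quat(np.asarray(quat, dtype=float)))

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "Orientation":
        return cls(Rotation.from_matrix(np.asarray(matrix, dtype=float)))

    @classmethod
    def from_axis_angle_deg(cls, axis: Sequence[float], angle_deg: float) -> "Orientation":
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        return cls(Rotation.from_rotvec(np.deg2rad(angle_deg) * axis))

    @classmethod
    def random(cls, seed: int) -> "Orientation":
        return cls(Rotation.random(rng=np.random.default_rng(seed)))

    # -- views -------------------------------------------------------
    @property
    def rotation(self) -> Rotation:
        return self._rot

    @property
    def matrix(self) -> np.ndarray:
        return self._rot.as_matrix()

    def as_quat(self) -> np.ndarray:
        return self._rot.as_quat()

    def as_zyz_deg(self) -> np.ndarray:
        import warnings

        with warnings.catch_warnings():
            # gimbal-locked angles are still a valid representation
            warnings.simplefilter("ignore", UserWarning)
            return self._rot.as_euler("ZYZ", degrees=True)

    # -- algebra -----------------------------------------------------
    def apply(self, points: np.ndarray) -> np.ndarray:
        return self._rot.apply(np.asarray(points, dtype=float))

    def compose(self, other: "Orientation") -> "Orientation":
        """Rotation equal to applying ``other`` first, then ``self``."""
        return Orientation(self._rot * other._rot)

    def inv(self) -> "Orientation":
        return Orientation(self._rot.inv())

    def angle_to(self, other: "Orientation") -> float:
        """Geodesic distance on SO(3) in degrees."""
        return float(np.rad2deg((self._rot.inv() * other._rot).magnitude()))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        a, b, g = self.as_zyz_deg()
        return f"Orientation(zyz_deg=({a:.3f}, {b:.3f}, {g:.3f}))"


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


def _element_symbol(atom: gemmi.Atom) -> str:
    name = atom.element.name
    if name and name != "X":
        return name
    # fall back on the leading letters of the atom name
    stripped = atom.name.strip().lstrip("0123456789")
    return (stripped[:1] or "X").upper()


def _model_from_gemmi(
    model: gemmi.Model,
    *,
    keep_waters: bool,
    altlocs: tuple[str, ...],
    frame_id: int | None,
) -> AtomModel:
    positions: list[tuple[float, float, float]] = []
    elements: list[str] = []
    labels: list[str] = []
    for chain in model:
        for residue in chain:
            if not keep_waters and (residue.is_water() or residue.name in _WATER_NAMES):
                continue
            for atom in residue:
                if atom.altloc not in ("", "\0") and atom.altloc not in altlocs:
                    continue
                p = atom.pos
                positions.append(
                    (p.x / ANGSTROM_PER_NM, p.y / ANGSTROM_PER_NM, p.z / ANGSTROM_PER_NM)
                )
                elements.append(_element_symbol(atom))
                labels.append(f"{chain.name}/{residue.name}{residue.seqid.num}")
    n = len(positions)
    model_out = AtomModel(
        positions=np.asarray(positions, dtype=float).reshape(n, 3),
        elements=elements,
        radii=np.full(n, FALLBACK_RADIUS_NM),
        labels=labels,
        frame_id=frame_id,
    )
    return assign_vdw_radii(model_out)


def read_pdb(
    path: str | Path,
    *,
    keep_waters: bool = False,
    altlocs: tuple[str, ...] = ("A",),
) -> AtomModel:
    """Read the first model of a PDB file into an :class:`AtomModel`.

    Coordinates are converted from angstrom to nm.  Waters are dropped by
    default and only blank/``A`` alternate locations are kept.  Radii are
    assigned from :data:`VDW_RADII_NM` on read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    structure = gemmi.read_structure(str(path))
    if len(structure) == 0:
        raise EmptyModelError(f"no models in {path}")
    model = _model_from_gemmi(
        structure[0], keep_waters=keep_waters, altlocs=altlocs, frame_id=None
    )
    if model.n_atoms == 0:
        raise EmptyModelError(f"no atoms left after filtering in {path}")
    return model


def write_pdb(models: AtomModel | Iterable[AtomModel], path: str | Path) -> None:
    """Write one model (or an iterable of frames as MODEL blocks) as PDB.

    Pseudo-atoms are emitted as one-atom residues; coordinates are converted
    back to angstrom.
    """
    if isinstance(models, AtomModel):
        models = [models]
    models = list(models)
    if not models:
        raise EmptyModelError("nothing to write")
    structure = gemmi.Structure()
    structure.name = "afmsim"
    for k, m in enumerate(models):
        gmodel = gemmi.Model(k + 1)
        chain = gemmi.Chain("A")
        for i in range(m.n_atoms):
            residue = gemmi.Residue()
            residue.name = "DUM"
            residue.seqid = gemmi.SeqId(i + 1, " ")
            atom = gemmi.Atom()
            elem = m.elements[i]
            atom.name = elem[:4]
            atom.element = gemmi.Element(elem)
            x, y, z = m.positions[i] * ANGSTROM_PER_NM
            atom.pos = gemmi.Position(x, y, z)
            residue.add_atom(atom)
            chain.add_residue(residue)
        gmodel.add_chain(chain)
        structure.add_model(gmodel)
    structure.setup_entities()
    structure.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Radii and placement
# ---------------------------------------------------------------------------


def assign_vdw_radii(
    model: AtomModel, table: Mapping[str, float] | None = None
) -> AtomModel:
    """Return a copy of ``model`` with per-element hard-sphere radii.

    Unknown elements receive :data:`FALLBACK_RADIUS_NM` and a logged warning.
    """
    table = dict(VDW_RADII_NM if table is None else table)
    radii = np.empty(model.n_atoms)
    unknown: set[str] = set()
    for i, element in enumerate(model.elements):
        key = element.capitalize()
        if key in table:
            radii[i] = table[key]
        elif element.upper() in table:
            radii[i] = table[element.upper()]
        else:
            radii[i] = FALLBACK_RADIUS_NM
            unknown.add(element)
    if unknown:
        logger.warning(
            "unknown element(s) %s: using fallback radius %.3f nm",
            sorted(unknown),
            FALLBACK_RADIUS_NM,
        )
    return replace(model, radii=radii)


def orient_and_ground(
    model: AtomModel,
    orientation: Orientation | None = None,
    *,
    center_xy: tuple[float, float] = (0.0, 0.0),
) -> AtomModel:
    """Rotate about the centroid, then rest the molecule on the substrate.

    After the call the lowest point of the sphere envelope touches ``z = 0``
    (``min_i(z_i - r_i) = 0``) and the lateral centroid sits at ``center_xy``.
    """
    if model.n_atoms == 0:
        raise EmptyModelError("cannot ground an empty model")
    if orientation is None:
        orientation = Orientation.identity()
    centroid = model.centroid()
    pos = orientation.apply(model.positions - centroid)
    pos[:, 0] += center_xy[0]
    pos[:, 1] += center_xy[1]
    pos[:, 2] -= np.min(pos[:, 2] - model.radii)
    return model.with_positions(pos)
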