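"""Trajectory metrics: hydrogen-bond occupancy, distances, RMSD and RMSF.

A hydrogen bond is scored geometrically the way MD post-processing tools
conventionally do for kinase–inhibitor hinge contacts: present in a frame
iff the donor-heavy→acceptor-heavy distance is ≤ 3.0 Å and the
donor−H···acceptor angle (vertex at the hydrogen) is ≥ 135°, both
thresholds inclusive. Occupancy is the percentage of frames passing.

RMSD is computed after optimal rigid-body superposition (Kabsch, proper
rotations only) of a selection onto a reference; RMSF is the per-atom
root-mean-square fluctuation about the time-averaged structure after
iterative alignment of all frames to that average.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import InvalidInputError

__all__ = [
    "Atom",
    "Trajectory",
    "HBondSpec",
    "OccupancyResult",
    "DistanceResult",
    "hbond_present",
    "hbond_occupancy",
    "distance_series",
    "rmsd_series",
    "rmsf_profile",
    "read_pdb_trajectory",
    "write_pdb_trajectory",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "BACKBONE_NAMES",
]

#: Atom names treated as protein backbone when selecting from a PDB.
BACKBONE_NAMES = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class Atom:
    """One atom row of the topology annotation."""

    id: int
    name: str
    element: str
    res_id: int
    res_name: str


@dataclass
class Trajectory:
    """Frames × atoms × 3 coordinates in Å with a light atom table."""

    coords: np.ndarray  # (n_frames, n_atoms, 3)
    atoms: list[Atom]
    _index: dict[int, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.ndim != 3 or c.shape[2] != 3:
            raise InvalidInputError(
                f"coords must have shape (n_frames, n_atoms, 3), got {c.shape}"
            )
        if c.shape[1] != len(self.atoms):
            raise InvalidInputError(
                f"{c.shape[1]} coordinate columns but {len(self.atoms)} atoms"
            )
        if not np.all(np.isfinite(c)):
            raise InvalidInputError("coordinates contain NaN/inf")
        self.coords = c
        self._index = {a.id: i for i, a in enumerate(self.atoms)}
        if len(self._index) != len(self.atoms):
            raise InvalidInputError("atom ids must be unique")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def atom_index(self, atom_id: int) -> int:
        try:
            return self._index[atom_id]
        except KeyError:
            raise InvalidInputError(f"no atom with id {atom_id} in trajectory") from None

    def select_ids(
        self, names: Optional[Sequence[str]] = None, res_ids: Optional[Sequence[int]] = None
    ) -> list[int]:
        """Atom ids matching the given atom names and/or residue ids."""
        out = []
        for a in self.atoms:
            if names is not None and a.name not in names:
                continue
            if res_ids is not None and a.res_id not in res_ids:
                continue
            out.append(a.id)
        return out


@dataclass(frozen=True)
class HBondSpec:
    """Donor-heavy / hydrogen / acceptor-heavy triple with geometric cutoffs."""

    donor_heavy: int
    hydrogen: int
    acceptor_heavy: int
    distance_cutoff: float = 3.0  # Å, donor-heavy to acceptor-heavy
    angle_cutoff: float = 135.0  # degrees, donor−H···acceptor at the H

    def __post_init__(self) -> None:
        ids = (self.donor_heavy, self.hydrogen, self.acceptor_heavy)
        if len(set(ids)) != 3:
            raise InvalidInputError(f"H-bond spec needs three distinct atoms, got {ids}")
        if self.distance_cutoff <= 0 or self.angle_cutoff <= 0:
            raise InvalidInputError("H-bond cutoffs must be positive")


@dataclass(frozen=True)
class OccupancyResult:
    """Frame counts and the derived occupancy percentage."""

    n_frames: int
    n_present: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_present <= self.n_frames):
            raise InvalidInputError(
                f"0 ≤ n_present ≤ n_frames violated: {self.n_present}/{self.n_frames}"
            )

    @property
    def occupancy_percent(self) -> float:
        return 100.0 * self.n_present / self.n_frames


class DistanceResult(NamedTuple):
    """Per-frame distances in Å and their arithmetic mean."""

    values: np.ndarray
    mean: float


def _angle_deg(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    u, w = a - vertex, b - vertex
    cosang = np.dot(u, w) / (np.linalg.norm(u) * np.linalg.norm(w))
    return math.degrees(math.acos(min(1.0, max(-1.0, cosang))))


def hbond_present(traj: Trajectory, frame: int, spec: HBondSpec) -> bool:
    """Is the hydrogen bond formed in this frame?

    True iff donor-heavy→acceptor distance ≤ cutoff and the D−H···A angle
    at the hydrogen ≥ cutoff; both comparisons inclusive, so a geometry at
    exactly 3.0 Å and 135° counts as bonded.
    """
    xyz = traj.coords[frame]
    d = xyz[traj.atom_index(spec.donor_heavy)]
    h = xyz[traj.atom_index(spec.hydrogen)]
    a = xyz[traj.atom_index(spec.acceptor_heavy)]
    # 1e-9 guard keeps the inclusive thresholds inclusive under float
    # round-off (a geometry constructed at exactly 3.0 Å must count)
    if float(np.linalg.norm(a - d)) > spec.distance_cutoff + 1e-9:
        return False
    return _angle_deg(d, h, a) >= spec.angle_cutoff - 1e-9


def hbond_occupancy(traj: Trajectory, spec: HBondSpec) -> OccupancyResult:
    """Count frames where the bond is present and report the percentage."""
    if traj.n_frames < 1:
        raise InvalidInputError("occupancy undefined for an empty trajectory")
    n_present = sum(hbond_present(traj, f, spec) for f in range(traj.n_frames))
    return OccupancyResult(n_frames=traj.n_frames, n_present=n_present)


def distance_series(traj: Trajectory, atom_i: int, atom_j: int) -> DistanceResult:
    """Euclidean distance between two atoms in every frame, on raw
    (unaligned) coordinates, plus the arithmetic mean."""
    if atom_i == atom_j:
        raise InvalidInputError(f"distance requires two distinct atoms, got id {atom_i} twice")
    i, j = traj.atom_index(atom_i), traj.atom_index(atom_j)
    d = np.linalg.norm(traj.coords[:, i] - traj.coords[:, j], axis=1)
    return DistanceResult(values=d, mean=float(d.mean()))


def _superpose(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Kabsch: return mobile optimally rotated/translated onto reference."""
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    return rot.apply(mob_c) + reference.mean(axis=0)


def rmsd_series(
    traj: Trajectory, reference: np.ndarray, selection: Sequence[int]
) -> np.ndarray:
    """Per-frame RMSD (Å) of a selection after optimal superposition.

    ``reference`` must hold one coordinate row per selected atom, in the
    same order as ``selection``.
    """
    sel = list(selection)
    if not sel:
        raise InvalidInputError("RMSD selection is empty")
    ref = np.asarray(reference, dtype=float)
    if ref.shape != (len(sel), 3):
        raise InvalidInputError(
            f"reference shape {ref.shape} does not match selection of {len(sel)} atoms"
        )
    idx = [traj.atom_index(a) for a in sel]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        fitted = _superpose(traj.coords[f, idx], ref)
        out[f] = math.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1)))
    return out


def rmsf_profile(
    traj: Trajectory, selection: Sequence[int], align_passes: int = 2
) -> np.ndarray:
    """Per-atom RMSF (Å) about the time-averaged structure.

    All frames are superposed onto the running mean structure; the mean is
    recomputed and the alignment repeated (2 passes by default), then each
    atom's fluctuation is √⟨|xᵢ(t) − ⟨xᵢ⟩|²⟩ over frames.
    """
    if traj.n_frames < 2:
        raise InvalidInputError("RMSF needs at least two frames")
    sel = list(selection)
    if not sel:
        raise InvalidInputError("RMSF selection is empty")
    idx = [traj.atom_index(a) for a in sel]
    frames = traj.coords[:, idx].copy()
    mean = frames.mean(axis=0)
    for _ in range(max(1, align_passes)):
        frames = np.stack([_superpose(f, mean) for f in frames])
        mean = frames.mean(axis=0)
    return np.sqrt(np.mean(np.sum((frames - mean) ** 2, axis=2), axis=0))


# ---------------------------------------------------------------------------
# Multi-model PDB and XYZ I/O

def write_pdb_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write frames as MODEL/ATOM/ENDMDL records (1-based serials)."""
    path = Path(path)
    with path.open("w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"MODEL     {f + 1:4d}\n")
            for a, (x, y, z) in zip(traj.atoms, traj.coords[f]):
                name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
                fh.write(
                    f"ATOM  {a.id + 1:5d} {name}{'':1s}{a.res_name:<3s} A"
                    f"{a.res_id:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_pdb_trajectory(path: str | Path) -> Trajectory:
    """Read a multi-model PDB into a trajectory.

    PDB serials are 1-based; internal atom ids are 0-based (serial − 1).
    Atom order and count must be identical across models.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("traj", str(path))
    models = list(structure)
    if not models:
        raise InvalidInputError(f"{path}: no models found")
    atoms0 = list(models[0].get_atoms())
    table = [
        Atom(
            id=a.serial_number - 1,
            name=a.get_name(),
            element=(a.element or "").strip() or a.get_name()[0],
            res_id=a.get_parent().id[1],
            res_name=a.get_parent().get_resname().strip(),
        )
        for a in atoms0
    ]
    coords = np.empty((len(models), len(table), 3))
    for f, model in enumerate(models):
        frame_atoms = list(model.get_atoms())
        if len(frame_atoms) != len(table):
            raise InvalidInputError(
                f"{path}: model {f + 1} has {len(frame_atoms)} atoms, "
                f"expected {len(table)}"
            )
        coords[f] = [a.coord for a in frame_atoms]
    return Trajectory(coords=coords, atoms=table)


def write_xyz_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write frames in extended-free XYZ (element + coordinates per line)."""
    path = Path(path)
    with path.open("w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"frame {f}\n")
            for a, (x, y, z) in zip(traj.atoms, traj.coords[f]):
                fh.write(f"{a.element:<2s} {x:14.8f} {y:14.8f} {z:14.8f}\n")


def read_xyz_trajectory(path: str | Path) -> Trajectory:
    """Read a multi-frame XYZ file; the atom table is synthesised from the
    element column (ids 0…n−1, one pseudo-residue)."""
    lines = Path(path).read_text().splitlines()
    frames: list[list[list[float]]] = []
    elements: list[str] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise InvalidInputError(f"{path}: expected atom count at line {i + 1}") from exc
        block = lines[i + 2 : i + 2 + n]
        if len(block) != n:
            raise InvalidInputError(f"{path}: truncated frame at line {i + 1}")
        frame = []
        frame_elems = []
        for ln in block:
            parts = ln.split()
            frame_elems.append(parts[0])
            frame.append([float(v) for v in parts[1:4]])
        if not elements:
            elements = frame_elems
        elif frame_elems != elements:
            raise InvalidInputError(f"{path}: element order changes between frames")
        frames.append(frame)
        i += 2 + n
    if not frames:
        raise InvalidInputError(f"{path}: no frames found")
    atoms = [
        Atom(id=j, name=e, element=e, res_id=1, res_name="UNK")
        for j, e in enumerate(elements)
    ]
    return Trajectory(coords=np.asarray(frames), atoms=atoms)
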