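"""Structure and trajectory I/O plus rigid-body superposition primitives.

Structures are read through gemmi (PDB and mmCIF) into a flat atom table
that keeps author residue numbering as found in the file.  A per-structure
``numbering_offset`` maps file numbering to mature-peptide numbering
(signal peptide removed); it defaults to 0 and is applied by
:func:`select_atoms`, never at read time.

Altloc policy: for each (chain, residue, atom name) the highest-occupancy
conformer is kept, ties broken by order of appearance.  Hydrogens are
dropped in selections by default; all geometry here is heavy-atom.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

from .errors import (
    DegenerateGeometryError,
    EmptySelectionError,
    FormatError,
    NotFoundError,
)

__all__ = [
    "Atom",
    "Structure",
    "PointSet",
    "RigidTransform",
    "load_structure",
    "write_structure",
    "load_trajectory",
    "load_xyz_trajectory",
    "select_atoms",
    "kabsch_superpose",
    "rotation_angle",
]


@dataclass
class Atom:
    """One atom: chain, author residue number/name, atom name, element, position (Å)."""

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError("atom position must be a finite 3-vector")
        if not self.atom_name:
            raise ValueError("atom_name must be non-empty")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Structure:
    """An ordered atom collection for one model of one file."""

    atoms: list[Atom]
    model_index: int = 0
    numbering_offset: int = 0

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def with_coords(self, xyz: np.ndarray) -> "Structure":
        """Copy of this structure with positions replaced (same topology)."""
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [
            Atom(a.chain_id, a.residue_number, a.residue_name, a.atom_name, a.element, p)
            for a, p in zip(self.atoms, xyz)
        ]
        return Structure(atoms, self.model_index, self.numbering_offset)


@dataclass
class PointSet:
    """Labelled 3-D points, the currency of all geometry operations."""

    labels: list[str]
    points: np.ndarray
    n_missing: int = 0  # residues in range lacking the requested atom

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if len(self.labels) != len(self.points):
            raise ValueError("labels and points must have equal length")
        if len(self.points) < 1:
            raise ValueError("a PointSet needs at least one point")

    def __len__(self) -> int:
        return len(self.points)

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["label", "x", "y", "z"])
            for lab, p in zip(self.labels, self.points):
                w.writerow([lab, f"{p[0]:.6f}", f"{p[1]:.6f}", f"{p[2]:.6f}"])


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        R = self.rotation
        if R.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or not np.isclose(
            np.linalg.det(R), 1.0, atol=1e-8
        ):
            raise ValueError("rotation must be proper orthogonal (det +1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


# ---------------------------------------------------------------------------
# reading / writing


def _coor_format(path: Path, format: str) -> gemmi.CoorFormat:
    if format == "pdb":
        return gemmi.CoorFormat.Pdb
    if format == "mmcif":
        return gemmi.CoorFormat.Mmcif
    if format == "auto":
        suffix = path.suffix.lower()
        if suffix in (".pdb", ".ent"):
            return gemmi.CoorFormat.Pdb
        if suffix in (".cif", ".mmcif"):
            return gemmi.CoorFormat.Mmcif
        raise FormatError(f"cannot infer structure format from suffix {suffix!r}")
    raise FormatError(f"unknown format {format!r}")


def _resolve_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Highest-occupancy conformer per atom name; ties broken by file order."""
    best: dict[str, gemmi.Atom] = {}
    for at in residue:
        prev = best.get(at.name)
        if prev is None or at.occ > prev.occ:
            best[at.name] = at
    # preserve file order of the surviving atoms
    chosen = set(id(a) for a in best.values())
    return [a for a in residue if id(a) in chosen]


def load_structure(
    path: str | Path,
    format: str = "auto",
    model: int = 0,
    numbering_offset: int = 0,
) -> Structure:
    """Read one model from a PDB or mmCIF file.

    ``model`` is a zero-based model index.  Residue numbers are kept exactly
    as in the file; ``numbering_offset`` is stored for later selections.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    fmt = _coor_format(path, format)
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"could not parse {path}: {exc}") from exc
    if model < 0 or model >= len(st):
        raise NotFoundError(
            f"model index {model} out of range; file has {len(st)} model(s)"
        )
    gmodel = st[model]
    atoms: list[Atom] = []
    for chain in gmodel:
        for residue in chain:
            for at in _resolve_altlocs(residue):
                atoms.append(
                    Atom(
                        chain_id=chain.name,
                        residue_number=residue.seqid.num,
                        residue_name=residue.name,
                        atom_name=at.name,
                        element=at.element.name,
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    )
                )
    return Structure(atoms, model_index=model, numbering_offset=numbering_offset)


def _to_gemmi(frames: Sequence[Structure], name: str = "ampardyn") -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = name
    for i, frame in enumerate(frames):
        model = gemmi.Model(i + 1)
        chain_map: dict[str, gemmi.Chain] = {}
        for a in frame.atoms:
            chain = chain_map.get(a.chain_id)
            if chain is None:
                chain = gemmi.Chain(a.chain_id)
                chain_map[a.chain_id] = chain
            if len(chain) == 0 or chain[-1].seqid.num != a.residue_number:
                res = gemmi.Residue()
                res.name = a.residue_name
                res.seqid = gemmi.SeqId(a.residue_number, " ")
                chain.add_residue(res)
            res = chain[-1]
            gat = gemmi.Atom()
            gat.name = a.atom_name
            gat.element = gemmi.Element(a.element)
            gat.pos = gemmi.Position(*a.position)
            gat.occ = 1.0
            res.add_atom(gat)
        for chain in chain_map.values():
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    return st


def write_structure(
    s: Structure | Sequence[Structure], path: str | Path, format: str = "auto"
) -> None:
    """Write one structure (or a frame list as a multi-model PDB)."""
    frames = [s] if isinstance(s, Structure) else list(s)
    path = Path(path)
    fmt = _coor_format(path, format)
    st = _to_gemmi(frames)
    if fmt == gemmi.CoorFormat.Pdb:
        st.write_pdb(str(path))
    else:
        doc = st.make_mmcif_document()
        doc.write_file(str(path))


def load_trajectory(
    path: str | Path, format: str = "auto", numbering_offset: int = 0
) -> list[Structure]:
    """Read all models of a multi-model PDB/mmCIF as an ordered frame list."""
    path = Path(path)
    fmt = _coor_format(path, format)
    st = gemmi.read_structure(str(path), format=fmt)
    return [
        load_structure(path, format=format, model=i, numbering_offset=numbering_offset)
        for i in range(len(st))
    ]


def load_xyz_trajectory(path: str | Path, topology: Structure) -> list[Structure]:
    """Read a plain-text XYZ frame series onto a known topology.

    Each frame: atom count line, comment line, then ``symbol x y z`` rows.
    The atom count must match the topology; coordinates replace the
    topology's positions frame by frame.
    """
    frames: list[Structure] = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError as exc:
            raise FormatError(f"bad XYZ atom count at line {i + 1}") from exc
        if n != len(topology.atoms):
            raise FormatError(
                f"frame at line {i + 1} has {n} atoms, topology has {len(topology.atoms)}"
            )
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise FormatError(f"truncated XYZ frame at line {i + 1}")
        xyz = np.empty((n, 3))
        for j, row in enumerate(block):
            parts = row.split()
            if len(parts) < 4:
                raise FormatError(f"bad XYZ row at line {i + 3 + j}")
            xyz[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frames.append(topology.with_coords(xyz))
        i += 2 + n
    return frames


# ---------------------------------------------------------------------------
# selections


def select_atoms(
    s: Structure,
    chain: str,
    residue_ranges: Sequence[tuple[int, int]],
    atom_name: str = "CA",
    include_hydrogens: bool = False,
) -> PointSet:
    """Select one named atom per residue over inclusive ranges.

    Ranges are in *mature-peptide* numbering; the structure's
    ``numbering_offset`` is added to file numbers before matching.
    Residues present but lacking the atom are skipped and counted in
    ``PointSet.n_missing``.
    """
    if not residue_ranges:
        raise ValueError("residue_ranges must be non-empty")
    for lo, hi in residue_ranges:
        if lo > hi:
            raise ValueError(f"invalid range ({lo}, {hi}): low > high")

    def in_ranges(num: int) -> bool:
        return any(lo <= num <= hi for lo, hi in residue_ranges)

    per_residue: dict[int, Atom] = {}
    residues_seen: set[int] = set()
    for a in s.atoms:
        if a.chain_id != chain:
            continue
        mature = a.residue_number + s.numbering_offset
        if not in_ranges(mature):
            continue
        residues_seen.add(mature)
        if a.atom_name != atom_name:
            continue
        if a.is_hydrogen and not include_hydrogens:
            continue
        per_residue.setdefault(mature, a)

    if not per_residue:
        raise EmptySelectionError(
            f"no {atom_name} atoms in chain {chain!r} over ranges {list(residue_ranges)}"
        )
    numbers = sorted(per_residue)
    labels = [f"{chain}:{n}" for n in numbers]
    points = np.array([per_residue[n].position for n in numbers])
    return PointSet(labels, points, n_missing=len(residues_seen) - len(per_residue))


def iter_residue_atoms(
    s: Structure,
    chain: str,
    residue_ranges: Sequence[tuple[int, int]] | None = None,
    include_hydrogens: bool = False,
) -> Iterable[tuple[tuple[str, int, str], list[Atom]]]:
    """Yield ((chain, mature number, residue name), heavy atoms) per residue."""
    groups: dict[tuple[int, str], list[Atom]] = {}
    order: list[tuple[int, str]] = []
    for a in s.atoms:
        if a.chain_id != chain:
            continue
        mature = a.residue_number + s.numbering_offset
        if residue_ranges is not None and not any(
            lo <= mature <= hi for lo, hi in residue_ranges
        ):
            continue
        if a.is_hydrogen and not include_hydrogens:
            continue
        key = (mature, a.residue_name)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(a)
    for num, name in order:
        yield (chain, num, name), groups[(num, name)]


# ---------------------------------------------------------------------------
# superposition


def kabsch_superpose(
    mobile: PointSet, reference: PointSet
) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the optimal proper transform and the post-fit r.m.s.d. (Å).
    """
    if len(mobile) != len(reference):
        raise ValueError(
            f"point counts differ: {len(mobile)} vs {len(reference)}"
        )
    if len(mobile) < 3:
        raise ValueError("superposition needs at least 3 points")
    P = mobile.points
    Q = reference.points
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    # collinear sets leave the rotation about the common axis undetermined
    sv = np.linalg.svd(P0, compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise DegenerateGeometryError("mobile points are (nearly) collinear")
    rot, _ = Rotation.align_vectors(Q0, P0)
    R = rot.as_matrix()
    t = cq - R @ cp
    transform = RigidTransform(R, t)
    diff = transform.apply(P) - Q
    rmsd = float(np.sqrt((diff**2).sum() / len(P)))
    return transform, rmsd


def rotation_angle(t: RigidTransform) -> float:
    """Rotation magnitude of a rigid transform, degrees in [0, 180]."""
    tr = float(np.trace(t.rotation))
    return float(np.degrees(np.arccos(np.clip((tr - 1.0) / 2.0, -1.0, 1.0))))
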