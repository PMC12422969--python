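"""Lobe-centre-of-mass conformational coordinates for two-lobed dimers.

Each subunit of the dimer is partitioned into an upper and a lower lobe
(clamshell halves) and reduced to Cα centroids:

* ``com1``/``com2`` — upper/lower lobe of subunit 1
* ``com3``/``com4`` — upper/lower lobe of subunit 2
* ``com13``/``com24`` — joint centroids of both upper / both lower lobes

Two scalar coordinates summarise the dimer conformation:

* **displacement torsion** — the signed dihedral over (com2, com1, com3,
  com4); the com1–com3 axis is the rotation axis, and the angle captures
  rotation of the two lower lobes relative to each other.  Near 0° for
  "flat" dimers, around −25° to −30° for displaced ones.
* **opening angle** — the signed angle between com13→com2 and com13→com4
  after projecting both onto the plane perpendicular to the axis running
  from com24 to a ghost point g2 placed 0.5 Å from com24 along the normal
  of the (com24, com1, com3) plane.  The projection removes the component
  of the angle that merely reflects displacement.

Angles are handled in radians internally and reported in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError
from .structio import PointSet, Structure, select_atoms

__all__ = [
    "LobeDefinition",
    "LobeCentroids",
    "CoordPair",
    "DEFAULT_LOBES",
    "dihedral",
    "lobe_centroids",
    "displacement_torsion",
    "opening_angle",
    "coords_series",
]


@dataclass(frozen=True)
class LobeDefinition:
    """Residue ranges (mature numbering, inclusive) defining the two lobes."""

    upper_ranges: tuple[tuple[int, int], ...]
    lower_ranges: tuple[tuple[int, int], ...]
    atom_name: str = "CA"

    def __post_init__(self):
        if not self.upper_ranges or not self.lower_ranges:
            raise ValueError("both lobes need at least one residue range")
        upper = set()
        for lo, hi in self.upper_ranges:
            upper.update(range(lo, hi + 1))
        for lo, hi in self.lower_ranges:
            if any(lo <= r <= hi for r in upper):
                raise ValueError("upper and lower lobe ranges overlap")


#: Clamshell partition of the receptor N-terminal domain used throughout:
#: upper lobe residues 117–243 and 354–380, lower lobe 1–116 and 244–353.
DEFAULT_LOBES = LobeDefinition(
    upper_ranges=((117, 243), (354, 380)),
    lower_ranges=((1, 116), (244, 353)),
)


@dataclass
class LobeCentroids:
    """The six lobe centroids plus the ghost point g2."""

    com1: np.ndarray
    com2: np.ndarray
    com3: np.ndarray
    com4: np.ndarray
    com13: np.ndarray
    com24: np.ndarray
    g2: np.ndarray


@dataclass(frozen=True)
class CoordPair:
    displacement_torsion: float  # degrees, signed, (-180, 180]
    opening_angle: float  # degrees, signed, (-180, 180]


def dihedral(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray) -> float:
    """Signed dihedral angle (radians) over four points, IUPAC atan2 convention."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if nb2 == 0 or np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise DegenerateGeometryError("dihedral undefined: collinear or coincident points")
    m = np.cross(n1, b2 / nb2)
    return float(np.arctan2(np.dot(m, n2), np.dot(n1, n2)))


def _ghost_point(com24: np.ndarray, com1: np.ndarray, com3: np.ndarray) -> np.ndarray:
    """g2 = com24 + 0.5 Å along the normal of the (com24, com1, com3) plane."""
    n = np.cross(com1 - com24, com3 - com24)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        raise DegenerateGeometryError("ghost point undefined: com1, com3, com24 collinear")
    return com24 + 0.5 * n / nn


def lobe_centroids(
    dimer: Structure | tuple[Structure, Structure],
    lobes: LobeDefinition = DEFAULT_LOBES,
    chains: tuple[str, str] = ("A", "B"),
) -> LobeCentroids:
    """Centroids of the four lobes, the joint centroids, and the ghost point.

    ``dimer`` is either one structure holding both subunits (selected by
    ``chains``) or a pair of structures, one per subunit.  Centroids are
    unweighted means of the selected atom positions (all-Cα selections make
    this identical to mass weighting).
    """
    if isinstance(dimer, Structure):
        pair = (dimer, dimer)
    else:
        pair = dimer

    def sel(sub: int, ranges) -> PointSet:
        return select_atoms(pair[sub], chains[sub], ranges, lobes.atom_name)

    up1 = sel(0, lobes.upper_ranges)
    lo1 = sel(0, lobes.lower_ranges)
    up2 = sel(1, lobes.upper_ranges)
    lo2 = sel(1, lobes.lower_ranges)
    for ps, what in ((up1, "upper-1"), (lo1, "lower-1"), (up2, "upper-2"), (lo2, "lower-2")):
        if len(ps) < 3:
            raise DegenerateGeometryError(f"lobe {what} has fewer than 3 atoms")

    com1 = up1.centroid()
    com2 = lo1.centroid()
    com3 = up2.centroid()
    com4 = lo2.centroid()
    com13 = np.vstack([up1.points, up2.points]).mean(axis=0)
    com24 = np.vstack([lo1.points, lo2.points]).mean(axis=0)
    g2 = _ghost_point(com24, com1, com3)
    return LobeCentroids(com1, com2, com3, com4, com13, com24, g2)


def displacement_torsion(c: LobeCentroids) -> float:
    """Signed dihedral (degrees) over (com2, com1, com3, com4)."""
    return float(np.degrees(dihedral(c.com2, c.com1, c.com3, c.com4)))


def opening_angle(c: LobeCentroids) -> float:
    """Signed projected angle (degrees) from com13→com2 to com13→com4.

    Both vectors are projected onto the plane perpendicular to the
    com24→g2 axis; the sign follows the right-hand rule about that axis.
    """
    axis = c.g2 - c.com24
    na = np.linalg.norm(axis)
    if na < 1e-12:
        raise DegenerateGeometryError("projection axis has zero length")
    a = axis / na
    v1 = c.com2 - c.com13
    v2 = c.com4 - c.com13
    p1 = v1 - np.dot(v1, a) * a
    p2 = v2 - np.dot(v2, a) * a
    if np.linalg.norm(p1) < 1e-12 or np.linalg.norm(p2) < 1e-12:
        raise DegenerateGeometryError("a lobe vector projects to zero length")
    return float(np.degrees(np.arctan2(np.dot(np.cross(p1, p2), a), np.dot(p1, p2))))


def coords_pair(
    dimer: Structure | tuple[Structure, Structure],
    lobes: LobeDefinition = DEFAULT_LOBES,
    chains: tuple[str, str] = ("A", "B"),
) -> CoordPair:
    """Both conformational coordinates of one dimer."""
    c = lobe_centroids(dimer, lobes, chains)
    return CoordPair(displacement_torsion(c), opening_angle(c))


def coords_series(
    frames: list[Structure],
    lobes: LobeDefinition = DEFAULT_LOBES,
    chains: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """Per-frame coordinates for an ordered frame series.

    Returns a DataFrame with columns ``frame``, ``torsion_deg``,
    ``opening_deg``; a frame missing a selection raises with its index.
    """
    rows = []
    for i, frame in enumerate(frames):
        try:
            cp = coords_pair(frame, lobes, chains)
        except Exception as exc:
            raise type(exc)(f"frame {i}: {exc}") from exc
        rows.append((i, cp.displacement_torsion, cp.opening_angle))
    return pd.DataFrame(rows, columns=["frame", "torsion_deg", "opening_deg"])
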