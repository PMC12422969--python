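"""Interface distance, displacement and contact-footprint measurements.

Selections are ``(chain_id, residue_ranges)`` pairs; ``residue_ranges`` of
``None`` means the whole chain.  All distances are heavy-atom, in Å.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ComparabilityError, EmptySelectionError, NotFoundError
from .structio import Structure, iter_residue_atoms, select_atoms

__all__ = [
    "Selection",
    "ContactPair",
    "Footprint",
    "com_separation",
    "residue_pair_distance",
    "contact_footprint",
    "footprint_difference",
]

Selection = tuple[str, list[tuple[int, int]] | None]

ResidueId = tuple[str, int, str]  # chain, mature number, residue name


@dataclass(frozen=True)
class ContactPair:
    residue_a: ResidueId
    residue_b: ResidueId
    min_distance: float

    @property
    def key(self) -> tuple[ResidueId, ResidueId]:
        return (self.residue_a, self.residue_b)


@dataclass
class Footprint:
    contacts: list[ContactPair]
    cutoff: float

    def keys(self) -> set[tuple[ResidueId, ResidueId]]:
        return {c.key for c in self.contacts}

    def __len__(self) -> int:
        return len(self.contacts)


def _whole_chain_ranges(s: Structure, chain: str) -> list[tuple[int, int]]:
    nums = [
        a.residue_number + s.numbering_offset for a in s.atoms if a.chain_id == chain
    ]
    if not nums:
        raise EmptySelectionError(f"chain {chain!r} has no atoms")
    return [(min(nums), max(nums))]


def _resolve(s: Structure, sel: Selection) -> tuple[str, list[tuple[int, int]]]:
    chain, ranges = sel
    if ranges is None:
        ranges = _whole_chain_ranges(s, chain)
    return chain, list(ranges)


def com_separation(
    s: Structure, selection_a: Selection, selection_b: Selection, atom_name: str = "CA"
) -> float:
    """Distance between the unweighted Cα centroids of two selections (Å)."""
    ca, ra = _resolve(s, selection_a)
    cb, rb = _resolve(s, selection_b)
    pa = select_atoms(s, ca, ra, atom_name)
    pb = select_atoms(s, cb, rb, atom_name)
    return float(np.linalg.norm(pa.centroid() - pb.centroid()))


def residue_pair_distance(
    s: Structure,
    res_a: tuple[str, int],
    res_b: tuple[str, int],
    atom_rule: str = "CA",
) -> float:
    """Distance between two residues under an atom rule.

    ``atom_rule`` is ``"CA"``, ``"CZ"`` (single named atom each side) or
    ``"closest-heavy"`` (minimum over all heavy-atom pairs).
    """
    if atom_rule not in ("CA", "CZ", "closest-heavy"):
        raise ValueError(f"unknown atom rule {atom_rule!r}")

    def atoms_of(res: tuple[str, int]):
        chain, num = res
        for rid, atoms in iter_residue_atoms(s, chain, [(num, num)]):
            return rid, atoms
        raise NotFoundError(f"residue {chain}:{num} not found")

    (_, _, name_a), atoms_a = atoms_of(res_a)
    (_, _, name_b), atoms_b = atoms_of(res_b)

    if atom_rule == "closest-heavy":
        d = cdist(
            np.array([a.position for a in atoms_a]),
            np.array([a.position for a in atoms_b]),
        )
        return float(d.min())

    def pick(atoms, res, name):
        for a in atoms:
            if a.atom_name == atom_rule:
                return a.position
        raise NotFoundError(
            f"residue {res[0]}:{res[1]} ({name}) has no {atom_rule} atom"
        )

    pa = pick(atoms_a, res_a, name_a)
    pb = pick(atoms_b, res_b, name_b)
    return float(np.linalg.norm(pa - pb))


def contact_footprint(
    s: Structure, selection_a: Selection, selection_b: Selection, cutoff: float = 4.0
) -> Footprint:
    """All residue pairs across the interface within a heavy-atom cutoff.

    A pair is a contact when the minimum distance over heavy-atom pairs is
    at most ``cutoff`` (default 4.0 Å).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ca, ra = _resolve(s, selection_a)
    cb, rb = _resolve(s, selection_b)
    res_a = list(iter_residue_atoms(s, ca, ra))
    res_b = list(iter_residue_atoms(s, cb, rb))
    if not res_a or not res_b:
        raise EmptySelectionError("a footprint selection matched no residues")
    contacts: list[ContactPair] = []
    coords_b = [np.array([a.position for a in atoms]) for _, atoms in res_b]
    for rid_a, atoms_a in res_a:
        xa = np.array([a.position for a in atoms_a])
        for (rid_b, _), xb in zip(res_b, coords_b):
            dmin = float(cdist(xa, xb).min())
            if dmin <= cutoff:
                contacts.append(ContactPair(rid_a, rid_b, dmin))
    return Footprint(contacts, cutoff)


def footprint_difference(
    a: Footprint, b: Footprint
) -> tuple[list[ContactPair], list[ContactPair]]:
    """Contacts lost (in ``a`` not ``b``) and gained (in ``b`` not ``a``).

    Identity is the residue-pair key; distances are ignored.  Footprints
    must share the cutoff to be comparable.
    """
    if a.cutoff != b.cutoff:
        raise ComparabilityError(
            f"cutoffs differ: {a.cutoff} vs {b.cutoff} Å"
        )
    keys_a, keys_b = a.keys(), b.keys()
    lost = [c for c in a.contacts if c.key not in keys_b]
    gained = [c for c in b.contacts if c.key not in keys_a]
    return lost, gained
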