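"""Core in-memory containers shared by all analysis modules.

The pipeline operates on a :class:`System` (static per-atom metadata with
role annotations) plus one :class:`Frame` of Cartesian coordinates per time
point.  Coordinates are in angstroms everywhere; readers convert on input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

__all__ = [
    "System",
    "Frame",
    "PentapocketError",
    "ValidationError",
    "ATOMIC_MASSES",
    "WATER_RESNAMES",
    "ION_RESNAMES",
    "STANDARD_AMINO_ACIDS",
]


class PentapocketError(Exception):
    """Base class for package errors."""


class ValidationError(PentapocketError):
    """Raised when an input structure, topology or config fails validation."""


ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "NA": 22.990,
    "CL": 35.45,
    "K": 39.098,
    "MG": 24.305,
    "CA": 40.078,
}

WATER_RESNAMES = frozenset({"HOH", "WAT", "TIP3", "TIP", "SOL", "SPC", "T3P"})
ION_RESNAMES = frozenset({"NA", "CL", "SOD", "CLA", "K", "POT", "MG", "CAL"})

STANDARD_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS HIE HID HIP ILE LEU LYS MET PHE PRO "
    "SER THR TRP TYR VAL".split()
)

ROLES = ("protein", "water", "ligand", "ion")


def element_from_name(name: str) -> str:
    """Best-effort element from a PDB atom name (two-letter ions first)."""
    stripped = name.strip()
    upper = stripped.upper()
    for two in ("NA", "CL", "MG", "BR"):
        if upper == two:
            return two
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return "X"


@dataclass
class System:
    """Static atom metadata for one molecular system.

    Arrays are parallel and of equal length N.  ``subunit_index`` is 0-4 for
    atoms of the five protein chains and -1 otherwise.  ``roles`` holds one of
    ``protein``, ``water``, ``ligand``, ``ion`` per atom.
    """

    names: np.ndarray
    elements: np.ndarray
    resnames: np.ndarray
    resids: np.ndarray
    icodes: np.ndarray
    chain_ids: np.ndarray
    subunit_index: np.ndarray
    roles: np.ndarray
    segids: Optional[np.ndarray] = None

    # caches built lazily
    _atom_lookup: dict = field(default_factory=dict, repr=False)
    _residue_atoms: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        n = len(self.names)
        for attr in ("elements", "resnames", "resids", "icodes", "chain_ids",
                     "subunit_index", "roles"):
            if len(getattr(self, attr)) != n:
                raise ValidationError(f"metadata array {attr!r} length mismatch")
        bad = set(np.unique(self.roles)) - set(ROLES)
        if bad:
            raise ValidationError(f"unknown atom roles: {sorted(bad)}")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def masses(self) -> np.ndarray:
        try:
            return self._masses
        except AttributeError:
            self._masses = np.array(
                [ATOMIC_MASSES.get(e, 0.0) for e in self.elements], dtype=float
            )
            return self._masses

    # ------------------------------------------------------------------ #
    # selections
    # ------------------------------------------------------------------ #
    def atom_index(self, subunit: int, resid: int, name: str,
                   icode: str = "") -> int:
        """Index of the unique protein atom (subunit, resid, name)."""
        key = (int(subunit), int(resid), name, icode)
        if not self._atom_lookup:
            for i in range(self.n_atoms):
                if self.subunit_index[i] < 0:
                    continue
                k = (int(self.subunit_index[i]), int(self.resids[i]),
                     str(self.names[i]), str(self.icodes[i]))
                if k in self._atom_lookup:
                    raise ValidationError(f"duplicate protein atom {k}")
                self._atom_lookup[k] = i
        try:
            return self._atom_lookup[key]
        except KeyError:
            raise ValidationError(
                f"atom {name!r} of residue {resid}{icode} in subunit "
                f"{subunit} not found"
            ) from None

    def residue_atom_indices(self, subunit: int, resid: int) -> np.ndarray:
        """All atom indices of one protein residue."""
        key = (int(subunit), int(resid))
        if not self._residue_atoms:
            prot = np.flatnonzero(self.subunit_index >= 0)
            for i in prot:
                k = (int(self.subunit_index[i]), int(self.resids[i]))
                self._residue_atoms.setdefault(k, []).append(int(i))
        if key not in self._residue_atoms:
            raise ValidationError(
                f"residue {resid} in subunit {subunit} not found")
        return np.asarray(self._residue_atoms[key], dtype=int)

    def role_indices(self, role: str) -> np.ndarray:
        return np.flatnonzero(self.roles == role)

    @property
    def water_oxygens(self) -> np.ndarray:
        """Indices of the single oxygen of every water molecule."""
        mask = (self.roles == "water") & (self.elements == "O")
        return np.flatnonzero(mask)

    @property
    def protein_subunits(self) -> list[int]:
        su = np.unique(self.subunit_index)
        return [int(s) for s in su if s >= 0]

    def ligand_groups(self) -> list[np.ndarray]:
        """Atom-index arrays, one per ligand molecule (grouped by chain+resid)."""
        lig = self.role_indices("ligand")
        groups: dict = {}
        for i in lig:
            key = (str(self.chain_ids[i]), int(self.resids[i]))
            groups.setdefault(key, []).append(int(i))
        return [np.asarray(groups[k], dtype=int) for k in sorted(groups)]


@dataclass
class Frame:
    """One trajectory frame: coordinates (N, 3) in angstrom + metadata."""

    system: System
    coords: np.ndarray
    frame_index: int = 0
    time: Optional[float] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.system.n_atoms, 3):
            raise ValidationError(
                f"coordinate array shape {self.coords.shape} does not match "
                f"atom count {self.system.n_atoms}"
            )

    def positions(self, indices: Iterable[int]) -> np.ndarray:
        return self.coords[np.asarray(list(indices), dtype=int)]


def angle_deg(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    """Angle (degrees) at *vertex* between rays vertex->a and vertex->b."""
    u = np.asarray(a, float) - np.asarray(vertex, float)
    v = np.asarray(b, float) - np.asarray(vertex, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValidationError("degenerate angle: coincident points")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))
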