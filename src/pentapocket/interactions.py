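"""Geometric interaction detectors and occurrence statistics.

Three interaction kinds are detected per frame with purely geometric
criteria:

* hydrogen bond -- donor-acceptor heavy-atom distance <= 3.0 A and
  donor-H-acceptor angle >= 135 deg (180 deg = linear);
* water bridge -- a single water simultaneously hydrogen-bonding the ligand
  and a protein residue in the same frame;
* cation-pi -- cation to aromatic-ring centre distance <= 6 A with the angle
  between the ring normal and the centre->cation direction < 45 deg or
  > 135 deg.

Occurrences are aggregated per residue (fraction of frames with at least one
interaction) and per pocket (mean simultaneous count per frame +- std), the
layout of the headline occurrence tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import Frame, ValidationError, angle_deg
from .topology import PentamerTopology, ResidueRef

logger = logging.getLogger(__name__)

_warned_donors: set[tuple[str, str]] = set()

__all__ = [
    "InteractionCriteria",
    "InteractionRecord",
    "detect_hbonds",
    "detect_water_bridges",
    "detect_cation_pi",
    "occurrence_summary",
    "intersubunit_hbond_total",
    "donor_hydrogens",
    "polar_atom_indices",
    "acceptor_atom_indices",
    "AROMATIC_RING_ATOMS",
]

AROMATIC_RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}


@dataclass(frozen=True)
class InteractionCriteria:
    """Geometric cutoffs for the three detectors (angstrom / degrees)."""

    hbond_distance_cutoff: float = 3.0
    hbond_angle_cutoff: float = 135.0
    cation_pi_distance_cutoff: float = 6.0
    cation_pi_angle_window: float = 45.0
    donor_hydrogen_max_dist: float = 1.2

    def __post_init__(self) -> None:
        for name in ("hbond_distance_cutoff", "cation_pi_distance_cutoff",
                     "donor_hydrogen_max_dist"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("hbond_angle_cutoff", "cation_pi_angle_window"):
            v = getattr(self, name)
            if not 0 <= v <= 180:
                raise ValidationError(f"{name} must lie in [0, 180]")

    @classmethod
    def from_config(cls, config: Mapping) -> "InteractionCriteria":
        crit = config.get("criteria", {})
        kwargs = {k: float(crit[k]) for k in
                  ("hbond_distance_cutoff", "hbond_angle_cutoff",
                   "cation_pi_distance_cutoff", "cation_pi_angle_window")
                  if k in crit}
        return cls(**kwargs)


@dataclass(frozen=True)
class InteractionRecord:
    """One detected interaction in one frame."""

    kind: str  # hbond | water_bridge | cation_pi
    frame_index: int
    pocket: Optional[str]
    residue: Optional[ResidueRef]
    atoms: tuple[int, ...]
    distance: float
    angle: Optional[float] = None
    water_id: Optional[int] = None  # bridging water oxygen atom index


def polar_atom_indices(frame: Frame, indices: Iterable[int]) -> np.ndarray:
    """Restrict an atom selection to N/O heavy atoms."""
    idx = np.asarray(list(indices), dtype=int)
    if idx.size == 0:
        return idx
    el = frame.system.elements[idx]
    return idx[np.isin(el, ("N", "O"))]


def acceptor_atom_indices(frame: Frame, indices: Iterable[int],
                          criteria: "InteractionCriteria" = None) -> np.ndarray:
    """Hydrogen-bond acceptors: O atoms plus N atoms without bonded H.

    Protonated nitrogens (backbone amides, ammonium, guanidinium, amide
    ND2/NE2) act as donors only; carbonyl, carboxylate, hydroxyl and water
    oxygens always accept.
    """
    criteria = criteria or InteractionCriteria()
    idx = polar_atom_indices(frame, indices)
    if idx.size == 0:
        return idx
    system = frame.system
    keep = []
    for a in idx:
        if system.elements[a] == "O":
            keep.append(a)
            continue
        same_res = np.flatnonzero(
            (system.chain_ids == system.chain_ids[a])
            & (system.resids == system.resids[a])
            & (system.elements == "H")
        )
        has_h = False
        if same_res.size:
            dist = np.linalg.norm(frame.coords[same_res] - frame.coords[a],
                                  axis=1)
            named = np.array([_suffix_matches(str(system.names[h]),
                                              str(system.names[a]))
                              for h in same_res])
            has_h = bool(np.any((named & (dist < 1.6))
                                | (dist < criteria.donor_hydrogen_max_dist)))
        if not has_h:
            keep.append(a)
    return np.asarray(keep, dtype=int)


def _suffix_matches(h_name: str, heavy_name: str) -> bool:
    """PDB naming convention: HH1~NH1, HG~OG, HZ1~NZ, H1~N, H~N, ..."""
    hs = h_name[1:]
    hv = heavy_name[1:]
    if hs == hv:
        return True
    return hs.rstrip("0123456789") == hv


def donor_hydrogens(frame: Frame, donor_indices: Iterable[int],
                    criteria: InteractionCriteria) -> dict[int, np.ndarray]:
    """Map each donor heavy atom to its bonded hydrogens.

    Hydrogens of the same residue are paired first by the PDB naming
    convention (within a generous 1.6 A covalent sanity cap), then by a
    plain covalent-distance criterion (< ``donor_hydrogen_max_dist``).
    Donors without any hydrogen are skipped with a warning (once per atom
    type).
    """
    system = frame.system
    out: dict[int, np.ndarray] = {}
    for d in np.asarray(list(donor_indices), dtype=int):
        same_res = np.flatnonzero(
            (system.chain_ids == system.chain_ids[d])
            & (system.resids == system.resids[d])
            & (system.elements == "H")
        )
        bonded = same_res
        if same_res.size:
            dist = np.linalg.norm(frame.coords[same_res] - frame.coords[d],
                                  axis=1)
            named = np.array([_suffix_matches(str(system.names[h]),
                                              str(system.names[d]))
                              for h in same_res])
            bonded = same_res[named & (dist < 1.6)]
            if bonded.size == 0:
                bonded = same_res[dist < criteria.donor_hydrogen_max_dist]
        if bonded.size == 0:
            tag = (str(system.resnames[d]), str(system.names[d]))
            if tag not in _warned_donors:  # warn once per atom type
                _warned_donors.add(tag)
                logger.warning(
                    "donor %s %s%d has no bonded hydrogen; skipped",
                    system.names[d], system.resnames[d], system.resids[d])
            continue
        out[int(d)] = bonded
    return out


def detect_hbonds(frame: Frame, donors: Iterable[int], acceptors: Iterable[int],
                  criteria: InteractionCriteria = InteractionCriteria(),
                  kind: str = "hbond", pocket: Optional[str] = None,
                  residue_of: Optional[Mapping[int, ResidueRef]] = None,
                  ) -> list[InteractionRecord]:
    """Detect hydrogen bonds between a donor set and an acceptor set.

    One record is emitted per (donor-H, acceptor) combination satisfying the
    distance and angle criteria; donor and acceptor heavy atoms must be
    distinct atoms of distinct residues.
    """
    donors = np.asarray(list(donors), dtype=int)
    acceptors = np.asarray(list(acceptors), dtype=int)
    if donors.size == 0 or acceptors.size == 0:
        return []
    dh = donor_hydrogens(frame, donors, criteria)
    if not dh:
        return []
    donor_arr = np.fromiter(dh.keys(), dtype=int)
    tree = cKDTree(frame.coords[acceptors])
    neighbours = tree.query_ball_point(frame.coords[donor_arr],
                                       criteria.hbond_distance_cutoff)
    system = frame.system
    records = []
    for d, near in zip(donor_arr, neighbours):
        for j in near:
            a = int(acceptors[j])
            if a == d:
                continue
            if (system.chain_ids[a] == system.chain_ids[d]
                    and system.resids[a] == system.resids[d]):
                continue  # no intra-residue bonds
            dist = float(np.linalg.norm(frame.coords[a] - frame.coords[d]))
            for h in dh[int(d)]:
                ang = angle_deg(frame.coords[d], frame.coords[h],
                                frame.coords[a])
                if ang >= criteria.hbond_angle_cutoff:
                    ref = residue_of.get(int(d)) or residue_of.get(a) \
                        if residue_of else None
                    records.append(InteractionRecord(
                        kind=kind, frame_index=frame.frame_index,
                        pocket=pocket, residue=ref,
                        atoms=(int(d), int(h), a),
                        distance=dist, angle=float(ang)))
    return records


def detect_water_bridges(frame: Frame, ligand_atoms: Iterable[int],
                         residue_atoms: Mapping[ResidueRef, Iterable[int]],
                         criteria: InteractionCriteria = InteractionCriteria(),
                         pocket: Optional[str] = None,
                         ) -> list[InteractionRecord]:
    """Detect single-water bridges between the ligand and protein residues.

    A bridge is recorded once per (residue, water) pair when that water
    hydrogen-bonds the ligand (either direction) and the residue in the same
    frame.  Direct ligand-residue hydrogen bonds are not bridges.
    """
    system = frame.system
    ligand_atoms = np.asarray(list(ligand_atoms), dtype=int)
    water_oxygens = system.water_oxygens
    if ligand_atoms.size == 0 or water_oxygens.size == 0:
        return []

    # restrict waters to those near the ligand to keep the search local
    tree = cKDTree(frame.coords[water_oxygens])
    near = sorted({int(water_oxygens[j])
                   for pt in frame.coords[polar_atom_indices(frame, ligand_atoms)]
                   for j in tree.query_ball_point(pt, 6.0)})
    if not near:
        return []

    def hbonded_waters(partner_atoms) -> set[int]:
        """Water oxygen indices H-bonded to any atom of *partner_atoms*."""
        partner_polar = polar_atom_indices(frame, partner_atoms)
        partner_acc = acceptor_atom_indices(frame, partner_atoms, criteria)
        found: set[int] = set()
        # water as donor
        for rec in detect_hbonds(frame, near, partner_acc, criteria):
            found.add(rec.atoms[0])
        # water as acceptor
        for rec in detect_hbonds(frame, partner_polar, near, criteria):
            a = rec.atoms[2]
            # map acceptor atom back to its water oxygen
            if system.roles[a] == "water":
                found.add(a)
        return found

    ligand_waters = hbonded_waters(ligand_atoms)
    if not ligand_waters:
        return []

    records = []
    for ref, atoms in residue_atoms.items():
        res_waters = hbonded_waters(atoms)
        for w in sorted(ligand_waters & res_waters):
            dist = float(np.min(np.linalg.norm(
                frame.coords[np.asarray(list(atoms), dtype=int)]
                - frame.coords[w], axis=1)))
            records.append(InteractionRecord(
                kind="water_bridge", frame_index=frame.frame_index,
                pocket=pocket, residue=ref, atoms=(w,),
                distance=dist, water_id=int(w)))
    return records


def ring_center_normal(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unweighted centroid and best-fit plane normal of ring atoms (SVD)."""
    points = np.asarray(points, dtype=float)
    if len(points) < 3:
        raise ValidationError("ring needs at least 3 atoms")
    center = points.mean(axis=0)
    centered = points - center
    _, s, vt = np.linalg.svd(centered)
    if s[1] < 1e-8:  # collinear/degenerate ring
        raise ValidationError("degenerate (collinear) ring atoms")
    return center, vt[2]


def detect_cation_pi(frame: Frame, cations: Iterable[int],
                     rings: Mapping[ResidueRef, Iterable[int]],
                     criteria: InteractionCriteria = InteractionCriteria(),
                     pocket: Optional[str] = None) -> list[InteractionRecord]:
    """Detect cation-pi contacts between cation atoms and aromatic rings."""
    records = []
    for c in np.asarray(list(cations), dtype=int):
        for ref, ring_idx in rings.items():
            ring_idx = np.asarray(list(ring_idx), dtype=int)
            center, normal = ring_center_normal(frame.coords[ring_idx])
            vec = frame.coords[c] - center
            dist = float(np.linalg.norm(vec))
            if dist > criteria.cation_pi_distance_cutoff or dist == 0.0:
                continue
            cosang = np.clip(np.dot(normal, vec / dist), -1.0, 1.0)
            ang = float(np.degrees(np.arccos(cosang)))
            w = criteria.cation_pi_angle_window
            if ang < w or ang > 180.0 - w:
                records.append(InteractionRecord(
                    kind="cation_pi", frame_index=frame.frame_index,
                    pocket=pocket, residue=ref,
                    atoms=(int(c),) + tuple(int(i) for i in ring_idx),
                    distance=dist, angle=ang))
    return records


# --------------------------------------------------------------------------- #
# aggregation
# --------------------------------------------------------------------------- #

def occurrence_summary(records: Sequence[InteractionRecord], n_frames: int,
                       model: str = "model") -> dict[str, pd.DataFrame]:
    """Aggregate records into per-residue occurrence and per-pocket counts.

    Returns two data frames: ``per_residue`` with occurrence % (fraction of
    frames with >= 1 record for that pocket/residue/kind) and ``per_pocket``
    with the mean simultaneous record count per frame +- std (frames without
    records count 0; multiple simultaneous bonds with one residue all count).
    """
    if n_frames < 1:
        raise ValidationError("n_frames must be >= 1")
    rows = [
        {
            "kind": r.kind,
            "pocket": r.pocket,
            "residue": (f"{r.residue.residue_name}{r.residue.residue_number}"
                        if r.residue else ""),
            "frame": r.frame_index,
        }
        for r in records
    ]
    per_residue_rows = []
    per_pocket_rows = []
    if rows:
        df = pd.DataFrame(rows)
        grouped = df.groupby(["kind", "pocket", "residue"])["frame"].nunique()
        for (kind, pocket, residue), nf in grouped.items():
            per_residue_rows.append({
                "model": model, "kind": kind, "pocket": pocket,
                "residue": residue,
                "occurrence_pct": 100.0 * nf / n_frames,
            })
        for (kind, pocket), sub in df.groupby(["kind", "pocket"]):
            present = sub.groupby("frame").size().to_numpy(dtype=float)
            counts = np.zeros(n_frames)
            counts[:len(present)] = present  # remaining frames have 0 records
            per_pocket_rows.append({
                "model": model, "kind": kind, "pocket": pocket,
                "mean_count": float(counts.mean()),
                "std_count": float(counts.std()),
            })
    per_residue = pd.DataFrame(
        per_residue_rows,
        columns=["model", "kind", "pocket", "residue", "occurrence_pct"])
    per_pocket = pd.DataFrame(
        per_pocket_rows,
        columns=["model", "kind", "pocket", "mean_count", "std_count"])
    return {"per_residue": per_residue, "per_pocket": per_pocket}


def intersubunit_hbond_total(frames: Iterable[Frame],
                             topology: PentamerTopology,
                             criteria: InteractionCriteria = InteractionCriteria(),
                             ) -> dict:
    """Direct protein-protein hydrogen bonds across subunit interfaces.

    Per frame, every hydrogen bond whose donor and acceptor heavy atoms sit
    on different subunits is counted (waters and ligands excluded).  Returns
    per-interface means plus the five-interface per-frame total as
    mean +- std.
    """
    interface_counts: dict[tuple[int, int], list[int]] = {}
    totals = []
    n = 0
    for frame in frames:
        n += 1
        system = frame.system
        protein = system.role_indices("protein")
        donors = polar_atom_indices(frame, protein)
        acceptors = acceptor_atom_indices(frame, protein, criteria)
        recs = detect_hbonds(frame, donors, acceptors, criteria)
        per_iface: dict[tuple[int, int], int] = {}
        total = 0
        for rec in recs:
            d, _, a = rec.atoms
            sd, sa = int(system.subunit_index[d]), int(system.subunit_index[a])
            if sd == sa:
                continue
            key = (min(sd, sa), max(sd, sa))
            per_iface[key] = per_iface.get(key, 0) + 1
            total += 1
        totals.append(total)
        for key, cnt in per_iface.items():
            interface_counts.setdefault(key, []).append(cnt)
    if n == 0:
        raise ValidationError("no frames provided")
    totals = np.asarray(totals, dtype=float)
    per_interface = {
        f"{k[0]}-{k[1]}": float(np.sum(v) / n)
        for k, v in sorted(interface_counts.items())
    }
    return {
        "per_interface_mean": per_interface,
        "total_mean": float(totals.mean()),
        "total_std": float(totals.std()),
        "n_frames": n,
    }
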