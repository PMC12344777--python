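"""Synthetic C5 pseudo-pentamer structures and trajectories.

The generator stands in for deposited MD data: it emits a five-chain
assembly whose chains are 72-degree rotations of one minimal residue
scaffold, with ligand particles in a configurable subset of the five
interfacial pockets, water particles placed with controlled counts inside
and outside each pocket cage, scripted Loop C opening/closing, scripted
hydrogen-bond / water-bridge / cation-pi geometries at programmed Bernoulli
rates, coupled Loop B'/Loop F' displacements, and isotropic Gaussian thermal
noise.  Every scripted quantity is recorded in a :class:`GroundTruthLedger`
so the full pipeline can be validated against exact expectations.

The scaffolds are geometric, not chemical: descriptors in this package are
purely geometric, so pseudo-residues with a handful of named atoms give
exact, desk-scale ground truth where real force-field dynamics could not.
Default rates, angles, water counts and distances emulate the statistics of
bound versus empty glycine-receptor pockets (bound: capped Loop C near 24
degrees, about one pocket water, contracted interface; empty: open lid near
33 degrees, about seven waters).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Optional, Sequence, Union

import numpy as np

from .core import Frame, System, ValidationError

__all__ = [
    "GeneratorParams",
    "GroundTruthLedger",
    "SyntheticEnsemble",
    "generate_pentamer",
    "generate_trajectory",
    "ground_truth_ledger",
]


# --------------------------------------------------------------------------- #
# template geometry (local pocket frame: x toward the principal subunit,
# y radially outward, z along the channel axis; units A)
# --------------------------------------------------------------------------- #

BACKBONE_OFFSETS = {
    "N": np.array([-0.9, 0.8, 0.2]),
    "H": np.array([-1.58, 1.48, 0.37]),   # ~1.0 A from N
    "C": np.array([1.2, -0.5, 0.3]),
    "O": np.array([1.6, -1.4, 0.1]),
}

# the 7 principal-side binding residues (Calpha cage vertices)
PRINCIPAL_CAGE = {
    115: ("PHE", (4.0, 2.5, -3.0)),
    173: ("GLU", (5.5, -2.0, 1.0)),
    174: ("SER", (6.5, 0.5, 2.5)),
    175: ("PHE", (5.0, 2.0, 3.5)),
    218: ("TYR", (4.5, -3.0, 4.0)),
    220: ("THR", (5.0, 0.0, 6.0)),
    223: ("PHE", (6.0, 3.0, 5.0)),
}
# the 4 complementary-side binding residues
COMPLEMENTARY_CAGE = {
    79: ("PHE", (-5.5, 1.5, 4.0)),
    81: ("ARG", (-6.0, -1.5, 0.5)),
    133: ("LEU", (-5.0, 2.5, -2.5)),
    145: ("SER", (-6.5, -0.5, -1.0)),
}
PRINCIPAL_EXTRA = {
    215: ("THR", (5.2, -1.5, 7.8)),  # Loop C hinge
    224: ("THR", (6.2, 1.5, 7.6)),   # Loop C hinge
    219: ("ASN", None),              # Loop C apex partner: angle-driven
    216: ("ALA", (5.0, -2.5, 8.5)),
    217: ("ALA", (4.6, -1.0, 9.0)),
    221: ("ALA", (5.6, 2.0, 8.8)),
    222: ("ALA", (6.0, 2.8, 7.9)),
    170: ("ALA", (6.8, -2.5, 0.0)),
    171: ("ALA", (6.4, -2.3, 0.8)),
    172: ("ALA", (6.0, -2.2, 1.6)),
    176: ("GLY", (6.9, 1.2, 3.0)),
    177: ("ALA", (7.2, 1.8, 3.6)),
    116: ("ALA", (3.5, 3.2, -2.0)),
    117: ("ALA", (3.2, 3.6, -1.0)),
    119: ("GLU", (3.2, 4.3, 0.0)),
    122: ("ALA", (2.8, 4.8, 1.0)),
    68: ("ALA", (4.0, -5.0, 1.0)),
    70: ("THR", (4.5, -5.5, 2.0)),
    71: ("ALA", (5.0, -5.8, 3.0)),
    49: ("LYS", (3.0, -5.5, -1.5)),
}
COMPLEMENTARY_EXTRA = {
    58: ("ASN", (-6.5, 1.0, 4.0)),
    77: ("ALA", (-5.2, 1.8, 3.0)),
    78: ("ALA", (-5.3, 1.6, 2.5)),
    80: ("ALA", (-5.8, -0.5, 1.2)),
    82: ("ALA", (-6.2, -2.0, -0.2)),
    132: ("ALA", (-4.8, 2.8, -3.2)),
    144: ("ALA", (-6.3, -0.3, -1.8)),
    147: ("ARG", (-3.2, 4.6, 0.3)),
    96: ("ASP", (-3.0, -5.5, -1.5)),
    135: ("ARG", (-5.2, 2.0, 5.5)),
    186: ("ALA", (-6.6, 2.0, 5.8)),
    188: ("ALA", (-6.7, 2.3, 6.2)),
    189: ("LYS", (-6.8, 2.5, 6.5)),
    190: ("ALA", (-7.0, 2.8, 7.0)),
    192: ("ALA", (-7.2, 3.0, 7.6)),
}

# ligand (glycine zwitterion) atoms in the pocket frame; H1 is set below so
# that it points along the ammonium -> bridge-water direction
LIGAND_ATOMS = {
    "N": (-1.2, 0.0, 1.3),
    "H2": (-2.1, 0.33, 1.58),
    "H3": (-2.1, -0.33, 1.58),
    "CA": (0.0, 0.0, 1.0),
    "C": (1.3, 0.0, 0.9),
    "O": (1.9, 0.9, 0.9),
    "OXT": (1.9, -0.9, 0.9),
}

RING_ATOM_NAMES = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
RING_RADIUS = 1.39


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


# directions of scripted geometry (unit vectors, pocket frame)
W1 = _unit((-0.5, 0.2, 0.84))    # ligand N -> bridge water oxygen
W2 = _unit((0.2, -0.95, 0.24))   # bridge water -> GLU173 OE1
W3 = _unit((0.7, 0.5, 0.51))     # bridge water -> SER174 OG

LIGAND_ATOMS["H1"] = tuple(np.asarray(LIGAND_ATOMS["N"]) + W1)

HBOND_SCRIPTS = (
    dict(key="ARG81", side="C", resid=81, donor="NH1", hydrogen="HH1",
         anchor="O", direction=_unit((-0.86, 0.43, 0.28))),
    dict(key="SER145", side="C", resid=145, donor="OG", hydrogen="HG",
         anchor="OXT", direction=_unit((-0.86, -0.43, 0.28))),
    dict(key="THR220", side="P", resid=220, donor="OG1", hydrogen="HG1",
         anchor="O", direction=_unit((0.2, 0.1, 0.975))),
    dict(key="PHE175", side="P", resid=175, donor="N", hydrogen="H",
         anchor="OXT", direction=_unit((0.45, 0.88, 0.15))),
)
HBOND_ON, HBOND_OFF = 2.3, 5.0

BRIDGE_SCRIPTS = (
    dict(key="GLU173", side="P", resid=173, atom="OE1", direction=W2),
    dict(key="SER174", side="P", resid=174, atom="OG", direction=W3,
         hydrogen=("HG", tuple(-W3))),
)
BRIDGE_ON, BRIDGE_OFF = 2.2, 5.5

CATION_PI_SCRIPTS = (
    dict(key="PHE175", side="P", resid=175, direction=_unit((0.85, 0.35, 0.4))),
    dict(key="TYR218", side="P", resid=218, direction=_unit((0.8, -0.5, 0.33))),
    dict(key="PHE223", side="P", resid=223, direction=_unit((0.6, 0.55, 0.58))),
    dict(key="PHE79", side="C", resid=79, direction=_unit((-0.9, 0.3, 0.32))),
)
PI_ON, PI_OFF = 4.5, 7.5

CONSERVED_SCRIPTS = (
    dict(key="GLU119-ARG147",
         acceptor=("P", 119, "OE1"), acceptor_offset=(0.0, 0.8, 0.0),
         donor=("C", 147, "NH1", "HH1"), direction=_unit((-1.0, 0.05, 0.05))),
    dict(key="LYS49-ASP96",
         acceptor=("C", 96, "OD1"), acceptor_offset=(0.8, 0.0, 0.3),
         donor=("P", 49, "NZ", "HZ1"), direction=_unit((1.0, 0.0, 0.0))),
    dict(key="ASN219-ASN58",
         acceptor=("C", 58, "OD1"), acceptor_offset=(0.5, -0.6, 0.6),
         donor=("P", 219, "ND2", "HD2"), direction=_unit((0.3, -0.9, -0.3))),
    dict(key="THR220-ARG135",
         acceptor=("P", 220, "OG1"), acceptor_offset=None,  # dynamic atom
         donor=("C", 135, "NH1", "HH1"), direction=_unit((-0.85, 0.35, 0.4))),
    dict(key="ASN219-LYS189",
         acceptor=("P", 219, "OD1"), acceptor_offset=None,  # dynamic atom
         donor=("C", 189, "NZ", "HZ1"), direction=_unit((-0.9, 0.3, -0.2))),
)
CONSERVED_ON, CONSERVED_OFF = 2.3, 5.0

ASN219_OD1_OFFSET = np.array([0.8, 0.5, -0.8])
THR220_OG1_STATIC = None  # off-position of the ligand script is used when empty

APEX_ARM_LENGTH = 5.0          # |O -> apex centroid|
BALL_CENTER_OFFSET = np.array([-1.5, 0.0, -1.0])  # from the cage vertex centroid
BALL_RADIUS = 0.55
BALL_JITTER = 0.1
PARK_Z = 50.0
EXTERIOR_Z = 40.0

STREAM_IDS = {"waters": 1, "noise": 2, "events": 3, "pushpull": 4}

FloatOrSchedule = Union[float, Sequence[float], np.ndarray]


# --------------------------------------------------------------------------- #
# parameters and ledger
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class GeneratorParams:
    """Scripted study conditions of one synthetic run.

    Defaults emulate the statistics of the bound/empty pocket contrast:
    occupied pockets hold 1 cage water, a capped Loop C (24 +- 1 deg) and a
    contracted interface (11.6 A); empty pockets hold 7 waters, an open lid
    (33 +- 2 deg) and the relaxed 12.4 A interface.  Interaction rates are
    per-frame Bernoulli probabilities.
    """

    n_frames: int = 500
    ring_radius: float = 21.6
    pocket_z: float = 10.0
    occupancy: tuple[bool, bool, bool, bool, bool] = (True,) * 5
    water_schedule: Optional[Mapping[str, FloatOrSchedule]] = None
    bound_waters: int = 1
    empty_waters: int = 7
    n_exterior_waters: int = 30
    loopc_mean: Optional[Mapping[str, float]] = None
    loopc_amplitude: Optional[Mapping[str, float]] = None
    bound_angle: float = 24.0
    empty_angle: float = 33.0
    bound_amplitude: float = 1.0
    empty_amplitude: float = 2.0
    loopc_period: float = 100.0
    hbond_rates: Mapping[str, float] = field(default_factory=lambda: {
        "ARG81": 0.93, "SER145": 0.93, "THR220": 0.80, "PHE175": 0.50})
    bridge_rates: Mapping[str, float] = field(default_factory=lambda: {
        "GLU173": 0.75, "SER174": 0.70})
    cationpi_rates: Mapping[str, float] = field(default_factory=lambda: {
        "PHE175": 0.98, "TYR218": 0.40, "PHE223": 0.35, "PHE79": 0.05})
    conserved_rates: Mapping[str, float] = field(default_factory=lambda: {
        "GLU119-ARG147": 0.90, "LYS49-ASP96": 0.70, "ASN219-ASN58": 0.60,
        "THR220-ARG135": 0.50, "ASN219-LYS189": 0.50})
    intrapocket_base: float = 12.4
    contraction: float = 0.8
    extra_contraction: Optional[Mapping[str, float]] = None
    pushpull_coupling: float = 0.5
    pushpull_amplitude: float = 1.0
    cage_scale: FloatOrSchedule = 1.0
    noise_sigma: float = 0.2

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValidationError("n_frames must be >= 1")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if not 0.0 <= self.pushpull_coupling <= 1.0:
            raise ValidationError("pushpull_coupling must lie in [0, 1]")
        if len(self.occupancy) != 5:
            raise ValidationError("occupancy must have 5 entries")
        for name in ("hbond_rates", "bridge_rates", "cationpi_rates",
                     "conserved_rates"):
            for k, v in getattr(self, name).items():
                if not 0.0 <= v <= 1.0:
                    raise ValidationError(f"{name}[{k}] outside [0, 1]")
        for lbl in POCKETS:
            sched = self._raw_water_schedule(lbl)
            arr = np.atleast_1d(np.asarray(sched))
            if arr.size not in (1, self.n_frames):
                raise ValidationError(
                    f"water schedule for pocket {lbl} has length {arr.size}, "
                    f"expected 1 or n_frames={self.n_frames}")

    def _raw_water_schedule(self, label: str):
        if self.water_schedule and label in self.water_schedule:
            return self.water_schedule[label]
        occupied = self.occupancy[POCKETS.index(label)]
        return self.bound_waters if occupied else self.empty_waters

    # ------------------------------------------------------------------ #
    # resolved per-pocket schedules
    # ------------------------------------------------------------------ #
    def waters(self, label: str) -> np.ndarray:
        arr = np.atleast_1d(np.asarray(self._raw_water_schedule(label),
                                       dtype=int))
        if arr.size == 1:
            arr = np.full(self.n_frames, int(arr[0]))
        if (arr < 0).any():
            raise ValidationError("water counts must be >= 0")
        if self.occupancy[POCKETS.index(label)] and (arr < 1).any():
            raise ValidationError(
                f"occupied pocket {label} needs >= 1 cage water (the bridge "
                "water)")
        return arr

    def angles(self, label: str) -> np.ndarray:
        i = POCKETS.index(label)
        occupied = self.occupancy[i]
        mean = (self.loopc_mean or {}).get(
            label, self.bound_angle if occupied else self.empty_angle)
        amp = (self.loopc_amplitude or {}).get(
            label, self.bound_amplitude if occupied else self.empty_amplitude)
        t = np.arange(self.n_frames, dtype=float)
        return mean + amp * np.sin(2.0 * np.pi * t / self.loopc_period)

    def scales(self) -> np.ndarray:
        arr = np.atleast_1d(np.asarray(self.cage_scale, dtype=float))
        if arr.size == 1:
            arr = np.full(self.n_frames, float(arr[0]))
        if arr.size != self.n_frames:
            raise ValidationError("cage_scale schedule length mismatch")
        if (arr <= 0).any():
            raise ValidationError("cage_scale must be positive")
        return arr

    def contraction_of(self, label: str) -> float:
        base = self.contraction if self.occupancy[POCKETS.index(label)] else 0.0
        return base + float((self.extra_contraction or {}).get(label, 0.0))


POCKETS = ("a", "b", "c", "d", "e")


@dataclass
class GroundTruthLedger:
    """Exact scripted expectations of one generated trajectory."""

    n_frames: int
    occupancy: tuple[bool, ...]
    water_counts: dict          # label -> int array (n_frames,)
    loopc_angles: dict          # label -> float array
    hull_volumes: dict          # label -> float array (pre-noise geometry)
    intrapocket_distance: dict  # label -> float array (pre-noise, planar)
    intrapocket_target: dict    # label -> scripted mean distance
    events: dict                # (kind, key) -> bool array; shared over pockets
    rates: dict                 # (kind, key) -> programmed rate
    pushpull_coupling: float
    pushpull_distances: dict    # label -> (d1 array, d2 array), pre-noise
    interpocket_base: float

    def occurrence(self, kind: str, key: str) -> float:
        """Realized scripted occurrence (%) for one interaction stream."""
        ev = self.events[(kind, key)]
        return 100.0 * float(np.mean(ev))

    def to_json(self, path) -> None:
        payload = {
            "n_frames": self.n_frames,
            "occupancy": list(self.occupancy),
            "pushpull_coupling": self.pushpull_coupling,
            "interpocket_base": self.interpocket_base,
            "intrapocket_target": self.intrapocket_target,
            "rates": {f"{k[0]}:{k[1]}": v for k, v in self.rates.items()},
            "water_counts": {k: np.asarray(v).tolist()
                             for k, v in self.water_counts.items()},
            "loopc_angles": {k: np.asarray(v).tolist()
                             for k, v in self.loopc_angles.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


# --------------------------------------------------------------------------- #
# assembly helpers
# --------------------------------------------------------------------------- #

class _PocketFrame:
    """Local frame -> global rotation at a given ring angle (degrees)."""

    def __init__(self, angle_deg: float, ring_radius: float, z0: float):
        beta = np.radians(angle_deg)
        self.origin = np.array([ring_radius * np.cos(beta),
                                ring_radius * np.sin(beta), z0])
        self.ey = np.array([np.cos(beta), np.sin(beta), 0.0])
        self.ex = np.array([np.sin(beta), -np.cos(beta), 0.0])
        self.ez = np.array([0.0, 0.0, 1.0])

    def to_global(self, local) -> np.ndarray:
        local = np.asarray(local, dtype=float)
        return (self.origin + local[0] * self.ex + local[1] * self.ey
                + local[2] * self.ez)

    def rotate(self, local) -> np.ndarray:
        """Rotate a local direction into global coordinates (no origin)."""
        local = np.asarray(local, dtype=float)
        return local[0] * self.ex + local[1] * self.ey + local[2] * self.ez


def _calibrated_cages(params: GeneratorParams) -> tuple[dict, dict]:
    """Cage Calpha local positions with the intrapocket distance calibrated.

    The complementary cluster is shifted so both planar centroids share the
    same local y, then the clusters are moved apart/together along x so the
    planar centroid separation equals the scripted target for each pocket.
    """
    prin = {r: np.array(pos) for r, (_, pos) in PRINCIPAL_CAGE.items()}
    comp = {r: np.array(pos) for r, (_, pos) in COMPLEMENTARY_CAGE.items()}
    p_cent = np.mean([v for v in prin.values()], axis=0)
    c_cent = np.mean([v for v in comp.values()], axis=0)
    dy = p_cent[1] - c_cent[1]
    for r in comp:
        comp[r] = comp[r] + np.array([0.0, dy, 0.0])
    gap0 = p_cent[0] - (c_cent[0])
    cages = {}
    for label in POCKETS:
        target = params.intrapocket_base - params.contraction_of(label)
        if target <= 0:
            raise ValidationError(f"non-positive intrapocket target for {label}")
        shift = 0.5 * (target - gap0)
        cages[label] = (
            {r: v + np.array([shift, 0.0, 0.0]) for r, v in prin.items()},
            {r: v - np.array([shift, 0.0, 0.0]) for r, v in comp.items()},
        )
    return cages, {"gap0": gap0}


def _hexagon(center: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """Six ring-atom positions around *center* in the plane normal to *normal*."""
    n = _unit(normal)
    seed = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(seed, n)) > 0.9:
        seed = np.array([1.0, 0.0, 0.0])
    e1 = _unit(np.cross(n, seed))
    e2 = np.cross(n, e1)
    angles = np.radians(np.arange(6) * 60.0)
    return center + RING_RADIUS * (np.outer(np.cos(angles), e1)
                                   + np.outer(np.sin(angles), e2))


SIDECHAIN_STATIC = {
    # (side, resid) -> list of (atom name, offset from Calpha)
    ("P", 119): [("OE1", (0.0, 0.8, 0.0))],
    ("C", 58): [("OD1", (0.5, -0.6, 0.6))],
    ("C", 96): [("OD1", (0.8, 0.0, 0.3))],
}

RESNAME_BY_SIDE_RESID = {}
for _r, (_nm, _pos) in {**PRINCIPAL_CAGE, **PRINCIPAL_EXTRA}.items():
    RESNAME_BY_SIDE_RESID[("P", _r)] = _nm
for _r, (_nm, _pos) in {**COMPLEMENTARY_CAGE, **COMPLEMENTARY_EXTRA}.items():
    RESNAME_BY_SIDE_RESID[("C", _r)] = _nm

# extra atoms that exist on scripted residues (placed dynamically)
SIDECHAIN_DYNAMIC = {
    ("C", 81): ["NH1", "HH1"],
    ("C", 145): ["OG", "HG"],
    ("P", 220): ["OG1", "HG1"],
    ("P", 173): ["OE1"],
    ("P", 174): ["OG", "HG"],
    ("P", 219): ["OD1", "ND2", "HD2"],
    ("C", 147): ["NH1", "HH1"],
    ("P", 49): ["NZ", "HZ1"],
    ("C", 135): ["NH1", "HH1"],
    ("C", 189): ["NZ", "HZ1"],
}
AROMATIC_SIDE_RESIDS = (("P", 115), ("P", 175), ("P", 218), ("P", 223),
                        ("C", 79))


def _element_of(name: str) -> str:
    return "H" if name.startswith("H") else name[0]


class _Builder:
    """Assembles the atom table and per-frame coordinate scripts."""

    def __init__(self, params: GeneratorParams):
        self.params = params
        self.frames = [_PocketFrame(72.0 * p + 36.0, params.ring_radius,
                                    params.pocket_z) for p in range(5)]
        self.chain_frames = [_PocketFrame(72.0 * c, params.ring_radius, 0.0)
                             for c in range(5)]
        self.cages, _ = _calibrated_cages(params)
        # atom table under construction
        self.names: list[str] = []
        self.resnames: list[str] = []
        self.resids: list[int] = []
        self.chains: list[str] = []
        self.roles: list[str] = []
        self.records: list[str] = []
        self.base: list[np.ndarray] = []
        # index maps: (chain_index, resid, name) -> atom index for protein,
        # plus per-pocket special groups
        self.index: dict = {}
        self.pocket_atoms: dict = {lbl: {} for lbl in POCKETS}
        self.water_slots: dict = {lbl: [] for lbl in POCKETS}
        self.exterior_waters: list = []
        self.h_parent: dict[int, int] = {}  # hydrogen -> bonded heavy atom
        self._build()

    # -- table construction ------------------------------------------------
    def _add_atom(self, name, resname, resid, chain, role, record, pos):
        self.names.append(name)
        self.resnames.append(resname)
        self.resids.append(resid)
        self.chains.append(chain)
        self.roles.append(role)
        self.records.append(record)
        self.base.append(np.asarray(pos, dtype=float))
        return len(self.names) - 1

    def _add_residue(self, chain_idx, resid, resname, ca_global, side, frame):
        chain = "ABCDE"[chain_idx]
        atoms = {}

        def off(o):
            return ca_global + frame.rotate(o)

        atoms["N"] = self._add_atom("N", resname, resid, chain, "protein",
                                    "ATOM", off(BACKBONE_OFFSETS["N"]))
        atoms["H"] = self._add_atom("H", resname, resid, chain, "protein",
                                    "ATOM", off(BACKBONE_OFFSETS["H"]))
        atoms["CA"] = self._add_atom("CA", resname, resid, chain, "protein",
                                     "ATOM", ca_global)
        atoms["C"] = self._add_atom("C", resname, resid, chain, "protein",
                                    "ATOM", off(BACKBONE_OFFSETS["C"]))
        atoms["O"] = self._add_atom("O", resname, resid, chain, "protein",
                                    "ATOM", off(BACKBONE_OFFSETS["O"]))
        key = (side, resid)
        for name, offset in SIDECHAIN_STATIC.get(key, []):
            atoms[name] = self._add_atom(name, resname, resid, chain,
                                         "protein", "ATOM", off(offset))
        for name in SIDECHAIN_DYNAMIC.get(key, []):
            atoms[name] = self._add_atom(name, resname, resid, chain,
                                         "protein", "ATOM", ca_global)
        if key in AROMATIC_SIDE_RESIDS:
            for name in RING_ATOM_NAMES:
                atoms[name] = self._add_atom(name, resname, resid, chain,
                                             "protein", "ATOM", ca_global)
        for name, idx in atoms.items():
            self.index[(chain_idx, resid, name)] = idx
        for name, idx in atoms.items():
            if not name.startswith("H"):
                continue
            suffix = name[1:]
            parent = None
            for heavy, hidx in atoms.items():
                if heavy.startswith("H") or heavy[0] not in "NO":
                    continue
                if heavy[1:] == suffix:
                    parent = hidx
                    break
            if parent is None:
                stripped = suffix.rstrip("0123456789")
                for heavy, hidx in atoms.items():
                    if heavy.startswith("H") or heavy[0] not in "NO":
                        continue
                    if heavy[1:] == stripped:
                        parent = hidx
                        break
            if parent is None:
                parent = atoms["N"]
            self.h_parent[idx] = parent
        return atoms

    def _build(self) -> None:
        params = self.params
        # protein: chains in order; each chain = principal residues of its own
        # pocket + complementary residues of the preceding pocket + tail
        for chain_idx in range(5):
            per_chain: list[tuple] = []
            own = chain_idx                 # principal side of pocket own
            prev = (chain_idx - 1) % 5      # complementary side of pocket prev
            prin_cage, _ = self.cages[POCKETS[own]]
            _, comp_cage = self.cages[POCKETS[prev]]
            for resid, (resname, pos) in sorted({**PRINCIPAL_CAGE,
                                                 **PRINCIPAL_EXTRA}.items()):
                local = prin_cage.get(resid, None if pos is None
                                      else np.asarray(pos, float))
                per_chain.append((resid, resname, "P", own, local))
            for resid, (resname, pos) in sorted({**COMPLEMENTARY_CAGE,
                                                 **COMPLEMENTARY_EXTRA}.items()):
                local = comp_cage.get(resid, np.asarray(pos, float))
                per_chain.append((resid, resname, "C", prev, local))
            # restrained tail near the lower rim of the chain wedge
            for k, resid in enumerate(range(236, 241)):
                per_chain.append((resid, "ALA", "T", chain_idx,
                                  np.array([0.6 * k, -2.0, -1.0 * k])))
            for resid, resname, side, pocket, local in sorted(per_chain):
                frame = (self.chain_frames[pocket] if side == "T"
                         else self.frames[pocket])
                if local is None:  # angle-driven Calpha: placeholder
                    ca = np.zeros(3)
                else:
                    ca = frame.to_global(local)
                atoms = self._add_residue(chain_idx, resid, resname, ca,
                                          side if side != "T" else "X",
                                          frame)
                if side in ("P", "C"):
                    self.pocket_atoms[POCKETS[pocket]].setdefault(
                        (side, resid), atoms)

        # ligands in occupied pockets
        for p, lbl in enumerate(POCKETS):
            if not params.occupancy[p]:
                continue
            frame = self.frames[p]
            lig = {}
            for name, local in LIGAND_ATOMS.items():
                lig[name] = self._add_atom(
                    name, "GLY", p + 1, "L", "ligand", "HETATM",
                    frame.to_global(local))
            for name in ("H1", "H2", "H3"):
                self.h_parent[lig[name]] = lig["N"]
            self.pocket_atoms[lbl]["ligand"] = lig

        # pocket waters: one slot per possible cage water (slot 0 of an
        # occupied pocket is the bridge water), parked when unused
        wat_resid = 0
        for p, lbl in enumerate(POCKETS):
            n_slots = int(np.max(params.waters(lbl)))
            frame = self.frames[p]
            for slot in range(n_slots):
                wat_resid += 1
                park = frame.to_global((2.0 * slot, 0.0, PARK_Z))
                o = self._add_atom("O", "HOH", wat_resid, "W", "water",
                                   "HETATM", park)
                h1 = self._add_atom("H1", "HOH", wat_resid, "W", "water",
                                    "HETATM", park + np.array([0.3, 0, -0.9]))
                h2 = self._add_atom("H2", "HOH", wat_resid, "W", "water",
                                    "HETATM", park + np.array([0.8, -0.6, 0]))
                self.h_parent[h1] = o
                self.h_parent[h2] = o
                self.water_slots[lbl].append((o, h1, h2))
        # exterior waters: a ring far above the assembly
        for k in range(params.n_exterior_waters):
            wat_resid += 1
            ang = 2.0 * np.pi * k / max(params.n_exterior_waters, 1)
            pos = np.array([params.ring_radius * np.cos(ang),
                            params.ring_radius * np.sin(ang),
                            EXTERIOR_Z + 3.0 * (k % 5)])
            o = self._add_atom("O", "HOH", wat_resid, "W", "water", "HETATM",
                               pos)
            h1 = self._add_atom("H1", "HOH", wat_resid, "W", "water",
                                "HETATM", pos + np.array([0.3, 0, -0.9]))
            h2 = self._add_atom("H2", "HOH", wat_resid, "W", "water",
                                "HETATM", pos + np.array([0.8, -0.6, 0]))
            self.h_parent[h1] = o
            self.h_parent[h2] = o
            self.exterior_waters.append((o, h1, h2))

    # -- system ------------------------------------------------------------
    def system(self) -> System:
        chains = np.array(self.chains, dtype="U2")
        roles = np.array(self.roles, dtype="U8")
        subunit = np.full(len(self.names), -1, dtype=int)
        for i, ch in enumerate(chains):
            if roles[i] == "protein":
                subunit[i] = "ABCDE".index(ch)
        return System(
            names=np.array(self.names, dtype="U6"),
            elements=np.array([_element_of(n) for n in self.names], dtype="U2"),
            resnames=np.array(self.resnames, dtype="U6"),
            resids=np.array(self.resids, dtype=int),
            icodes=np.array([""] * len(self.names), dtype="U2"),
            chain_ids=chains,
            subunit_index=subunit,
            roles=roles,
            segids=chains.astype("U8"),
        )


def _apex_position(theta_deg: float, hinge: np.ndarray, ref: np.ndarray
                   ) -> np.ndarray:
    """Apex centroid realizing the scripted Loop C angle at the hinge."""
    u = _unit(ref - hinge)
    z = np.array([0.0, 0.0, 1.0])
    w = _unit(z - np.dot(z, u) * u)
    th = np.radians(theta_deg)
    return hinge + APEX_ARM_LENGTH * (np.cos(th) * u + np.sin(th) * w)


# --------------------------------------------------------------------------- #
# trajectory generation
# --------------------------------------------------------------------------- #

class SyntheticEnsemble:
    """A synthetic system plus its full coordinate trajectory."""

    def __init__(self, system: System, coords: np.ndarray):
        self.system = system
        self.coords = coords  # (n_frames, n_atoms, 3)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> Frame:
        return Frame(system=self.system, coords=self.coords[i], frame_index=i)

    def frames(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    # -- writers ----------------------------------------------------------
    def _universe(self):
        import MDAnalysis as mda

        sys_ = self.system
        reskeys: list[tuple[str, int]] = []
        res_names: list[str] = []
        atom_resindex = []
        for i in range(sys_.n_atoms):
            key = (str(sys_.chain_ids[i]), int(sys_.resids[i]))
            if not reskeys or reskeys[-1] != key:
                reskeys.append(key)
                res_names.append(str(sys_.resnames[i]))
            atom_resindex.append(len(reskeys) - 1)
        segkeys: list[str] = []
        res_segindex = []
        for ch, _ in reskeys:
            if not segkeys or segkeys[-1] != ch:
                segkeys.append(ch)
            res_segindex.append(len(segkeys) - 1)
        u = mda.Universe.empty(
            n_atoms=sys_.n_atoms, n_residues=len(reskeys),
            n_segments=len(segkeys),
            atom_resindex=np.array(atom_resindex),
            residue_segindex=np.array(res_segindex), trajectory=True)
        u.add_TopologyAttr("names", sys_.names)
        u.add_TopologyAttr("elements", sys_.elements)
        u.add_TopologyAttr("chainIDs", sys_.chain_ids)
        u.add_TopologyAttr(
            "record_types",
            np.where(sys_.roles == "protein", "ATOM", "HETATM"))
        u.add_TopologyAttr("resnames", res_names)
        u.add_TopologyAttr("resids", [resid for _, resid in reskeys])
        u.add_TopologyAttr("segids", segkeys)
        u.atoms.positions = self.coords[0]
        return u

    def write_pdb(self, path) -> None:
        """Write the first frame as a PDB file (the topology partner)."""
        import MDAnalysis as mda

        u = self._universe()
        with mda.Writer(str(path), n_atoms=len(u.atoms)) as w:
            w.write(u.atoms)

    def write_dcd(self, path) -> None:
        import MDAnalysis as mda

        u = self._universe()
        with mda.Writer(str(path), n_atoms=len(u.atoms)) as w:
            for i in range(self.n_frames):
                u.atoms.positions = self.coords[i]
                w.write(u.atoms)

    def write_multimodel_pdb(self, path) -> None:
        import MDAnalysis as mda

        u = self._universe()
        with mda.Writer(str(path), n_atoms=len(u.atoms),
                        multiframe=True) as w:
            for i in range(self.n_frames):
                u.atoms.positions = self.coords[i]
                w.write(u.atoms)


def _orientation_rules(builder: "_Builder", params: GeneratorParams
                       ) -> list[tuple[int, int, int]]:
    """(hydrogen, donor, target-atom) triples for adaptive H orientation.

    Scripted donors keep their hydrogen pointed at the partner atom of their
    interaction; the bridge water and the ligand ammonium point at each
    other.  Targets are real atoms, so the rule is frame-independent.
    """
    rules: list[tuple[int, int, int]] = []
    for p, lbl in enumerate(POCKETS):
        patoms = builder.pocket_atoms[lbl]
        occupied = params.occupancy[p]
        if occupied:
            lig = patoms["ligand"]
            w0_o, w0_h1, w0_h2 = builder.water_slots[lbl][0]
            oe1 = patoms[("P", 173)]["OE1"]
            ser = patoms[("P", 174)]
            rules.append((lig["H1"], lig["N"], w0_o))
            rules.append((w0_h1, w0_o, lig["N"]))
            rules.append((w0_h2, w0_o, oe1))
            rules.append((ser["HG"], ser["OG"], w0_o))
            for script in HBOND_SCRIPTS:
                atoms = patoms[(script["side"], script["resid"])]
                rules.append((atoms[script["hydrogen"]],
                              atoms[script["donor"]],
                              lig[script["anchor"]]))
        for script in CONSERVED_SCRIPTS:
            aside, aresid, aname = script["acceptor"]
            dside, dresid, dname, hname = script["donor"]
            datoms = patoms[(dside, dresid)]
            rules.append((datoms[hname], datoms[dname],
                          patoms[(aside, aresid)][aname]))
    return rules


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(
        np.random.SeedSequence(entropy=int(seed) % (2 ** 31),
                               spawn_key=(STREAM_IDS[stream],))))


def generate_trajectory(params: GeneratorParams, seed: int
                        ) -> tuple[SyntheticEnsemble, GroundTruthLedger]:
    """Generate a scripted trajectory plus its ground-truth ledger."""
    from scipy.spatial import ConvexHull

    builder = _Builder(params)
    system = builder.system()
    n_atoms = system.n_atoms
    T = params.n_frames
    base = np.array(builder.base)

    # random streams (seed-scoped so one schedule never shifts another)
    ev_rng = _rng(seed, "events")
    events: dict = {}
    rates: dict = {}
    for script in HBOND_SCRIPTS:
        r = params.hbond_rates.get(script["key"], 0.0)
        events[("hbond", script["key"])] = ev_rng.random(T) < r
        rates[("hbond", script["key"])] = r
    for script in BRIDGE_SCRIPTS:
        r = params.bridge_rates.get(script["key"], 0.0)
        events[("water_bridge", script["key"])] = ev_rng.random(T) < r
        rates[("water_bridge", script["key"])] = r
    for script in CATION_PI_SCRIPTS:
        r = params.cationpi_rates.get(script["key"], 0.0)
        events[("cation_pi", script["key"])] = ev_rng.random(T) < r
        rates[("cation_pi", script["key"])] = r
    for script in CONSERVED_SCRIPTS:
        r = params.conserved_rates.get(script["key"], 0.0)
        events[("conserved", script["key"])] = ev_rng.random(T) < r
        rates[("conserved", script["key"])] = r

    pp_rng = _rng(seed, "pushpull")
    u_series = pp_rng.standard_normal(T)
    v_series = pp_rng.standard_normal(T)
    c = params.pushpull_coupling
    q_series = c * u_series + np.sqrt(max(0.0, 1.0 - c * c)) * v_series

    wat_rng = _rng(seed, "waters")
    max_slots = max((len(builder.water_slots[lbl]) for lbl in POCKETS),
                    default=0)
    ball_jitter = (wat_rng.random((T, max(max_slots, 1), 3)) - 0.5) \
        * 2.0 * BALL_JITTER

    noise_rng = _rng(seed, "noise")

    scales = params.scales()
    angle_sched = {lbl: params.angles(lbl) for lbl in POCKETS}
    water_sched = {lbl: params.waters(lbl) for lbl in POCKETS}

    # fixed ball-slot directions (unit sphere spiral) for the cage waters
    golden = np.pi * (3.0 - np.sqrt(5.0))
    ks = np.arange(max(max_slots, 1))
    zdir = 1.0 - 2.0 * (ks + 0.5) / max(max_slots, 1)
    rdir = np.sqrt(np.clip(1.0 - zdir ** 2, 0.0, 1.0))
    ball_dirs = np.stack([rdir * np.cos(golden * ks),
                          rdir * np.sin(golden * ks), zdir], axis=1)

    ledger_water = {lbl: water_sched[lbl].copy() for lbl in POCKETS}
    ledger_angle = {lbl: angle_sched[lbl].copy() for lbl in POCKETS}
    ledger_volume = {lbl: np.zeros(T) for lbl in POCKETS}
    ledger_intra = {lbl: np.zeros(T) for lbl in POCKETS}
    ledger_push = {lbl: (np.zeros(T), np.zeros(T)) for lbl in POCKETS}

    coords = np.empty((T, n_atoms, 3))
    idx = builder.index

    # push-pull geometry: SER174(+, pocket q) -> SER145(-, pocket q) and
    # LYS189(-, pocket q-1) -> SER145(-, pocket q), all on consecutive chains
    push_geo = {}
    for p, lbl in enumerate(POCKETS):
        chain_mid = (p + 1) % 5
        chain_far = (p + 2) % 5
        i_b = idx[(chain_mid, 174, "CA")]
        i_f = idx[(chain_mid, 189, "CA")]
        i_e = idx[(chain_far, 145, "CA")]
        e1 = _unit(base[i_e] - base[i_b])
        e2 = _unit(base[i_e] - base[i_f])
        push_geo[lbl] = (i_b, i_f, i_e, e1, e2,
                         float(np.linalg.norm(base[i_e] - base[i_b])),
                         float(np.linalg.norm(base[i_e] - base[i_f])))

    a_amp = params.pushpull_amplitude

    for t in range(T):
        xyz = base.copy()
        s = scales[t]
        for p, lbl in enumerate(POCKETS):
            frame_p = builder.frames[p]
            patoms = builder.pocket_atoms[lbl]
            occupied = params.occupancy[p]

            # --- cage scaling about the vertex centroid -------------------
            cage_res = ([("P", r) for r in PRINCIPAL_CAGE]
                        + [("C", r) for r in COMPLEMENTARY_CAGE])
            ca_idx = [patoms[key]["CA"] for key in cage_res]
            centroid = base[ca_idx].mean(axis=0)
            if s != 1.0:
                for key in cage_res:
                    atoms = patoms[key]
                    ca_new = centroid + s * (base[atoms["CA"]] - centroid)
                    delta = ca_new - base[atoms["CA"]]
                    for name, ai in atoms.items():
                        xyz[ai] = base[ai] + delta

            # --- Loop C apex from the angle schedule ----------------------
            hinge = 0.5 * (xyz[patoms[("P", 215)]["CA"]]
                           + xyz[patoms[("P", 224)]["CA"]])
            ref = 0.5 * (xyz[patoms[("C", 58)]["CA"]]
                         + xyz[patoms[("C", 81)]["CA"]])
            apex = _apex_position(angle_sched[lbl][t], hinge, ref)
            asn = patoms[("P", 219)]
            thr_ca = xyz[patoms[("P", 220)]["CA"]]
            asn_ca = 2.0 * apex - thr_ca
            xyz[asn["CA"]] = asn_ca
            for name in ("N", "H", "C", "O"):
                xyz[asn[name]] = asn_ca + frame_p.rotate(BACKBONE_OFFSETS[name])
            xyz[asn["OD1"]] = asn_ca + frame_p.rotate(ASN219_OD1_OFFSET)

            # --- ligand-anchored scripts ----------------------------------
            lig_anchor = {name: frame_p.to_global(pos)
                          for name, pos in LIGAND_ATOMS.items()}
            w0_pos = lig_anchor["N"] + BRIDGE_ON * frame_p.rotate(W1)
            for script in HBOND_SCRIPTS:
                side, resid = script["side"], script["resid"]
                atoms = patoms[(side, resid)]
                on = occupied and events[("hbond", script["key"])][t]
                dist = HBOND_ON if on else HBOND_OFF
                direction = frame_p.rotate(script["direction"])
                target = lig_anchor[script["anchor"]]
                donor_pos = target + dist * direction
                xyz[atoms[script["donor"]]] = donor_pos
                xyz[atoms[script["hydrogen"]]] = donor_pos - direction
            for script in BRIDGE_SCRIPTS:
                atoms = patoms[(script["side"], script["resid"])]
                on = occupied and events[("water_bridge", script["key"])][t]
                dist = BRIDGE_ON if on else BRIDGE_OFF
                direction = frame_p.rotate(script["direction"])
                pos = w0_pos + dist * direction
                xyz[atoms[script["atom"]]] = pos
                if "hydrogen" in script:
                    hname, hoff = script["hydrogen"]
                    xyz[atoms[hname]] = pos + frame_p.rotate(hoff)
            for script in CATION_PI_SCRIPTS:
                atoms = patoms[(script["side"], script["resid"])]
                on = occupied and events[("cation_pi", script["key"])][t]
                dist = PI_ON if on else PI_OFF
                direction = frame_p.rotate(script["direction"])
                center = lig_anchor["N"] + dist * direction
                ring = _hexagon(center, direction)
                for name, pos in zip(RING_ATOM_NAMES, ring):
                    xyz[atoms[name]] = pos
            # PHE115 keeps a static ring away from the ligand
            phe115 = patoms[("P", 115)]
            ring = _hexagon(xyz[phe115["CA"]] + np.array([0.4, 0.4, -0.5]),
                            frame_p.ey)
            for name, pos in zip(RING_ATOM_NAMES, ring):
                xyz[phe115[name]] = pos

            # --- conserved intersubunit pairs -----------------------------
            for script in CONSERVED_SCRIPTS:
                on = events[("conserved", script["key"])][t]
                aside, aresid, aname = script["acceptor"]
                acc_atoms = patoms[(aside, aresid)]
                if script["acceptor_offset"] is not None:
                    acc_pos = xyz[acc_atoms["CA"]] + frame_p.rotate(
                        script["acceptor_offset"])
                    xyz[acc_atoms[aname]] = acc_pos
                else:
                    acc_pos = xyz[acc_atoms[aname]]
                dside, dresid, dname, hname = script["donor"]
                datoms = patoms[(dside, dresid)]
                dist = CONSERVED_ON if on else CONSERVED_OFF
                direction = frame_p.rotate(script["direction"])
                donor_pos = acc_pos + dist * direction
                xyz[datoms[dname]] = donor_pos
                xyz[datoms[hname]] = donor_pos - direction

            # --- cage waters ----------------------------------------------
            k = int(water_sched[lbl][t])
            slots = builder.water_slots[lbl]
            vertex_centroid = xyz[[patoms[key]["CA"] for key in cage_res]] \
                .mean(axis=0)
            ball_center = vertex_centroid + frame_p.rotate(BALL_CENTER_OFFSET)
            for slot, (o, h1, h2) in enumerate(slots):
                in_use = slot < k
                if occupied and slot == 0:
                    pos = w0_pos  # the bridge water (always slot 0)
                elif in_use:
                    ball_slot = slot - 1 if occupied else slot
                    d = (ball_dirs[ball_slot] * BALL_RADIUS
                         + ball_jitter[t, ball_slot])
                    pos = ball_center + frame_p.rotate(d)
                else:
                    pos = base[o]  # parked far above the pocket
                xyz[o] = pos
                if occupied and slot == 0:
                    xyz[h1] = pos - frame_p.rotate(W1)
                    xyz[h2] = pos + frame_p.rotate(W2)
                else:
                    xyz[h1] = pos + np.array([0.3, 0.0, -0.9])
                    xyz[h2] = pos + np.array([0.8, -0.6, 0.0])

        # --- push-pull displacements (after all pocket scripts so cage
        # scaling cannot overwrite them; each label owns one chain pair) ----
        for lbl in POCKETS:
            i_b, i_f, i_e, e1, e2, _, _ = push_geo[lbl]
            xyz[i_b] = xyz[i_b] + a_amp * u_series[t] * e1
            xyz[i_f] = xyz[i_f] + a_amp * q_series[t] * e2
            ledger_push[lbl][0][t] = float(np.linalg.norm(xyz[i_e] - xyz[i_b]))
            ledger_push[lbl][1][t] = float(np.linalg.norm(xyz[i_e] - xyz[i_f]))

        # --- ledger geometry (pre-noise) ----------------------------------
        for p, lbl in enumerate(POCKETS):
            patoms = builder.pocket_atoms[lbl]
            cage_res = ([("P", r) for r in PRINCIPAL_CAGE]
                        + [("C", r) for r in COMPLEMENTARY_CAGE])
            verts = xyz[[patoms[key]["CA"] for key in cage_res]]
            ledger_volume[lbl][t] = ConvexHull(verts).volume
            prin = verts[:7, :2].mean(axis=0)
            comp = verts[7:, :2].mean(axis=0)
            ledger_intra[lbl][t] = float(np.linalg.norm(prin - comp))

        coords[t] = xyz

    if params.noise_sigma > 0:
        noise = noise_rng.standard_normal(coords.shape) * params.noise_sigma
        if builder.h_parent:
            h_idx = np.fromiter(builder.h_parent.keys(), dtype=int)
            p_idx = np.fromiter(builder.h_parent.values(), dtype=int)
            noise[:, h_idx, :] = noise[:, p_idx, :]
        coords += noise
        # scripted hydrogens reorient toward their (noisy) partner atoms,
        # as rigid waters and hydroxyls do while a bond persists; at sigma=0
        # this is the identity (the script already places them collinear)
        for h, d, a in _orientation_rules(builder, params):
            vec = coords[:, a, :] - coords[:, d, :]
            vec /= np.linalg.norm(vec, axis=1, keepdims=True)
            coords[:, h, :] = coords[:, d, :] + vec

    # interpocket baseline from the noise-free first frame
    axis = np.array([0.0, 0.0, 1.0])
    inter = []
    for p, lbl in enumerate(POCKETS):
        nxt = POCKETS[(p + 1) % 5]
        patoms = builder.pocket_atoms[lbl]
        qatoms = builder.pocket_atoms[nxt]
        comp = np.mean([base[patoms[("C", r)]["CA"]][:2]
                        for r in COMPLEMENTARY_CAGE], axis=0)
        prin = np.mean([base[qatoms[("P", r)]["CA"]][:2]
                        for r in PRINCIPAL_CAGE], axis=0)
        inter.append(float(np.linalg.norm(comp - prin)))

    ledger = GroundTruthLedger(
        n_frames=T,
        occupancy=tuple(params.occupancy),
        water_counts=ledger_water,
        loopc_angles=ledger_angle,
        hull_volumes=ledger_volume,
        intrapocket_distance=ledger_intra,
        intrapocket_target={lbl: params.intrapocket_base
                            - params.contraction_of(lbl) for lbl in POCKETS},
        events=events,
        rates=rates,
        pushpull_coupling=c,
        pushpull_distances=ledger_push,
        interpocket_base=float(np.mean(inter)),
    )
    return SyntheticEnsemble(system=system, coords=coords), ledger


def generate_pentamer(params: Optional[GeneratorParams] = None,
                      seed: int = 0) -> SyntheticEnsemble:
    """Generate a single-frame synthetic pentamer structure."""
    params = params or GeneratorParams()
    single = replace(params, n_frames=1, cage_scale=1.0,
                     water_schedule={
                         lbl: int(np.atleast_1d(params.waters(lbl))[0])
                         for lbl in POCKETS})
    ensemble, _ = generate_trajectory(single, seed)
    return ensemble


def ground_truth_ledger(params: GeneratorParams, seed: int
                        ) -> GroundTruthLedger:
    """The exact expectations for ``generate_trajectory(params, seed)``."""
    _, ledger = generate_trajectory(params, seed)
    return ledger
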