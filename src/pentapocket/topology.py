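"""Pentamer topology: pockets, subunit pairing and residue role assignment.

A homopentameric receptor ECD carries five orthosteric pockets at the
interfaces between adjacent subunits.  Each pocket is formed by a principal
(+) subunit contributing loops A-C (and Loop 2) and a complementary (-)
subunit contributing loops D-F.  Pockets are labelled ``a`` to ``e`` in ring
order; pocket ``x`` has principal subunit ``i`` and complementary subunit
``i+1 (mod 5)`` (reversible for structures of opposite handedness).
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

from .core import System, ValidationError

__all__ = [
    "ResidueRef",
    "PocketSpec",
    "PentamerTopology",
    "POCKET_LABELS",
    "default_config",
    "load_config",
    "build_topology",
    "adjacent_pockets",
]

POCKET_LABELS = ("a", "b", "c", "d", "e")


@dataclass(frozen=True)
class ResidueRef:
    """Reference to one residue of one subunit (author/PDB numbering)."""

    subunit_index: int
    residue_number: int
    residue_name: str
    insertion_code: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.subunit_index <= 4:
            raise ValidationError(
                f"subunit index {self.subunit_index} outside 0-4 for "
                f"{self.residue_name}{self.residue_number}"
            )
        if self.residue_number <= 0:
            raise ValidationError(
                f"non-positive residue number in {self.residue_name}"
                f"{self.residue_number}"
            )

    def __str__(self) -> str:  # e.g. "ARG81(+2)"
        return (f"{self.residue_name}{self.residue_number}"
                f"{self.insertion_code}(sub{self.subunit_index})")


@dataclass(frozen=True)
class PocketSpec:
    """One interfacial binding pocket.

    Carries the 7 principal-side and 4 complementary-side binding residues,
    the three anchor pairs of the Loop C orientation angle, the occupancy
    flag, and (after resolution against a structure) the Calpha atom indices
    used by the per-frame geometry.
    """

    label: str
    principal_subunit: int
    complementary_subunit: int
    principal_binding_residues: tuple[ResidueRef, ...]
    complementary_binding_residues: tuple[ResidueRef, ...]
    loopc_apex_pair: tuple[ResidueRef, ResidueRef]
    loopc_hinge_pair: tuple[ResidueRef, ResidueRef]
    complementary_reference_pair: tuple[ResidueRef, ResidueRef]
    occupied: bool = False
    # resolved atom indices (set by build_topology)
    principal_ca: Optional[np.ndarray] = field(default=None, compare=False)
    complementary_ca: Optional[np.ndarray] = field(default=None, compare=False)
    apex_ca: Optional[np.ndarray] = field(default=None, compare=False)
    hinge_ca: Optional[np.ndarray] = field(default=None, compare=False)
    reference_ca: Optional[np.ndarray] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.label not in POCKET_LABELS:
            raise ValidationError(f"unknown pocket label {self.label!r}")
        if self.principal_subunit == self.complementary_subunit:
            raise ValidationError(
                f"pocket {self.label}: principal and complementary subunits "
                "must differ"
            )
        if len(self.principal_binding_residues) != 7:
            raise ValidationError(
                f"pocket {self.label}: expected 7 principal binding residues, "
                f"got {len(self.principal_binding_residues)}"
            )
        if len(self.complementary_binding_residues) != 4:
            raise ValidationError(
                f"pocket {self.label}: expected 4 complementary binding "
                f"residues, got {len(self.complementary_binding_residues)}"
            )
        pairs = [self.loopc_apex_pair, self.loopc_hinge_pair,
                 self.complementary_reference_pair]
        keys = [frozenset((r.subunit_index, r.residue_number) for r in p)
                for p in pairs]
        if len(set(keys)) != 3:
            raise ValidationError(
                f"pocket {self.label}: the three angle-anchor pairs must be "
                "disjoint residue pairs"
            )

    @property
    def binding_residues(self) -> tuple[ResidueRef, ...]:
        return self.principal_binding_residues + self.complementary_binding_residues

    @property
    def cage_ca(self) -> np.ndarray:
        """Calpha indices of the 11 binding residues (cage vertices)."""
        if self.principal_ca is None or self.complementary_ca is None:
            raise ValidationError(
                f"pocket {self.label} has not been resolved against a structure")
        return np.concatenate([self.principal_ca, self.complementary_ca])


@dataclass(frozen=True)
class PentamerTopology:
    """The validated five-pocket assembly consumed by every analysis module."""

    pockets: tuple[PocketSpec, ...]
    loop_definitions: Mapping[str, tuple[int, int]]
    restrained_tail: tuple[int, int]
    occupancy_pattern: tuple[bool, bool, bool, bool, bool]
    ring_reversed: bool = False

    def __post_init__(self) -> None:
        labels = tuple(p.label for p in self.pockets)
        if labels != POCKET_LABELS:
            raise ValidationError(
                f"pocket labels must cover a-e once in ring order, got {labels}")
        principals = sorted(p.principal_subunit for p in self.pockets)
        complementaries = sorted(p.complementary_subunit for p in self.pockets)
        if principals != [0, 1, 2, 3, 4] or complementaries != [0, 1, 2, 3, 4]:
            raise ValidationError(
                "each subunit must appear exactly once as principal and once "
                "as complementary"
            )
        step = -1 if self.ring_reversed else 1
        for p in self.pockets:
            if p.complementary_subunit != (p.principal_subunit + step) % 5:
                raise ValidationError(
                    f"pocket {p.label}: subunits {p.principal_subunit}/"
                    f"{p.complementary_subunit} are not ring-adjacent"
                )

    def pocket(self, label: str) -> PocketSpec:
        try:
            return self.pockets[POCKET_LABELS.index(label)]
        except ValueError:
            raise ValidationError(f"unknown pocket label {label!r}") from None

    def pocket_specs(self) -> tuple[PocketSpec, ...]:
        """The five pockets in ring order a -> e."""
        return self.pockets

    def occupied_pockets(self) -> tuple[PocketSpec, ...]:
        return tuple(p for p in self.pockets if p.occupied)

    def serialize(self) -> str:
        """Canonical JSON form (used for determinism checks and hashing)."""
        def ref(r: ResidueRef):
            return [r.subunit_index, r.residue_number, r.residue_name,
                    r.insertion_code]

        payload = {
            "pockets": [
                {
                    "label": p.label,
                    "principal_subunit": p.principal_subunit,
                    "complementary_subunit": p.complementary_subunit,
                    "principal_binding_residues":
                        [ref(r) for r in p.principal_binding_residues],
                    "complementary_binding_residues":
                        [ref(r) for r in p.complementary_binding_residues],
                    "loopc_apex_pair": [ref(r) for r in p.loopc_apex_pair],
                    "loopc_hinge_pair": [ref(r) for r in p.loopc_hinge_pair],
                    "complementary_reference_pair":
                        [ref(r) for r in p.complementary_reference_pair],
                    "occupied": p.occupied,
                }
                for p in self.pockets
            ],
            "loop_definitions": {k: list(v)
                                 for k, v in sorted(self.loop_definitions.items())},
            "restrained_tail": list(self.restrained_tail),
            "occupancy_pattern": list(self.occupancy_pattern),
            "ring_reversed": self.ring_reversed,
        }
        return json.dumps(payload, sort_keys=True)


def adjacent_pockets(label: str) -> tuple[str, str]:
    """Cyclic neighbours (left, right) of a pocket label: a -> (e, b)."""
    if label not in POCKET_LABELS:
        raise ValidationError(f"unknown pocket label {label!r}")
    i = POCKET_LABELS.index(label)
    return POCKET_LABELS[(i - 1) % 5], POCKET_LABELS[(i + 1) % 5]


# --------------------------------------------------------------------------- #
# configuration
# --------------------------------------------------------------------------- #

def default_config() -> dict:
    """The shipped glycine-receptor ECD pocket definitions."""
    with importlib.resources.files("pentapocket.data").joinpath(
            "glyr_ecd.yaml").open() as fh:
        return yaml.safe_load(fh)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    base = default_config()
    base.update(cfg or {})
    return base


def _parse_residue_entry(entry) -> tuple[int, str]:
    """Accept {number, name} mappings or 'ARG81'-style strings."""
    if isinstance(entry, Mapping):
        return int(entry["number"]), str(entry["name"]).upper()
    text = str(entry).strip().upper()
    name = "".join(ch for ch in text if ch.isalpha())
    number = int("".join(ch for ch in text if ch.isdigit()))
    return number, name


def _occupancy_from_config(config: Mapping) -> tuple[bool, ...]:
    occ = config.get("occupied_pockets", "all")
    if occ in ("all", True):
        return (True,) * 5
    if occ in ("none", None, False):
        return (False,) * 5
    if isinstance(occ, Mapping):
        return tuple(bool(occ.get(lbl, False)) for lbl in POCKET_LABELS)
    labels = [str(x).lower() for x in occ]
    unknown = set(labels) - set(POCKET_LABELS)
    if unknown:
        raise ValidationError(f"unknown pocket labels in occupancy: {sorted(unknown)}")
    return tuple(lbl in labels for lbl in POCKET_LABELS)


def topology_from_config(config: Mapping,
                         system: Optional[System] = None) -> PentamerTopology:
    """Construct (and optionally resolve) a topology from a config mapping.

    When *system* is given, every declared residue is resolved to its Calpha
    atom; unresolvable residues raise a :class:`ValidationError` naming the
    offender.
    """
    reversed_ring = bool(config.get("ring_reversed", False))
    step = -1 if reversed_ring else 1
    occupancy = _occupancy_from_config(config)

    principal_defs = [_parse_residue_entry(e)
                      for e in config["principal_binding_residues"]]
    complementary_defs = [_parse_residue_entry(e)
                          for e in config["complementary_binding_residues"]]
    apex = [_parse_residue_entry(e) for e in config["loopc_apex_pair"]]
    hinge = [_parse_residue_entry(e) for e in config["loopc_hinge_pair"]]
    cref = [_parse_residue_entry(e)
            for e in config["complementary_reference_pair"]]

    pockets = []
    for i, label in enumerate(POCKET_LABELS):
        prin, comp = i, (i + step) % 5

        def refs(defs, subunit):
            return tuple(ResidueRef(subunit, num, nam) for num, nam in defs)

        spec = PocketSpec(
            label=label,
            principal_subunit=prin,
            complementary_subunit=comp,
            principal_binding_residues=refs(principal_defs, prin),
            complementary_binding_residues=refs(complementary_defs, comp),
            loopc_apex_pair=refs(apex, prin),
            loopc_hinge_pair=refs(hinge, prin),
            complementary_reference_pair=refs(cref, comp),
            occupied=occupancy[i],
        )
        if system is not None:
            spec = _resolve_pocket(spec, system)
        pockets.append(spec)

    loops = {str(k): (int(v[0]), int(v[1]))
             for k, v in config.get("loops", {}).items()}
    tail = tuple(config.get("restrained_tail", (236, 240)))
    return PentamerTopology(
        pockets=tuple(pockets),
        loop_definitions=loops,
        restrained_tail=(int(tail[0]), int(tail[1])),
        occupancy_pattern=occupancy,
        ring_reversed=reversed_ring,
    )


def _resolve_ca(system: System, ref: ResidueRef) -> int:
    try:
        idx = system.atom_index(ref.subunit_index, ref.residue_number, "CA",
                                ref.insertion_code)
    except ValidationError:
        raise ValidationError(
            f"binding residue {ref} cannot be resolved to a Calpha atom"
        ) from None
    resname = str(system.resnames[idx])
    if resname != ref.residue_name:
        raise ValidationError(
            f"residue {ref} resolves to {resname}, expected {ref.residue_name}")
    return idx


def _resolve_pocket(spec: PocketSpec, system: System) -> PocketSpec:
    def resolve_all(refs):
        return np.array([_resolve_ca(system, r) for r in refs], dtype=int)

    return replace(
        spec,
        principal_ca=resolve_all(spec.principal_binding_residues),
        complementary_ca=resolve_all(spec.complementary_binding_residues),
        apex_ca=resolve_all(spec.loopc_apex_pair),
        hinge_ca=resolve_all(spec.loopc_hinge_pair),
        reference_ca=resolve_all(spec.complementary_reference_pair),
    )


def build_topology(system: System, config: Optional[Mapping] = None
                   ) -> PentamerTopology:
    """Validate a structure against a pocket config and return the topology.

    Requires exactly five protein chains; every declared residue must resolve
    to a Calpha atom in the structure.
    """
    if config is None:
        config = default_config()
    subunits = system.protein_subunits
    if len(subunits) != 5:
        raise ValidationError(
            f"expected 5 protein chains, found {len(subunits)}")
    return topology_from_config(config, system=system)
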