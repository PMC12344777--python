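"""Structure/trajectory reading and result-table writing.

File parsing is delegated to MDAnalysis (PDB, DCD, XTC, multi-model PDB);
this module adds the molecule-role annotation (protein / water / ligand /
ion) and the subunit indexing that the analysis modules rely on.  All
coordinates are handled in angstroms (MDAnalysis converts XTC nanometres on
read).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    Frame,
    ION_RESNAMES,
    STANDARD_AMINO_ACIDS,
    System,
    ValidationError,
    WATER_RESNAMES,
    element_from_name,
)

__all__ = [
    "read_structure",
    "iter_trajectory",
    "system_from_universe",
    "SummaryTable",
    "write_tables",
    "read_table",
]


def _load_universe(path, *coordinate_paths):
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            return mda.Universe(str(path), *(str(p) for p in coordinate_paths))
        except (OSError, ValueError, EOFError) as exc:
            raise ValidationError(f"cannot parse {path}: {exc}") from exc


def _classify_atoms(universe, water_resnames, ion_resnames, ligand_resnames):
    """Assign a molecule role to every atom; unknown residues are an error."""
    atoms = universe.atoms
    n = len(atoms)
    resnames = np.array([r.upper() for r in atoms.resnames])
    try:
        record_types = np.array(atoms.record_types)
    except Exception:
        record_types = np.array(["ATOM"] * n)

    roles = np.empty(n, dtype=object)
    offenders = set()
    for i in range(n):
        rn = resnames[i]
        if rn in water_resnames:
            roles[i] = "water"
        elif rn in ion_resnames:
            roles[i] = "ion"
        elif rn in ligand_resnames and record_types[i] == "HETATM":
            roles[i] = "ligand"
        elif rn in STANDARD_AMINO_ACIDS:
            roles[i] = "protein"
        elif rn in ligand_resnames:
            roles[i] = "ligand"
        else:
            offenders.add(rn)
    if offenders:
        raise ValidationError(
            "atoms with unknown molecule role (declare them as water/ion/"
            f"ligand in the config): {sorted(offenders)}"
        )
    return roles.astype("U8")


def system_from_universe(universe, config: Optional[Mapping] = None) -> System:
    """Build a role-annotated :class:`System` from an MDAnalysis universe."""
    config = config or {}
    water = {str(x).upper() for x in config.get("water_resnames", WATER_RESNAMES)}
    ions = {str(x).upper() for x in config.get("ion_resnames", ION_RESNAMES)}
    ligands = {str(x).upper() for x in config.get("ligand_resnames", ("GLY", "LIG"))}

    atoms = universe.atoms
    roles = _classify_atoms(universe, water, ions, ligands)
    names = np.array(atoms.names, dtype="U6")
    try:
        elements = np.array([e.upper() for e in atoms.elements], dtype="U2")
    except Exception:
        elements = np.array([element_from_name(nm) for nm in names], dtype="U2")
    try:
        chain_ids = np.array(atoms.chainIDs, dtype="U2")
    except Exception:
        chain_ids = np.array(atoms.segids, dtype="U4")
    try:
        icodes = np.array(atoms.icodes, dtype="U2")
    except Exception:
        icodes = np.array([""] * len(atoms), dtype="U2")

    # protein chains in order of first appearance -> subunit indices 0..n-1
    subunit = np.full(len(atoms), -1, dtype=int)
    order: list[str] = []
    for i in np.flatnonzero(roles == "protein"):
        cid = str(chain_ids[i])
        if cid not in order:
            order.append(cid)
        subunit[i] = order.index(cid)

    return System(
        names=names,
        elements=elements,
        resnames=np.array([r.upper() for r in atoms.resnames], dtype="U6"),
        resids=np.array(atoms.resids, dtype=int),
        icodes=icodes,
        chain_ids=chain_ids,
        subunit_index=subunit,
        roles=roles,
        segids=np.array(atoms.segids, dtype="U8"),
    )


def read_structure(path, config: Optional[Mapping] = None
                   ) -> tuple[System, Frame]:
    """Read a PDB structure into a role-annotated system + first frame."""
    u = _load_universe(path)
    system = system_from_universe(u, config)
    coords = np.array(u.atoms.positions, dtype=float)
    return system, Frame(system=system, coords=coords, frame_index=0)


def iter_trajectory(system: System, path, stride: int = 1,
                    structure_path=None) -> Iterator[Frame]:
    """Stream frames from a trajectory (DCD/XTC/multi-model PDB).

    ``stride=k`` yields frames 0, k, 2k, ...; the frame index recorded on
    each :class:`Frame` is the index in the file.  An atom-count mismatch
    against *system* fails before the first frame is yielded.
    """
    if stride < 1:
        raise ValidationError(f"stride must be >= 1, got {stride}")
    path = Path(path)
    if structure_path is not None:
        u = _load_universe(structure_path, path)
    elif path.suffix.lower() in (".pdb", ".ent"):
        u = _load_universe(path)
    else:
        raise ValidationError(
            f"{path.suffix} trajectories need a structure_path topology")
    if len(u.atoms) != system.n_atoms:
        raise ValidationError(
            f"atom count mismatch: trajectory has {len(u.atoms)} atoms, "
            f"structure has {system.n_atoms}"
        )
    for ts in u.trajectory[::stride]:
        yield Frame(
            system=system,
            coords=np.array(ts.positions, dtype=float),
            frame_index=int(ts.frame),
            time=float(ts.time) if ts.time is not None else None,
        )


# --------------------------------------------------------------------------- #
# tables
# --------------------------------------------------------------------------- #

class SummaryTable:
    """Occurrence/mean/std summary rows keyed by (model, pocket, name).

    The canonical column layout is ``model, pocket, residue, occurrence_pct,
    mean, std`` with a ``units`` attribute carried alongside.
    """

    COLUMNS = ("model", "pocket", "residue", "occurrence_pct", "mean", "std")

    def __init__(self, rows: Optional[Sequence[Mapping]] = None,
                 units: str = "", name: str = "summary"):
        self.units = units
        self.name = name
        self.frame = pd.DataFrame(list(rows or []), columns=list(self.COLUMNS))
        self._validate()

    def _validate(self) -> None:
        occ = self.frame["occurrence_pct"].dropna()
        if len(occ) and ((occ < 0).any() or (occ > 100).any()):
            raise ValidationError("occurrence values must lie in [0, 100]")
        std = self.frame["std"].dropna()
        if len(std) and (std < -1e-12).any():
            raise ValidationError("standard deviations must be >= 0")

    def __len__(self) -> int:
        return len(self.frame)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.6g")

    def to_json(self, path) -> None:
        payload = {
            "name": self.name,
            "units": self.units,
            "rows": json.loads(self.frame.to_json(orient="records")),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def write_tables(tables: Mapping[str, SummaryTable], out_dir) -> list[Path]:
    """Write each table as CSV and JSON under *out_dir*; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for key, table in tables.items():
        csv_path = out_dir / f"{key}.csv"
        json_path = out_dir / f"{key}.json"
        table.to_csv(csv_path)
        table.to_json(json_path)
        written += [csv_path, json_path]
    return written


def read_table(path) -> SummaryTable:
    """Reread a written CSV summary table (round-trip partner of write_tables)."""
    frame = pd.read_csv(path)
    missing = set(SummaryTable.COLUMNS) - set(frame.columns)
    if missing:
        raise ValidationError(f"summary table {path} lacks columns {sorted(missing)}")
    table = SummaryTable(name=Path(path).stem)
    table.frame = frame[list(SummaryTable.COLUMNS)]
    table._validate()
    return table
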