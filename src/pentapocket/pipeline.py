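"""End-to-end orchestration: trajectory -> descriptor bundle -> report.

``run_pipeline`` drives every analysis stage over one model (one occupancy
pattern): interaction occurrence tables per bound pocket, per-pocket
water/volume/angle time series, adjacent-pocket angle correlations,
assembly distances, contact maps, push-pull correlations, conserved-pair
hydrogen bonds, intersubunit totals and the two collective variables.  The
bundle is deterministic for identical inputs, and writes CSV/JSON tables
plus a manifest with a config hash and frame counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import Frame, System, ValidationError
from .topology import (PentamerTopology, build_topology, default_config,
                       POCKET_LABELS)
from .interactions import (AROMATIC_RING_ATOMS, InteractionCriteria,
                           acceptor_atom_indices, detect_cation_pi,
                           detect_hbonds, detect_water_bridges,
                           intersubunit_hbond_total,
                           occurrence_summary, polar_atom_indices)
from .pocket import pocket_timeseries
from .assembly import (adjacent_angle_correlations, backbone_rmsd,
                       conserved_pair_hbonds, contact_map, loop_rmsf,
                       pocket_com_distances, pushpull_analysis)
from .colvars import SolvationParams, com_distance, solvation_coordination
from . import io as pio

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ResultBundle", "run_pipeline", "render_report"]


@dataclass
class RunConfig:
    """Inputs and options of one pipeline run."""

    structure: Optional[str] = None       # PDB path
    trajectory: Optional[str] = None      # DCD/XTC/multi-model PDB path
    frames: Optional[Sequence[Frame]] = None  # in-memory alternative
    config: Optional[Mapping] = None      # pocket/criteria config mapping
    model: str = "model"
    stride: int = 1
    pockets: Optional[Sequence[str]] = None
    out_dir: Optional[str] = None
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.stride < 1:
            raise ValidationError("stride must be >= 1")
        if self.frames is None:
            if not self.structure:
                raise ValidationError("either frames or a structure path is "
                                      "required")
            if not Path(self.structure).exists():
                raise ValidationError(f"structure path {self.structure} "
                                      "does not exist")
            if self.trajectory and not Path(self.trajectory).exists():
                raise ValidationError(f"trajectory path {self.trajectory} "
                                      "does not exist")


@dataclass
class ResultBundle:
    """All pipeline outputs for one model."""

    model: str
    manifest: dict
    occurrence_tables: dict      # kind -> {"per_residue": df, "per_pocket": df}
    pocket_series: dict          # label -> PocketTimeSeries
    pocket_summaries: pd.DataFrame
    angle_correlations: dict
    assembly_table: object
    contact_maps: dict
    pushpull: dict
    conserved_pairs: pd.DataFrame
    intersubunit: dict
    rmsd: dict                   # subunit -> series
    rmsf: pd.DataFrame
    colvars: pd.DataFrame


def _stage(name):
    """Decorator-free stage guard: wraps exceptions with the stage name."""
    class _Ctx:
        def __init__(self, label):
            self.label = label

        def __enter__(self):
            logger.info("stage: %s", self.label)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"stage {self.label!r} failed: {exc}") from exc
            return False
    return _Ctx(name)


class _StageError(ValidationError):
    pass


def _load_frames(config: RunConfig, topo_config: Mapping
                 ) -> tuple[System, list[Frame]]:
    if config.frames is not None:
        frames = list(config.frames)[::config.stride]
        if not frames:
            raise ValidationError("no frames to analyze")
        return frames[0].system, frames
    system, first = pio.read_structure(config.structure, topo_config)
    if config.trajectory:
        frames = list(pio.iter_trajectory(
            system, config.trajectory, stride=config.stride,
            structure_path=config.structure))
    else:
        frames = [first]
    return system, frames


def _assign_ligands(system: System, frames: Sequence[Frame],
                    topology: PentamerTopology) -> dict[str, np.ndarray]:
    """Assign each ligand molecule to its nearest pocket (first frame)."""
    groups = system.ligand_groups()
    first = frames[0]
    out: dict[str, np.ndarray] = {}
    for group in groups:
        center = first.coords[group].mean(axis=0)
        best, best_d = None, np.inf
        for spec in topology.pocket_specs():
            cage_center = first.coords[spec.cage_ca].mean(axis=0)
            d = np.linalg.norm(center - cage_center)
            if d < best_d:
                best, best_d = spec.label, d
        if best in out:
            raise ValidationError(
                f"two ligand molecules assigned to pocket {best}")
        out[best] = group
    return out


def _pocket_interactions(frames: Sequence[Frame],
                         topology: PentamerTopology,
                         ligand_by_pocket: Mapping[str, np.ndarray],
                         criteria: InteractionCriteria):
    """Hydrogen-bond / bridge / cation-pi records for every bound pocket."""
    system = frames[0].system
    records = {"hbond": [], "water_bridge": [], "cation_pi": []}
    for spec in topology.pocket_specs():
        if spec.label not in ligand_by_pocket:
            continue
        lig = ligand_by_pocket[spec.label]
        residue_atoms = {}
        rings = {}
        for ref in spec.binding_residues:
            atoms = system.residue_atom_indices(ref.subunit_index,
                                                ref.residue_number)
            residue_atoms[ref] = atoms
            ring_names = AROMATIC_RING_ATOMS.get(ref.residue_name)
            if ring_names:
                names = system.names[atoms]
                ring_idx = [atoms[list(names).index(nm)]
                            for nm in ring_names if nm in names]
                if len(ring_idx) >= 5:
                    rings[ref] = np.array(ring_idx)
        residue_of = {int(a): ref for ref, atoms in residue_atoms.items()
                      for a in atoms}
        all_res_atoms = np.concatenate(list(residue_atoms.values()))
        for frame in frames:
            lig_polar = polar_atom_indices(frame, lig)
            res_polar = polar_atom_indices(frame, all_res_atoms)
            lig_acc = acceptor_atom_indices(frame, lig, criteria)
            res_acc = acceptor_atom_indices(frame, all_res_atoms, criteria)
            recs = detect_hbonds(frame, res_polar, lig_acc, criteria,
                                 pocket=spec.label, residue_of=residue_of)
            recs += detect_hbonds(frame, lig_polar, res_acc, criteria,
                                  pocket=spec.label, residue_of=residue_of)
            records["hbond"].extend(recs)
            records["water_bridge"].extend(detect_water_bridges(
                frame, lig, residue_atoms, criteria, pocket=spec.label))
            cations = lig[(frame.system.names[lig] == "N")]
            records["cation_pi"].extend(detect_cation_pi(
                frame, cations, rings, criteria, pocket=spec.label))
    return records


def run_pipeline(config: RunConfig) -> ResultBundle:
    """Run every analysis stage; see the module docstring."""
    config.validate()
    logging.getLogger("pentapocket").setLevel(config.log_level.upper())
    topo_config = dict(default_config())
    if config.config:
        topo_config.update(config.config)
    criteria = InteractionCriteria.from_config(topo_config)

    with _stage("structure_io"):
        system, frames = _load_frames(config, topo_config)
        topology = build_topology(system, topo_config)
    n_frames = len(frames)

    with _stage("interaction_analysis"):
        ligand_by_pocket = _assign_ligands(system, frames, topology)
        # occupancy follows the ligands actually present in the structure
        observed = sorted(ligand_by_pocket)
        if set(observed) != {lbl for lbl, occ
                             in zip(POCKET_LABELS,
                                    topology.occupancy_pattern) if occ}:
            from .topology import topology_from_config

            topo_config = dict(topo_config)
            topo_config["occupied_pockets"] = observed
            topology = topology_from_config(topo_config, system=system)
        records = _pocket_interactions(frames, topology, ligand_by_pocket,
                                       criteria)
        occurrence_tables = {
            kind: occurrence_summary(recs, n_frames, model=config.model)
            for kind, recs in records.items()
        }
        intersubunit = intersubunit_hbond_total(frames, topology, criteria)

    with _stage("pocket_geometry"):
        wanted = config.pockets or POCKET_LABELS
        pocket_series = {
            spec.label: pocket_timeseries(frames, spec)
            for spec in topology.pocket_specs() if spec.label in wanted
        }
        pocket_summaries = pd.DataFrame(
            [ts.summary() for ts in pocket_series.values()])

    with _stage("assembly_analysis"):
        angle_correlations = (
            adjacent_angle_correlations(pocket_series)
            if len(pocket_series) == 5 and n_frames >= 3 else {})
        assembly_table = pocket_com_distances(frames, topology)
        contact_maps = {
            spec.label: contact_map(
                frames, spec,
                cutoff=float(topo_config["criteria"].get("contact_cutoff", 11.0)))
            for spec in topology.pocket_specs() if spec.label in wanted
        }
        pushpull = pushpull_analysis(frames, topology)
        conserved = conserved_pair_hbonds(
            frames, topology,
            pairs=[tuple(p) for p in topo_config.get("conserved_pairs", [])]
            or None, criteria=criteria)
        rmsd = {su: backbone_rmsd(frames, su)
                for su in system.protein_subunits}
        rmsf = (pd.concat([loop_rmsf(frames, su, topology.loop_definitions)
                           for su in system.protein_subunits],
                          ignore_index=True)
                if n_frames >= 2 else pd.DataFrame())

    with _stage("collective_variables"):
        cv_rows = []
        solv_params = SolvationParams()
        for label, lig in sorted(ligand_by_pocket.items()):
            spec = topology.pocket(label)
            site = np.concatenate([
                system.residue_atom_indices(r.subunit_index, r.residue_number)
                for r in spec.binding_residues])
            for frame in frames:
                cv_rows.append({
                    "pocket": label,
                    "frame": frame.frame_index,
                    "com_distance_A": com_distance(frame, lig, site),
                    "solvation": solvation_coordination(
                        frame, solv_params, ligand_atoms=lig),
                })
        colvars = pd.DataFrame(
            cv_rows, columns=["pocket", "frame", "com_distance_A", "solvation"])

    manifest = {
        "software": "pentapocket",
        "version": _version(),
        "model": config.model,
        "n_frames": n_frames,
        "stride": config.stride,
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            json.dumps(_hashable(topo_config), sort_keys=True).encode()
        ).hexdigest(),
        "occupancy": list(topology.occupancy_pattern),
    }
    bundle = ResultBundle(
        model=config.model, manifest=manifest,
        occurrence_tables=occurrence_tables, pocket_series=pocket_series,
        pocket_summaries=pocket_summaries,
        angle_correlations=angle_correlations,
        assembly_table=assembly_table, contact_maps=contact_maps,
        pushpull=pushpull, conserved_pairs=conserved,
        intersubunit=intersubunit, rmsd=rmsd, rmsf=rmsf, colvars=colvars,
    )
    if config.out_dir:
        write_bundle(bundle, config.out_dir)
    return bundle


def _version() -> str:
    from . import __version__

    return __version__


def _hashable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _hashable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_hashable(v) for v in obj]
    return obj


def write_bundle(bundle: ResultBundle, out_dir) -> None:
    """Serialize a bundle as CSV/JSON files under *out_dir*."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "manifest.json").write_text(json.dumps(bundle.manifest, indent=1))
    for kind, tables in bundle.occurrence_tables.items():
        tables["per_residue"].to_csv(out / f"occurrence_{kind}.csv",
                                     index=False, float_format="%.6g")
        tables["per_pocket"].to_csv(out / f"counts_{kind}.csv",
                                    index=False, float_format="%.6g")
    for label, ts in bundle.pocket_series.items():
        ts.to_frame().to_csv(out / f"pocket_{label}_timeseries.csv",
                             index=False, float_format="%.8g")
    bundle.pocket_summaries.to_csv(out / "pocket_summaries.csv", index=False,
                                   float_format="%.6g")
    (out / "angle_correlations.json").write_text(
        json.dumps(bundle.angle_correlations, indent=1))
    bundle.assembly_table.to_frame().to_csv(out / "assembly_distances.csv",
                                            index=False, float_format="%.6g")
    for label, cmap in bundle.contact_maps.items():
        cmap.to_frame().to_csv(out / f"contact_map_{label}.csv",
                               float_format="%.6g")
    pp = {lbl: {"correlation": s.correlation}
          for lbl, s in bundle.pushpull.items()}
    (out / "pushpull_correlations.json").write_text(json.dumps(pp, indent=1))
    bundle.conserved_pairs.to_csv(out / "conserved_pair_hbonds.csv",
                                  index=False, float_format="%.6g")
    (out / "intersubunit_hbonds.json").write_text(
        json.dumps(bundle.intersubunit, indent=1))
    bundle.colvars.to_csv(out / "colvars.csv", index=False,
                          float_format="%.8g")
    if len(bundle.rmsf):
        bundle.rmsf.to_csv(out / "loop_rmsf.csv", index=False,
                           float_format="%.6g")


def render_report(bundle: ResultBundle, display_offset: bool = True) -> str:
    """Human-readable per-model summary mirroring the published table layout.

    Bound pockets are flagged; when *display_offset* is set the water-count
    column of bound pockets is raised by 5 in the rendered table only
    (display-only convention, flagged in the header).
    """
    lines = [f"model: {bundle.model}",
             f"frames: {bundle.manifest['n_frames']}"]
    if not bundle.pocket_series:
        lines.append("no pockets analyzed")
        return "\n".join(lines)
    note = (" (+5 display offset on bound-pocket waters)"
            if display_offset else "")
    lines.append(f"\npocket summaries{note}:")
    lines.append(f"{'pocket':>6} {'bound':>6} {'waters':>8} {'volume':>9} "
                 f"{'angle':>7}")
    for label, ts in bundle.pocket_series.items():
        s = ts.summary(display_offset=display_offset)
        flag = "bound" if ts.occupied else "empty"
        lines.append(f"{label:>6} {flag:>6} {s['water_mean']:>8.2f} "
                     f"{s['volume_mean']:>9.1f} {s['angle_mean']:>7.2f}")
    lines.append("\nintrapocket distances (A; bound pockets marked *):")
    at = bundle.assembly_table
    for label, ts in bundle.pocket_series.items():
        mark = "*" if ts.occupied else " "
        lines.append(f"  {label}{mark} {at.intrapocket_mean[label]:.2f} "
                     f"+- {at.intrapocket_std[label]:.2f}")
    lines.append("\ninterpocket distances (A):")
    for lbl, v in at.interpocket_mean.items():
        lines.append(f"  {lbl} {v:.2f} +- {at.interpocket_std[lbl]:.2f}")
    if bundle.angle_correlations:
        lines.append("\nadjacent Loop C angle correlations:")
        for lbl, r in bundle.angle_correlations.items():
            lines.append(f"  {lbl} r = {r:+.3f}")
    lines.append("\nintersubunit hydrogen bonds: "
                 f"{bundle.intersubunit['total_mean']:.1f} "
                 f"+- {bundle.intersubunit['total_std']:.1f}")
    return "\n".join(lines)
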