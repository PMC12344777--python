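"""Shared fixtures: synthetic runs and random-geometry frame builders."""

from __future__ import annotations

import numpy as np
import pytest

from pentapocket.core import Frame, System
from pentapocket.synthetic import GeneratorParams, generate_trajectory
from pentapocket.topology import build_topology, default_config


def topology_for(ensemble, occupancy):
    cfg = dict(default_config())
    cfg["occupied_pockets"] = [lbl for lbl, occ in zip("abcde", occupancy)
                               if occ]
    return build_topology(ensemble.system, cfg)


def make_system(names, elements, resids, chains, roles, resnames=None,
                subunits=None):
    """Construct a bare System from parallel lists (test scaffolding)."""
    n = len(names)
    resnames = resnames or ["UNK"] * n
    if subunits is None:
        subunits = [(-1 if r != "protein" else 0)
                    for r in roles]
    return System(
        names=np.array(names, dtype="U6"),
        elements=np.array(elements, dtype="U2"),
        resnames=np.array(resnames, dtype="U6"),
        resids=np.array(resids, dtype=int),
        icodes=np.array([""] * n, dtype="U2"),
        chain_ids=np.array(chains, dtype="U2"),
        subunit_index=np.array(subunits, dtype=int),
        roles=np.array(roles, dtype="U8"),
    )


def random_polar_frame(rng, n_donors=20, n_acceptors=20, n_waters=0,
                       box=12.0):
    """A frame of donor (N-H) groups, acceptor O atoms and optional waters
    scattered uniformly in a cubic box; every group is its own residue."""
    names, elements, resids, chains, roles, resnames = [], [], [], [], [], []
    coords = []
    resid = 0
    for _ in range(n_donors):
        resid += 1
        base = rng.uniform(0, box, 3)
        hdir = rng.normal(size=3)
        hdir /= np.linalg.norm(hdir)
        for nm, el, pos in (("N", "N", base), ("H", "H", base + hdir)):
            names.append(nm)
            elements.append(el)
            resids.append(resid)
            chains.append("D")
            roles.append("protein")
            resnames.append("ASN")
            coords.append(pos)
    for _ in range(n_acceptors):
        resid += 1
        names.append("O")
        elements.append("O")
        resids.append(resid)
        chains.append("A")
        roles.append("protein")
        resnames.append("SER")
        coords.append(rng.uniform(0, box, 3))
    for _ in range(n_waters):
        resid += 1
        base = rng.uniform(0, box, 3)
        for nm, el, pos in (("O", "O", base),
                            ("H1", "H", base + np.array([0.95, 0, 0.2])),
                            ("H2", "H", base + np.array([-0.3, 0.9, 0.2]))):
            names.append(nm)
            elements.append(el)
            resids.append(resid)
            chains.append("W")
            roles.append("water")
            resnames.append("HOH")
            coords.append(pos)
    subunits = [0 if c == "D" else (1 if c == "A" else -1) for c in chains]
    system = make_system(names, elements, resids, chains, roles, resnames,
                         subunits)
    return Frame(system=system, coords=np.array(coords), frame_index=0)


def random_rigid_motion(rng):
    """A uniform random rotation matrix and translation vector."""
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=rng).as_matrix(), rng.uniform(-50, 50, 3)


def apply_rigid(frame: Frame, R, t) -> Frame:
    return Frame(system=frame.system, coords=frame.coords @ R.T + t,
                 frame_index=frame.frame_index)


# --------------------------------------------------------------------------- #
# session-scoped synthetic runs (generation dominates the suite cost)
# --------------------------------------------------------------------------- #

@pytest.fixture(scope="session")
def noise_free_run():
    """Short noise-free two-ligand run with exact scripted ground truth."""
    params = GeneratorParams(n_frames=60, noise_sigma=0.0,
                             occupancy=(False, False, True, False, True),
                             pushpull_amplitude=0.0)
    ensemble, ledger = generate_trajectory(params, seed=101)
    topology = topology_for(ensemble, params.occupancy)
    return params, ensemble, ledger, topology


@pytest.fixture(scope="session")
def noisy_run():
    """The study-condition run: sigma = 0.2 A, 500 frames, two ligands."""
    params = GeneratorParams(n_frames=500, noise_sigma=0.2,
                             occupancy=(False, False, True, False, True))
    ensemble, ledger = generate_trajectory(params, seed=202)
    topology = topology_for(ensemble, params.occupancy)
    return params, ensemble, ledger, topology


@pytest.fixture(scope="session")
def noisy_bundle(noisy_run):
    """Full pipeline output for the noisy study-condition run."""
    from pentapocket.pipeline import RunConfig, run_pipeline

    _, ensemble, _, _ = noisy_run
    return run_pipeline(RunConfig(frames=list(ensemble.frames()),
                                  model="Two"))
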