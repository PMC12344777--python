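"""Geometric interaction detectors against closed-form cases and brute-force
oracles."""

import numpy as np
import pytest

from pentapocket.core import Frame, ValidationError
from pentapocket.interactions import (InteractionCriteria, detect_cation_pi,
                                      detect_hbonds, detect_water_bridges,
                                      occurrence_summary, InteractionRecord,
                                      intersubunit_hbond_total,
                                      ring_center_normal)
from pentapocket.topology import ResidueRef

from .conftest import (apply_rigid, make_system, random_polar_frame,
                       random_rigid_motion)
from .oracles import cation_pi_oracle, hbond_pairs_oracle, water_bridge_oracle

CRIT = InteractionCriteria()


def _nho_frame(o_pos):
    system = make_system(
        names=["N", "H", "O"], elements=["N", "H", "O"],
        resids=[1, 1, 2], chains=["A", "A", "B"],
        roles=["protein"] * 3, resnames=["ASN", "ASN", "SER"],
        subunits=[0, 0, 1])
    coords = np.array([[0.0, 0, 0], [1.0, 0, 0], list(o_pos)])
    return Frame(system=system, coords=coords)


def test_collinear_hbond_detected():
    frame = _nho_frame((2.9, 0, 0))
    recs = detect_hbonds(frame, [0], [2], CRIT)
    assert len(recs) == 1
    assert recs[0].distance == pytest.approx(2.9)
    assert recs[0].angle == pytest.approx(180.0)


def test_hbond_distance_cutoff_is_sharp():
    assert detect_hbonds(_nho_frame((3.1, 0, 0)), [0], [2], CRIT) == []


def test_hbond_angle_cutoff():
    # acceptor perpendicular to the N-H bond at the H: angle 90 deg
    assert detect_hbonds(_nho_frame((1.0, 1.5, 0)), [0], [2], CRIT) == []


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_hbond_oracle_agreement_random_frames(seed):
    rng = np.random.default_rng(seed)
    for _ in range(30):
        frame = random_polar_frame(rng, n_donors=25, n_acceptors=25)
        donors = np.flatnonzero(frame.system.names == "N")
        acceptors = np.flatnonzero((frame.system.names == "O")
                                   & (frame.system.roles == "protein"))
        got = {r.atoms for r in detect_hbonds(frame, donors, acceptors, CRIT)}
        assert got == hbond_pairs_oracle(frame, donors, acceptors)


def test_hbond_rigid_motion_invariance():
    rng = np.random.default_rng(7)
    frame = random_polar_frame(rng, n_donors=30, n_acceptors=30)
    donors = np.flatnonzero(frame.system.names == "N")
    acceptors = np.flatnonzero(frame.system.names == "O")
    base = {r.atoms for r in detect_hbonds(frame, donors, acceptors, CRIT)}
    for _ in range(5):
        R, t = random_rigid_motion(rng)
        moved = apply_rigid(frame, R, t)
        assert {r.atoms
                for r in detect_hbonds(moved, donors, acceptors, CRIT)} == base


# --------------------------------------------------------------------------- #
# water bridges
# --------------------------------------------------------------------------- #

def _bridge_frame(water_offset=(0.0, 0.0, 0.0)):
    """Ligand N-H3 group, one water, one GLU carboxylate O."""
    system = make_system(
        names=["N", "H1", "O", "H1", "H2", "OE1"],
        elements=["N", "H", "O", "H", "H", "O"],
        resids=[1, 1, 2, 2, 2, 3],
        chains=["L", "L", "W", "W", "W", "A"],
        roles=["ligand", "ligand", "water", "water", "water", "protein"],
        resnames=["GLY", "GLY", "HOH", "HOH", "HOH", "GLU"],
        subunits=[-1, -1, -1, -1, -1, 0])
    wo = np.array([2.6, 0, 0]) + np.array(water_offset)
    coords = np.array([
        [0.0, 0, 0], [1.0, 0, 0],          # ligand N donates toward water
        wo, wo + [0.0, 1.0, 0.0], wo + [0.0, -0.3, 0.95],
        wo + [0.0, 2.6, 0.0],              # OE1 collinear with water H1
    ])
    return Frame(system=system, coords=coords)


def test_water_bridge_both_legs():
    frame = _bridge_frame()
    ref = ResidueRef(0, 173, "GLU")
    recs = detect_water_bridges(frame, [0, 1], {ref: [5]}, CRIT)
    assert len(recs) == 1
    assert recs[0].residue == ref
    assert recs[0].water_id == 2


def test_one_sided_water_contact_is_no_bridge():
    frame = _bridge_frame()
    ref = ResidueRef(0, 173, "GLU")
    far = frame.coords.copy()
    far[5] = [20.0, 20, 20]  # residue leg broken
    frame2 = Frame(system=frame.system, coords=far)
    assert detect_water_bridges(frame2, [0, 1], {ref: [5]}, CRIT) == []


@pytest.mark.parametrize("seed", [3, 4])
def test_water_bridge_oracle_composition(seed):
    rng = np.random.default_rng(seed)
    for _ in range(20):
        frame = random_polar_frame(rng, n_donors=8, n_acceptors=8,
                                   n_waters=15, box=10.0)
        sys_ = frame.system
        # treat donor groups as the "ligand", acceptor Os as residues
        lig = np.flatnonzero(sys_.chain_ids == "D")
        residues = {ResidueRef(1, int(sys_.resids[i]), "SER"): [int(i)]
                    for i in np.flatnonzero((sys_.names == "O")
                                            & (sys_.roles == "protein"))}
        got = {(r.residue, r.water_id)
               for r in detect_water_bridges(frame, lig, residues, CRIT)}
        assert got == water_bridge_oracle(frame, lig, residues)


# --------------------------------------------------------------------------- #
# cation-pi
# --------------------------------------------------------------------------- #

def _ring_frame(cation_pos):
    names = ["NZ"] + ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    elements = ["N"] + ["C"] * 6
    angles = np.radians(np.arange(6) * 60)
    ring = np.stack([1.39 * np.cos(angles), 1.39 * np.sin(angles),
                     np.zeros(6)], axis=1)
    coords = np.vstack([[cation_pos], ring])
    system = make_system(names, elements, resids=[1] + [2] * 6,
                         chains=["L"] + ["A"] * 6,
                         roles=["ligand"] + ["protein"] * 6,
                         resnames=["GLY"] + ["PHE"] * 6,
                         subunits=[-1] + [0] * 6)
    return Frame(system=system, coords=coords)


def test_cation_on_ring_axis_interacts():
    frame = _ring_frame([0, 0, 5.0])
    ref = ResidueRef(0, 175, "PHE")
    recs = detect_cation_pi(frame, [0], {ref: range(1, 7)}, CRIT)
    assert len(recs) == 1
    assert recs[0].angle in (pytest.approx(0.0, abs=1e-9),
                             pytest.approx(180.0, abs=1e-9))


def test_cation_in_ring_plane_does_not_interact():
    frame = _ring_frame([5.0, 0, 0])
    ref = ResidueRef(0, 175, "PHE")
    assert detect_cation_pi(frame, [0], {ref: range(1, 7)}, CRIT) == []


def test_cation_pi_oracle_200_random_placements():
    rng = np.random.default_rng(11)
    ref = ResidueRef(0, 175, "PHE")
    for _ in range(200):
        pos = rng.uniform(-7, 7, 3)
        frame = _ring_frame(pos)
        got = bool(detect_cation_pi(frame, [0], {ref: range(1, 7)}, CRIT))
        assert got == cation_pi_oracle(pos, [0, 0, 0], [0, 0, 1])


def test_degenerate_ring_fails():
    pts = np.outer(np.arange(6), [1.0, 0, 0])  # collinear
    with pytest.raises(ValidationError):
        ring_center_normal(pts)


# --------------------------------------------------------------------------- #
# aggregation
# --------------------------------------------------------------------------- #

def _record(kind, frame_index, pocket="a", resid=81, name="ARG"):
    return InteractionRecord(kind=kind, frame_index=frame_index, pocket=pocket,
                             residue=ResidueRef(1, resid, name), atoms=(0,),
                             distance=2.5)


def test_occurrence_saturation():
    recs = [_record("hbond", t) for t in range(10)]
    out = occurrence_summary(recs, n_frames=10)
    assert out["per_residue"].occurrence_pct.iloc[0] == 100.0


def test_occurrence_empty_records():
    out = occurrence_summary([], n_frames=10)
    assert len(out["per_residue"]) == 0
    assert len(out["per_pocket"]) == 0


def test_occurrence_counts_multiplicity():
    # two simultaneous bonds in half the frames -> occurrence 50%, mean 1.0
    recs = []
    for t in range(0, 10, 2):
        recs += [_record("hbond", t), _record("hbond", t)]
    out = occurrence_summary(recs, n_frames=10)
    assert out["per_residue"].occurrence_pct.iloc[0] == 50.0
    assert out["per_pocket"].mean_count.iloc[0] == pytest.approx(1.0)


def test_occurrence_idempotent_under_duplicate_free_union():
    recs = [_record("hbond", t) for t in range(5)]
    once = occurrence_summary(recs, 10)["per_residue"]
    twice = occurrence_summary(recs + recs, 10)["per_residue"]
    assert once.occurrence_pct.iloc[0] == twice.occurrence_pct.iloc[0]


def test_occurrence_requires_frames():
    with pytest.raises(ValidationError):
        occurrence_summary([], 0)


def test_intersubunit_engineered_bond_per_interface(noise_free_run):
    _, ensemble, ledger, topology = noise_free_run
    res = intersubunit_hbond_total([ensemble.frame(0)], topology)
    keys = ["GLU119-ARG147", "LYS49-ASP96", "ASN219-ASN58",
            "THR220-ARG135", "ASN219-LYS189"]
    scripted = sum(int(ledger.events[("conserved", k)][0]) for k in keys) * 5
    assert res["total_mean"] == scripted
    assert len(res["per_interface_mean"]) == 5
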