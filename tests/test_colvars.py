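"""Collective variables: binding-site COM distance and ligand solvation."""

import numpy as np
import pytest

from pentapocket.colvars import (SolvationParams, com_distance,
                                 solvation_coordination, switching_term)
from pentapocket.core import Frame, ValidationError

from .conftest import apply_rigid, make_system, random_rigid_motion
from .oracles import solvation_oracle


def _frame_with(names, elements, roles, coords, resids=None):
    n = len(names)
    resids = resids or list(range(1, n + 1))
    resnames = ["GLY" if r == "ligand" else
                ("HOH" if r == "water" else "ALA") for r in roles]
    system = make_system(names, elements, resids, ["X"] * n, roles, resnames,
                         subunits=[-1 if r != "protein" else 0 for r in roles])
    return Frame(system=system, coords=np.asarray(coords, float))


def test_com_distance_two_atoms():
    frame = _frame_with(["C", "CA"], ["C", "C"], ["ligand", "protein"],
                        [[0, 0, 0], [4.0, 0, 0]])
    assert com_distance(frame, [0], [1]) == pytest.approx(4.0)


def test_com_distance_coincident_centroids():
    frame = _frame_with(["C", "C", "CA", "CA"], ["C"] * 4,
                        ["ligand", "ligand", "protein", "protein"],
                        [[1, 0, 0], [-1, 0, 0], [0, 2, 0], [0, -2, 0]])
    assert com_distance(frame, [0, 1], [2, 3]) == pytest.approx(0.0)


def test_com_distance_mass_weighted_oracle():
    rng = np.random.default_rng(5)
    for _ in range(20):
        nl, ns = rng.integers(2, 8), rng.integers(2, 8)
        elements = (list(rng.choice(["C", "N", "O", "H"], nl))
                    + list(rng.choice(["C", "N", "O"], ns)))
        coords = rng.uniform(-10, 10, (nl + ns, 3))
        frame = _frame_with(elements, elements,
                            ["ligand"] * nl + ["protein"] * ns, coords)
        masses = frame.system.masses
        com_l = np.average(coords[:nl], axis=0, weights=masses[:nl])
        com_s = np.average(coords[nl:], axis=0, weights=masses[nl:])
        expect = np.linalg.norm(com_l - com_s)
        assert com_distance(frame, range(nl), range(nl, nl + ns)) == \
            pytest.approx(expect, abs=1e-12)


def test_com_distance_empty_selection_fails():
    frame = _frame_with(["C"], ["C"], ["ligand"], [[0, 0, 0]])
    with pytest.raises(ValidationError):
        com_distance(frame, [], [0])


# --------------------------------------------------------------------------- #
# solvation coordination
# --------------------------------------------------------------------------- #

def _solvation_frame(water_positions, lig_pos=(0.0, 0.0, 0.0)):
    names = ["CA"]
    elements = ["C"]
    roles = ["ligand"]
    coords = [list(lig_pos)]
    for w in water_positions:
        names.append("O")
        elements.append("O")
        roles.append("water")
        coords.append(list(w))
    return _frame_with(names, elements, roles, coords)


def test_pair_at_d0_gives_six_tenths():
    frame = _solvation_frame([[2.5, 0, 0]])
    assert solvation_coordination(frame) == pytest.approx(0.6, abs=1e-12)


def test_small_distance_limit_is_one():
    frame = _solvation_frame([[1e-3, 0, 0]])
    assert solvation_coordination(frame) == pytest.approx(1.0, abs=1e-6)


def test_no_water_within_cutoff_gives_zero():
    frame = _solvation_frame([[12.0, 0, 0], [0, 15.0, 0]])
    assert solvation_coordination(frame) == 0.0


def test_continuity_across_d0():
    params = SolvationParams()
    lo = switching_term(np.array([2.5 - 1e-6]), params)[0]
    hi = switching_term(np.array([2.5 + 1e-6]), params)[0]
    assert lo == pytest.approx(0.6, abs=1e-5)
    assert hi == pytest.approx(0.6, abs=1e-5)
    assert abs(lo - hi) < 1e-5


def test_pair_term_monotone_decreasing_in_unit_interval():
    params = SolvationParams()
    d = np.linspace(0.05, 9.95, 2000)
    vals = switching_term(d, params)
    assert np.all(np.diff(vals) < 0)
    assert np.all(vals > 0) and np.all(vals < 1)


def test_solvation_against_double_sum_oracle():
    rng = np.random.default_rng(8)
    waters = rng.uniform(-12, 12, (500, 3))
    lig = rng.uniform(-2, 2, (3, 3))
    names = ["CA", "C", "N"] + ["O"] * 500
    elements = ["C", "C", "N"] + ["O"] * 500
    roles = ["ligand"] * 3 + ["water"] * 500
    coords = np.vstack([lig, waters])
    frame = _frame_with(names, elements, roles, coords)
    got = solvation_coordination(frame)
    expect = solvation_oracle(lig[:2], waters)  # carbons only
    assert got == pytest.approx(expect, abs=1e-10)


def test_cv_rigid_motion_invariance():
    rng = np.random.default_rng(13)
    waters = rng.uniform(-8, 8, (50, 3))
    frame = _solvation_frame(waters, lig_pos=(0.5, -0.5, 0.2))
    base_solv = solvation_coordination(frame)
    R, t = random_rigid_motion(rng)
    moved = apply_rigid(frame, R, t)
    assert solvation_coordination(moved) == pytest.approx(base_solv, rel=1e-8)


def test_solvation_params_validation():
    with pytest.raises(ValidationError):
        SolvationParams(d0=-1.0)
    with pytest.raises(ValidationError):
        SolvationParams(cutoff=2.0)
    with pytest.raises(ValidationError):
        SolvationParams(numerator_exponent=5)
    with pytest.raises(ValidationError):
        SolvationParams(numerator_exponent=10, denominator_exponent=6)
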