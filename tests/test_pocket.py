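"""Convex-hull cage, water counting and the Loop C orientation angle."""

import numpy as np
import pytest

from pentapocket.core import Frame, ValidationError, angle_deg
from pentapocket.pocket import (cage_from_points, count_waters_in_cage,
                                loopc_angle, pocket_cage, pocket_timeseries,
                                points_in_hull)
from pentapocket.synthetic import GeneratorParams, generate_trajectory
from pentapocket.topology import build_topology

from .conftest import make_system, random_rigid_motion
from .oracles import hull_volume_mc_oracle, points_in_hull_oracle


def _water_frame(water_positions):
    n = len(water_positions)
    names, elements, resids, chains, roles, resnames = [], [], [], [], [], []
    for k in range(n):
        names.append("O")
        elements.append("O")
        resids.append(k + 1)
        chains.append("W")
        roles.append("water")
        resnames.append("HOH")
    system = make_system(names, elements, resids, chains, roles, resnames,
                         subunits=[-1] * n)
    return Frame(system=system, coords=np.asarray(water_positions, float))


CUBE = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1],
                 [1, 1, 0], [1, 0, 1], [0, 1, 1], [1, 1, 1]], dtype=float)


def test_unit_cube_volume():
    points = np.vstack([CUBE, [[0.5, 0.5, 0.5], [0.2, 0.3, 0.4],
                               [0.7, 0.6, 0.5]]])  # 8 vertices + 3 interior
    cage = cage_from_points(points)
    assert cage.volume == pytest.approx(1.0, abs=1e-12)


def test_regular_tetrahedron_volume():
    a = 2.0
    tetra = a / np.sqrt(2) * np.array(
        [[1, 0, -1 / np.sqrt(2) * 0 + 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0]],
        dtype=float)
    # canonical embedding: vertices of a regular tetrahedron with edge a
    tetra = a / 2.0 * np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1],
                                [-1, -1, 1]], dtype=float) / np.sqrt(2)
    interior = np.array([[0, 0, 0], [0.05, 0.02, -0.03]])
    cage = cage_from_points(np.vstack([tetra, interior]))
    assert cage.volume == pytest.approx(a ** 3 / (6 * np.sqrt(2)), rel=1e-12)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_hull_volume_against_monte_carlo(seed):
    rng = np.random.default_rng(seed)
    points = rng.uniform(-5, 5, size=(11, 3))
    cage = cage_from_points(points)
    mc = hull_volume_mc_oracle(points, n_samples=1_000_000, seed=seed + 100)
    assert cage.volume == pytest.approx(mc, rel=0.01)


def test_degenerate_coplanar_points_fail():
    flat = np.column_stack([np.random.default_rng(0).uniform(0, 1, (8, 2)),
                            np.zeros(8)])
    with pytest.raises(ValidationError):
        cage_from_points(flat)


def test_water_at_centroid_counted():
    cage = cage_from_points(CUBE * 10)
    frame = _water_frame([[5.0, 5.0, 5.0]])
    assert count_waters_in_cage(frame, cage) == 1


def test_far_waters_not_counted():
    cage = cage_from_points(CUBE)
    frame = _water_frame([[30.0, 30, 30], [-20, 0, 0]])
    assert count_waters_in_cage(frame, cage) == 0


def test_boundary_water_counts_as_inside():
    cage = cage_from_points(CUBE)
    frame = _water_frame([[0.5, 0.5, 1.0]])  # exactly on the top facet
    assert count_waters_in_cage(frame, cage) == 1


@pytest.mark.parametrize("seed", [5, 6])
def test_point_in_hull_matches_delaunay_oracle(seed):
    rng = np.random.default_rng(seed)
    for _ in range(50):
        vertices = rng.uniform(-4, 4, size=(11, 3))
        cage = cage_from_points(vertices)
        pts = rng.uniform(-5, 5, size=(100, 3))
        mine = points_in_hull(pts, cage)
        oracle = points_in_hull_oracle(pts, vertices)
        assert np.array_equal(mine, oracle)


def test_hull_volume_rigid_invariance_and_scaling():
    rng = np.random.default_rng(3)
    points = rng.uniform(-3, 3, size=(11, 3))
    v0 = cage_from_points(points).volume
    R, t = random_rigid_motion(rng)
    assert cage_from_points(points @ R.T + t).volume == \
        pytest.approx(v0, rel=1e-8)
    for s in (0.5, 2.0):
        assert cage_from_points(points * s).volume == \
            pytest.approx(v0 * s ** 3, rel=1e-10)


# --------------------------------------------------------------------------- #
# Loop C angle
# --------------------------------------------------------------------------- #

def test_orthogonal_rays_angle():
    assert angle_deg([1, 0, 0], [0, 0, 0], [0, 1, 0]) == pytest.approx(90.0)


def test_straight_angle():
    assert angle_deg([1, 0, 0], [0, 0, 0], [-1, 0, 0]) == pytest.approx(180.0)


def test_angle_formula_oracle_random_triples():
    rng = np.random.default_rng(9)
    for _ in range(100):
        a, o, b = rng.uniform(-10, 10, (3, 3))
        u, v = a - o, b - o
        expect = np.degrees(np.arccos(np.clip(
            np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1)))
        assert angle_deg(a, o, b) == pytest.approx(expect, abs=1e-10)


def test_coincident_points_fail():
    with pytest.raises(ValidationError):
        angle_deg([1, 0, 0], [1, 0, 0], [0, 1, 0])


def test_loopc_angle_pair_swap_symmetry(noise_free_run):
    from dataclasses import replace

    _, ensemble, _, topology = noise_free_run
    frame = ensemble.frame(0)
    spec = topology.pocket_specs()[0]
    swapped = replace(spec, apex_ca=spec.apex_ca[::-1].copy(),
                      hinge_ca=spec.hinge_ca[::-1].copy(),
                      reference_ca=spec.reference_ca[::-1].copy())
    assert loopc_angle(frame, spec) == pytest.approx(
        loopc_angle(frame, swapped), abs=1e-12)


def test_loopc_angle_rigid_invariance(noise_free_run):
    _, ensemble, _, topology = noise_free_run
    frame = ensemble.frame(0)
    spec = topology.pocket_specs()[1]
    base = loopc_angle(frame, spec)
    rng = np.random.default_rng(4)
    R, t = random_rigid_motion(rng)
    moved = Frame(system=frame.system, coords=frame.coords @ R.T + t)
    assert loopc_angle(moved, spec) == pytest.approx(base, rel=1e-8)


# --------------------------------------------------------------------------- #
# time series
# --------------------------------------------------------------------------- #

def test_constant_water_series(noise_free_run):
    _, ensemble, ledger, topology = noise_free_run
    spec = topology.pocket("c")  # occupied, scripted 1 interior water
    ts = pocket_timeseries(list(ensemble.frames()), spec)
    assert ts.summary()["water_mean"] == pytest.approx(1.0)
    assert ts.summary()["water_std"] == 0.0


def test_display_offset_applies_only_to_bound_summary(noise_free_run):
    _, ensemble, _, topology = noise_free_run
    frames = [ensemble.frame(i) for i in range(3)]
    bound = pocket_timeseries(frames, topology.pocket("c"))
    empty = pocket_timeseries(frames, topology.pocket("a"))
    assert bound.summary(display_offset=True)["water_mean"] == \
        bound.summary()["water_mean"] + 5.0
    assert empty.summary(display_offset=True)["water_mean"] == \
        empty.summary()["water_mean"]
    # stored data never offset
    assert bound.water_count.max() <= 2


def test_scripted_cage_swelling_monotone_volume():
    n = 30
    params = GeneratorParams(
        n_frames=n, noise_sigma=0.0, occupancy=(False,) * 5,
        pushpull_amplitude=0.0,
        loopc_amplitude={lbl: 0.0 for lbl in "abcde"},
        cage_scale=np.linspace(1.0, 1.3, n))
    ensemble, _ = generate_trajectory(params, seed=21)
    topology = build_topology(ensemble.system)
    ts = pocket_timeseries(list(ensemble.frames()), topology.pocket("b"))
    assert np.all(np.diff(ts.hull_volume) > 0)
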