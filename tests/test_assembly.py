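"""Assembly metrics: channel axis, RMSD/RMSF, contact maps, centre-of-mass
distances, correlations and the push-pull analysis."""

import numpy as np
import pytest

from pentapocket.assembly import (backbone_rmsd, channel_axis, contact_map,
                                  conserved_pair_hbonds, loop_rmsf,
                                  loopc_correlation, pocket_com_distances,
                                  pushpull_analysis)
from pentapocket.core import Frame, ValidationError
from pentapocket.pocket import pocket_timeseries
from pentapocket.synthetic import GeneratorParams, generate_trajectory
from pentapocket.topology import build_topology

from .conftest import apply_rigid, make_system, random_rigid_motion
from .oracles import contact_map_oracle


# --------------------------------------------------------------------------- #
# channel axis
# --------------------------------------------------------------------------- #

def test_axis_of_ideal_pentamer_is_z(noise_free_run):
    _, ensemble, _, topology = noise_free_run
    axis = channel_axis(ensemble.frame(0), topology)
    assert abs(axis @ np.array([0, 0, 1.0])) > 1 - 1e-6
    # sign: oriented from the restrained tail (low z) toward the body (+z)
    assert axis[2] > 0


def test_axis_follows_known_rotation(noise_free_run):
    _, ensemble, _, topology = noise_free_run
    frame = ensemble.frame(0)
    rng = np.random.default_rng(0)
    R, t = random_rigid_motion(rng)
    base_axis = channel_axis(frame, topology)
    moved = apply_rigid(frame, R, t)
    axis = channel_axis(moved, topology)
    expect = R @ base_axis
    assert np.linalg.norm(axis - expect) < 1e-6


def test_axis_translation_invariance(noise_free_run):
    _, ensemble, _, topology = noise_free_run
    frame = ensemble.frame(0)
    a0 = channel_axis(frame, topology)
    moved = Frame(system=frame.system, coords=frame.coords + [100, -50, 7])
    assert np.allclose(channel_axis(moved, topology), a0, atol=1e-9)


# --------------------------------------------------------------------------- #
# RMSD / RMSF
# --------------------------------------------------------------------------- #

def _backbone_blob(n_res=250, seed=0):
    """A single-subunit system of n_res pseudo-residues (4 backbone atoms)."""
    rng = np.random.default_rng(seed)
    names, elements, resids, chains, roles, resnames = [], [], [], [], [], []
    coords = []
    for r in range(n_res):
        base = rng.uniform(0, 40, 3)
        for k, nm in enumerate(("N", "CA", "C", "O")):
            names.append(nm)
            elements.append(nm[0])
            resids.append(r + 1)
            chains.append("A")
            roles.append("protein")
            resnames.append("ALA")
            coords.append(base + 0.5 * k)
    system = make_system(names, elements, resids, chains, roles, resnames,
                         subunits=[0] * len(names))
    return system, np.asarray(coords)


def test_rmsd_identity_is_zero():
    system, xyz = _backbone_blob()
    frame = Frame(system=system, coords=xyz)
    assert backbone_rmsd([frame], 0)[0] == pytest.approx(0.0, abs=1e-6)


def test_rmsd_removes_rigid_motion():
    system, xyz = _backbone_blob()
    f0 = Frame(system=system, coords=xyz)
    rng = np.random.default_rng(1)
    R, t = random_rigid_motion(rng)
    f1 = Frame(system=system, coords=xyz @ R.T + t, frame_index=1)
    assert backbone_rmsd([f0, f1], 0)[1] == pytest.approx(0.0, abs=1e-8)


def test_rmsd_of_isotropic_noise_is_sigma_root3():
    system, xyz = _backbone_blob(n_res=250)  # 1000 backbone atoms
    sigma = 0.3
    rng = np.random.default_rng(2)
    noisy = xyz + rng.normal(0, sigma, xyz.shape)
    f0 = Frame(system=system, coords=xyz)
    f1 = Frame(system=system, coords=noisy, frame_index=1)
    rmsd = backbone_rmsd([f0, f1], 0)[1]
    assert rmsd == pytest.approx(sigma * np.sqrt(3), rel=0.05)


def test_rmsf_static_trajectory_is_zero():
    system, xyz = _backbone_blob(n_res=30)
    frames = [Frame(system=system, coords=xyz.copy(), frame_index=i)
              for i in range(4)]
    df = loop_rmsf(frames, 0, {"A": (1, 30)})
    assert np.allclose(df.rmsf, 0.0, atol=1e-10)


def test_rmsf_localizes_jitter_to_one_loop():
    system, xyz = _backbone_blob(n_res=60, seed=3)
    sigma = 0.4
    rng = np.random.default_rng(4)
    loop_mask = (system.resids >= 10) & (system.resids <= 20)
    frames = []
    for i in range(200):
        c = xyz.copy()
        c[loop_mask] += rng.normal(0, sigma, (loop_mask.sum(), 3))
        frames.append(Frame(system=system, coords=c, frame_index=i))
    df = loop_rmsf(frames, 0, {"hot": (10, 20), "cold": (30, 60)})
    hot = df[df.loop == "hot"].rmsf.mean()
    cold = df[df.loop == "cold"].rmsf.mean()
    assert hot == pytest.approx(sigma * np.sqrt(3), rel=0.1)
    assert cold < 0.15 * hot


def test_rmsf_empty_pocket_loopc_exceeds_bound(noisy_run):
    _, ensemble, _, topology = noisy_run
    frames = [ensemble.frame(i) for i in range(0, 500, 5)]
    # pocket c bound (principal subunit 2), pocket a empty (principal 0)
    bound = loop_rmsf(frames, 2, topology.loop_definitions)
    empty = loop_rmsf(frames, 0, topology.loop_definitions)
    bound_c = bound[(bound.loop == "C") & (bound.resid == 219)].rmsf.iloc[0]
    empty_c = empty[(empty.loop == "C") & (empty.resid == 219)].rmsf.iloc[0]
    assert empty_c > bound_c  # wider scripted swing for the open lid


# --------------------------------------------------------------------------- #
# contact maps
# --------------------------------------------------------------------------- #

def _two_ca_frames(distance, n_frames=3):
    system = make_system(
        names=["CA", "CA"], elements=["C", "C"], resids=[1, 2],
        chains=["A", "B"], roles=["protein", "protein"],
        resnames=["ALA", "ALA"], subunits=[0, 1])
    coords = np.array([[0.0, 0, 0], [distance, 0, 0]])
    return [Frame(system=system, coords=coords.copy(), frame_index=i)
            for i in range(n_frames)]


class _SpecStub:
    label = "a"
    principal_subunit = 0
    complementary_subunit = 1


@pytest.mark.parametrize("distance,expected", [(10.0, 1.0), (12.0, 0.0)])
def test_contact_map_pinned_pairs(distance, expected):
    cmap = contact_map(_two_ca_frames(distance), _SpecStub(), cutoff=11.0)
    assert cmap.matrix[0, 0] == expected


def test_contact_map_matches_bruteforce(noisy_run):
    _, ensemble, _, topology = noisy_run
    frames = [ensemble.frame(i) for i in range(0, 60, 3)]
    spec = topology.pocket_specs()[2]
    cmap = contact_map(frames, spec, cutoff=11.0)
    sys_ = ensemble.system
    pi = np.flatnonzero((sys_.names == "CA") & (sys_.subunit_index ==
                                                spec.principal_subunit))
    ci = np.flatnonzero((sys_.names == "CA") & (sys_.subunit_index ==
                                                spec.complementary_subunit))
    oracle = contact_map_oracle(frames, pi, ci, 11.0)
    assert np.array_equal(cmap.matrix, oracle)


# --------------------------------------------------------------------------- #
# pocket centre-of-mass distances
# --------------------------------------------------------------------------- #

def test_c5_symmetric_distances_equal(noise_free_run):
    params, ensemble, _, _ = noise_free_run
    # rebuild with uniform occupancy so all pockets are equivalent
    from dataclasses import replace

    uni, _ = generate_trajectory(
        replace(params, occupancy=(True,) * 5, n_frames=3), seed=9)
    topo = build_topology(uni.system)
    table = pocket_com_distances([uni.frame(0)], topo)
    intra = list(table.intrapocket_mean.values())
    inter = list(table.interpocket_mean.values())
    assert np.ptp(intra) < 1e-9
    assert np.ptp(inter) < 1e-9


def test_contraction_recovered(noisy_run):
    _, ensemble, ledger, topology = noisy_run
    frames = list(ensemble.frames())
    table = pocket_com_distances(frames, topology)
    # bound pockets (c, e) scripted 0.8 A closer than empty (a, b, d)
    for lbl in "ce":
        assert table.intrapocket_mean[lbl] == pytest.approx(
            ledger.intrapocket_target[lbl], abs=0.05)
    for lbl in "abd":
        assert table.intrapocket_mean[lbl] == pytest.approx(
            ledger.intrapocket_target[lbl], abs=0.05)


def test_mean_positions_variant_close_to_per_frame(noise_free_run):
    _, ensemble, _, topology = noise_free_run
    frames = [ensemble.frame(i) for i in range(5)]
    per_frame = pocket_com_distances(frames, topology)
    on_means = pocket_com_distances(frames, topology, mean_positions=True)
    for lbl in "abcde":
        assert on_means.intrapocket_mean[lbl] == pytest.approx(
            per_frame.intrapocket_mean[lbl], abs=0.05)


# --------------------------------------------------------------------------- #
# correlations
# --------------------------------------------------------------------------- #

def test_correlation_of_series_with_itself():
    x = np.random.default_rng(0).normal(size=100)
    assert loopc_correlation(x, x) == pytest.approx(1.0)
    assert loopc_correlation(x, -x) == pytest.approx(-1.0)


def test_correlation_recovers_bivariate_rho():
    rng = np.random.default_rng(12)
    n = 10_000
    u = rng.normal(size=n)
    v = rng.normal(size=n)
    rho = 0.5
    y = rho * u + np.sqrt(1 - rho ** 2) * v
    assert loopc_correlation(u, y) == pytest.approx(rho, abs=0.03)


def test_zero_variance_correlation_fails():
    with pytest.raises(ValidationError):
        loopc_correlation(np.ones(10), np.arange(10.0))


def test_pushpull_static_structure_undefined(noise_free_run):
    _, ensemble, _, topology = noise_free_run
    frames = [ensemble.frame(0)] * 5  # rigid static trajectory
    out = pushpull_analysis(frames, topology)
    assert all(s.correlation is None for s in out.values())


def test_pushpull_correlation_monotone_in_coupling():
    rs = []
    for c in (0.0, 0.5, 1.0):
        params = GeneratorParams(n_frames=400, noise_sigma=0.2,
                                 pushpull_coupling=c)
        ensemble, _ = generate_trajectory(params, seed=31)
        topo = build_topology(ensemble.system)
        out = pushpull_analysis(list(ensemble.frames()), topo)
        rs.append(np.mean([s.correlation for s in out.values()]))
    assert rs[0] < rs[1] < rs[2]
    assert abs(rs[0]) < 3 / np.sqrt(400)  # independent jitter -> null bound


def test_pushpull_exact_coupling_noise_free():
    params = GeneratorParams(n_frames=50, noise_sigma=0.0,
                             pushpull_coupling=1.0)
    ensemble, _ = generate_trajectory(params, seed=33)
    topo = build_topology(ensemble.system)
    out = pushpull_analysis(list(ensemble.frames()), topo)
    for s in out.values():
        assert s.correlation == pytest.approx(1.0, abs=1e-9)


# --------------------------------------------------------------------------- #
# conserved pairs
# --------------------------------------------------------------------------- #

def test_conserved_pair_occurrence_recovery(noise_free_run):
    _, ensemble, ledger, topology = noise_free_run
    frames = list(ensemble.frames())
    df = conserved_pair_hbonds(frames, topology)
    for key in ("GLU119-ARG147", "LYS49-ASP96", "ASN219-ASN58",
                "THR220-ARG135", "ASN219-LYS189"):
        expect = 100.0 * ledger.events[("conserved", key)].mean()
        got = df[df.pair == key].occurrence_pct
        assert np.allclose(got, expect)


def test_separated_residues_never_bond(noise_free_run):
    _, ensemble, _, topology = noise_free_run
    frames = [ensemble.frame(0)]
    df = conserved_pair_hbonds(frames, topology, pairs=[("GLU119", "ASP96")])
    assert (df.occurrence_pct == 0.0).all()
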