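"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a detector's answer from the printed definitions with
plain double loops / closed-form geometry and no shared code path with the
package implementation (no KDTree, no hull equations).
"""

from __future__ import annotations

import numpy as np

from pentapocket.core import Frame


def hbond_pairs_oracle(frame: Frame, donors, acceptors, d_cut=3.0,
                       ang_cut=135.0, h_cut=1.2):
    """All (donor, H, acceptor) triples satisfying the criteria, by triple loop."""
    system = frame.system
    xyz = frame.coords
    out = set()
    donors = list(donors)
    acceptors = list(acceptors)
    hydrogens = [i for i in range(system.n_atoms) if system.elements[i] == "H"]
    for d in donors:
        hs = [h for h in hydrogens
              if system.chain_ids[h] == system.chain_ids[d]
              and system.resids[h] == system.resids[d]
              and np.linalg.norm(xyz[h] - xyz[d]) < h_cut]
        for a in acceptors:
            if a == d:
                continue
            if (system.chain_ids[a] == system.chain_ids[d]
                    and system.resids[a] == system.resids[d]):
                continue
            if np.linalg.norm(xyz[a] - xyz[d]) > d_cut:
                continue
            for h in hs:
                u = xyz[d] - xyz[h]
                v = xyz[a] - xyz[h]
                cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
                ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                if ang >= ang_cut:
                    out.add((int(d), int(h), int(a)))
    return out


def water_bridge_oracle(frame: Frame, ligand_atoms, residue_atoms,
                        d_cut=3.0, ang_cut=135.0):
    """(residue, water-oxygen) pairs bridging ligand and residue, by
    composing the hydrogen-bond oracle with a shared-water join."""
    system = frame.system
    waters = [int(i) for i in system.water_oxygens]

    def polar(idx):
        return [int(i) for i in idx if system.elements[i] in ("N", "O")]

    def acceptors(idx):
        keep = []
        for i in polar(idx):
            if system.elements[i] == "O":
                keep.append(i)
                continue
            has_h = any(
                system.chain_ids[h] == system.chain_ids[i]
                and system.resids[h] == system.resids[i]
                and np.linalg.norm(frame.coords[h] - frame.coords[i]) < 1.2
                for h in range(system.n_atoms) if system.elements[h] == "H")
            if not has_h:
                keep.append(i)
        return keep

    def bonded_waters(partner):
        found = set()
        for (d, h, a) in hbond_pairs_oracle(frame, waters, acceptors(partner),
                                            d_cut, ang_cut):
            found.add(d)
        for (d, h, a) in hbond_pairs_oracle(frame, polar(partner), waters,
                                            d_cut, ang_cut):
            found.add(a)
        return found

    lig_w = bonded_waters(ligand_atoms)
    out = set()
    for ref, atoms in residue_atoms.items():
        for w in bonded_waters(atoms) & lig_w:
            out.add((ref, w))
    return out


def cation_pi_oracle(cation, center, normal, d_cut=6.0, window=45.0):
    """Direct arccos test against a ring whose centre/normal are known
    exactly by construction."""
    vec = np.asarray(cation, float) - np.asarray(center, float)
    dist = np.linalg.norm(vec)
    if dist == 0 or dist > d_cut:
        return False
    cosang = np.dot(np.asarray(normal, float), vec / dist)
    ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
    return ang < window or ang > 180.0 - window


def points_in_hull_oracle(points, vertices):
    """Delaunay-membership test (independent of the facet half-space path)."""
    from scipy.spatial import Delaunay

    tri = Delaunay(np.asarray(vertices, float))
    return tri.find_simplex(np.atleast_2d(points)) >= 0


def hull_volume_mc_oracle(vertices, n_samples=1_000_000, seed=0):
    """Monte-Carlo rejection estimate of a convex hull volume."""
    vertices = np.asarray(vertices, float)
    lo = vertices.min(axis=0)
    hi = vertices.max(axis=0)
    rng = np.random.default_rng(seed)
    pts = rng.uniform(lo, hi, size=(n_samples, 3))
    frac = np.mean(points_in_hull_oracle(pts, vertices))
    return float(frac * np.prod(hi - lo))


def contact_map_oracle(frames, idx_a, idx_b, cutoff):
    """Per-frame double-loop distance thresholding."""
    n = 0
    total = np.zeros((len(idx_a), len(idx_b)))
    for frame in frames:
        n += 1
        for i, a in enumerate(idx_a):
            for j, b in enumerate(idx_b):
                if np.linalg.norm(frame.coords[a] - frame.coords[b]) < cutoff:
                    total[i, j] += 1
    return total / n


def solvation_oracle(lig_xyz, wat_xyz, d0=2.5, cutoff=10.0, n=6, m=10):
    """Direct double loop over the printed switching sum."""
    total = 0.0
    for c in np.atleast_2d(lig_xyz):
        for w in np.atleast_2d(wat_xyz):
            d = float(np.linalg.norm(c - w))
            if d > cutoff:
                continue
            x = d / d0
            if abs(x - 1.0) < 1e-12:
                total += n / m
            else:
                total += (1 - x ** n) / (1 - x ** m)
    return total
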