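"""Subunit-assembly metrics: RMSD/RMSF, contact maps, pocket centre-of-mass
distances in the plane orthogonal to the channel axis, Loop C correlations,
and the push-pull distance analysis.

The channel (pseudo-C5) axis is estimated as the inertia-tensor eigenvector
with the unique eigenvalue of the Calpha cloud -- parameter-free and stable
for a ring-shaped assembly -- oriented from the restrained C-terminal tail
toward the body of the domain.  "Centre of mass of the Calpha" is the
unweighted centroid (all Calpha are carbons).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation
from scipy.stats import pearsonr

from .core import Frame, System, ValidationError
from .interactions import (InteractionCriteria, acceptor_atom_indices,
                           detect_hbonds, polar_atom_indices)
from .pocket import PocketTimeSeries
from .topology import PentamerTopology, PocketSpec, POCKET_LABELS, ResidueRef

__all__ = [
    "channel_axis",
    "backbone_rmsd",
    "loop_rmsf",
    "ContactMap",
    "contact_map",
    "PocketAssemblyTable",
    "pocket_com_distances",
    "loopc_correlation",
    "adjacent_angle_correlations",
    "PushPullSeries",
    "pushpull_analysis",
    "conserved_pair_hbonds",
]

BACKBONE_NAMES = ("N", "CA", "C", "O")


def _ca_indices(system: System, subunit: Optional[int] = None) -> np.ndarray:
    mask = (system.roles == "protein") & (system.names == "CA")
    if subunit is not None:
        mask &= system.subunit_index == subunit
    return np.flatnonzero(mask)


def channel_axis(frame: Frame, topology: PentamerTopology) -> np.ndarray:
    """Unit vector along the pseudo-C5 channel axis.

    Eigenvector of the Calpha inertia tensor whose eigenvalue is most
    separated from the other two (the symmetry axis of a ring has the unique
    moment); sign-oriented from the restrained-tail centroid toward the
    overall Calpha centroid.
    """
    system = frame.system
    ca = _ca_indices(system)
    if ca.size < 3:
        raise ValidationError("need at least 3 Calpha atoms for the axis")
    pts = frame.coords[ca] - frame.coords[ca].mean(axis=0)
    r2 = np.sum(pts ** 2)
    inertia = r2 * np.eye(3) - pts.T @ pts  # unit masses
    evals, evecs = np.linalg.eigh(inertia)
    gaps = [min(abs(evals[i] - evals[j]) for j in range(3) if j != i)
            for i in range(3)]
    if max(gaps) < 1e-10 * max(abs(evals).max(), 1.0):
        raise ValidationError("degenerate inertia tensor: no unique axis")
    axis = evecs[:, int(np.argmax(gaps))]
    axis = axis / np.linalg.norm(axis)

    lo, hi = topology.restrained_tail
    tail_mask = (system.resids[ca] >= lo) & (system.resids[ca] <= hi)
    if tail_mask.any():
        tail_centroid = frame.coords[ca[tail_mask]].mean(axis=0)
        direction = frame.coords[ca].mean(axis=0) - tail_centroid
        if np.dot(axis, direction) < 0:
            axis = -axis
    return axis


def _superpose(mobile: np.ndarray, reference: np.ndarray
               ) -> tuple[np.ndarray, float]:
    """Optimal rigid superposition of *mobile* onto *reference* (Kabsch).

    Returns the transformed coordinates and the post-fit RMSD.
    """
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    rot, rssd = Rotation.align_vectors(reference - rc, mobile - mc)
    moved = rot.apply(mobile - mc) + rc
    return moved, float(rssd / np.sqrt(len(mobile)))


def _backbone_indices(system: System, subunit: int) -> np.ndarray:
    mask = ((system.subunit_index == subunit)
            & np.isin(system.names, BACKBONE_NAMES))
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValidationError(f"no backbone atoms for subunit {subunit}")
    return idx


def backbone_rmsd(frames: Sequence[Frame], subunit: int,
                  reference: Optional[Frame] = None) -> np.ndarray:
    """Per-frame backbone RMSD of one subunit to the reference frame.

    The reference defaults to the first frame of the run; rigid-body motion
    is removed by optimal superposition before the deviation is measured.
    """
    frames = list(frames)
    if not frames:
        raise ValidationError("empty trajectory")
    ref = reference if reference is not None else frames[0]
    idx = _backbone_indices(ref.system, subunit)
    ref_xyz = ref.coords[idx]
    out = np.empty(len(frames))
    for k, frame in enumerate(frames):
        if frame.system.n_atoms != ref.system.n_atoms:
            raise ValidationError("atom mismatch between frame and reference")
        _, rmsd = _superpose(frame.coords[idx], ref_xyz)
        out[k] = rmsd
    return out


def loop_rmsf(frames: Sequence[Frame], subunit: int,
              loop_ranges: Mapping[str, tuple[int, int]]) -> pd.DataFrame:
    """Per-residue Calpha RMSF of one subunit, grouped by loop.

    Each frame's subunit backbone is superposed first onto the initial frame
    (to build the average structure) and then onto that average; the RMSF of
    each Calpha is taken about its mean position after the second pass.
    """
    frames = list(frames)
    if len(frames) < 2:
        raise ValidationError("RMSF needs at least 2 frames")
    system = frames[0].system
    bb = _backbone_indices(system, subunit)
    ca = _ca_indices(system, subunit)
    ca_pos_in_bb = np.searchsorted(bb, ca)

    ref = frames[0].coords[bb]
    pass1 = np.stack([_superpose(f.coords[bb], ref)[0] for f in frames])
    avg = pass1.mean(axis=0)
    pass2 = np.stack([_superpose(f.coords[bb], avg)[0] for f in frames])
    mean2 = pass2.mean(axis=0)
    dev2 = np.sum((pass2 - mean2) ** 2, axis=2)  # (n_frames, n_bb)
    rmsf_bb = np.sqrt(dev2.mean(axis=0))
    rmsf_ca = rmsf_bb[ca_pos_in_bb]

    resids = system.resids[ca]
    loops = np.full(len(ca), "", dtype=object)
    for loop, (lo, hi) in loop_ranges.items():
        loops[(resids >= lo) & (resids <= hi)] = loop
    return pd.DataFrame({
        "subunit": subunit,
        "resid": resids,
        "resname": system.resnames[ca],
        "loop": loops,
        "rmsf": rmsf_ca,
    })


# --------------------------------------------------------------------------- #
# contact maps
# --------------------------------------------------------------------------- #

@dataclass
class ContactMap:
    """Occurrence fractions of Calpha-Calpha distances below the cutoff."""

    pocket: str
    principal_resids: np.ndarray
    complementary_resids: np.ndarray
    matrix: np.ndarray  # (n_principal, n_complementary) in [0, 1]
    cutoff: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.principal_resids,
                            columns=self.complementary_resids)


def contact_map(frames: Iterable[Frame], pocket: PocketSpec,
                cutoff: float = 11.0) -> ContactMap:
    """Fraction of frames with Calpha pairs closer than *cutoff* (strict <)
    between the principal and complementary subunits of one pocket."""
    first = None
    total = None
    n = 0
    for frame in frames:
        if first is None:
            first = frame.system
            pi = _ca_indices(first, pocket.principal_subunit)
            ci = _ca_indices(first, pocket.complementary_subunit)
            total = np.zeros((pi.size, ci.size))
        d = np.linalg.norm(
            frame.coords[pi][:, None, :] - frame.coords[ci][None, :, :],
            axis=2)
        total += d < cutoff
        n += 1
    if n == 0:
        raise ValidationError("empty trajectory")
    return ContactMap(
        pocket=pocket.label,
        principal_resids=first.resids[pi],
        complementary_resids=first.resids[ci],
        matrix=total / n,
        cutoff=cutoff,
    )


# --------------------------------------------------------------------------- #
# pocket centre-of-mass distances
# --------------------------------------------------------------------------- #

@dataclass
class PocketAssemblyTable:
    """Planar intra- and interpocket binding-residue centroid distances.

    Intrapocket: distance between a pocket's principal-side and
    complementary-side Calpha centroids, projected onto the plane orthogonal
    to the channel axis.  Interpocket (labelled ``x-y``): distance between
    the complementary-side centroid of pocket x and the principal-side
    centroid of pocket y, the two centroids carried by the shared subunit.
    """

    intrapocket_mean: dict
    intrapocket_std: dict
    interpocket_mean: dict
    interpocket_std: dict
    n_frames: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lbl in POCKET_LABELS:
            rows.append({"metric": "intrapocket", "label": lbl,
                         "mean_A": self.intrapocket_mean[lbl],
                         "std_A": self.intrapocket_std[lbl]})
        for lbl, v in self.interpocket_mean.items():
            rows.append({"metric": "interpocket", "label": lbl,
                         "mean_A": v, "std_A": self.interpocket_std[lbl]})
        return pd.DataFrame(rows)


def _planar(points: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Project points onto the plane orthogonal to *axis*."""
    return points - np.outer(points @ axis, axis)


def pocket_com_distances(frames: Sequence[Frame], topology: PentamerTopology,
                         mean_positions: bool = False) -> PocketAssemblyTable:
    """Intrapocket and interpocket planar centroid distances.

    By default distances are measured per frame and averaged; with
    ``mean_positions=True`` the centroids are time-averaged first and the
    distances measured once between the mean positions.
    """
    frames = list(frames)
    if not frames:
        raise ValidationError("empty trajectory")
    pockets = topology.pocket_specs()
    intra = {p.label: [] for p in pockets}
    inter_labels = {}
    # interpocket pair for shared subunit: complementary centroid of pocket x
    # and principal centroid of pocket y where y follows x in the ring
    for i, p in enumerate(pockets):
        q = pockets[(i + 1) % 5]
        inter_labels[f"{p.label}-{q.label}"] = (p.label, q.label)
    inter = {lbl: [] for lbl in inter_labels}

    prin_centroids = {p.label: [] for p in pockets}
    comp_centroids = {p.label: [] for p in pockets}
    for frame in frames:
        axis = channel_axis(frame, topology)
        for p in pockets:
            prin = _planar(frame.coords[p.principal_ca], axis).mean(axis=0)
            comp = _planar(frame.coords[p.complementary_ca], axis).mean(axis=0)
            prin_centroids[p.label].append(prin)
            comp_centroids[p.label].append(comp)
            intra[p.label].append(np.linalg.norm(prin - comp))
        for lbl, (x, y) in inter_labels.items():
            inter[lbl].append(np.linalg.norm(
                comp_centroids[x][-1] - prin_centroids[y][-1]))

    if mean_positions:
        intra_mean, intra_std, inter_mean, inter_std = {}, {}, {}, {}
        for p in pockets:
            pm = np.mean(prin_centroids[p.label], axis=0)
            cm = np.mean(comp_centroids[p.label], axis=0)
            intra_mean[p.label] = float(np.linalg.norm(pm - cm))
            intra_std[p.label] = 0.0
        for lbl, (x, y) in inter_labels.items():
            cm = np.mean(comp_centroids[x], axis=0)
            pm = np.mean(prin_centroids[y], axis=0)
            inter_mean[lbl] = float(np.linalg.norm(cm - pm))
            inter_std[lbl] = 0.0
    else:
        intra_mean = {k: float(np.mean(v)) for k, v in intra.items()}
        intra_std = {k: float(np.std(v)) for k, v in intra.items()}
        inter_mean = {k: float(np.mean(v)) for k, v in inter.items()}
        inter_std = {k: float(np.std(v)) for k, v in inter.items()}
    return PocketAssemblyTable(
        intrapocket_mean=intra_mean, intrapocket_std=intra_std,
        interpocket_mean=inter_mean, interpocket_std=inter_std,
        n_frames=len(frames),
    )


# --------------------------------------------------------------------------- #
# correlations
# --------------------------------------------------------------------------- #

def loopc_correlation(series_a: np.ndarray, series_b: np.ndarray) -> float:
    """Pearson correlation between two per-frame angle series."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if len(a) != len(b):
        raise ValidationError("series length mismatch")
    if len(a) < 3:
        raise ValidationError("correlation needs at least 3 frames")
    tol_a = 1e-12 * (abs(a.mean()) + 1.0)
    tol_b = 1e-12 * (abs(b.mean()) + 1.0)
    if np.std(a) <= tol_a or np.std(b) <= tol_b:
        raise ValidationError("undefined correlation: zero-variance series")
    r = float(pearsonr(a, b).statistic)
    if np.isnan(r):
        raise ValidationError("undefined correlation")
    return r


def adjacent_angle_correlations(series: Mapping[str, PocketTimeSeries]
                                ) -> dict[str, float]:
    """Pearson r of Loop C angles for each adjacent pocket pair (a-b ... e-a)."""
    out = {}
    for i, lbl in enumerate(POCKET_LABELS):
        nxt = POCKET_LABELS[(i + 1) % 5]
        out[f"{lbl}-{nxt}"] = loopc_correlation(
            series[lbl].loopc_angle, series[nxt].loopc_angle)
    return out


@dataclass
class PushPullSeries:
    """Distances through the covalently linked Loop B'/Loop F' of one subunit.

    For the consecutive-subunit triplet starting at the principal subunit of
    pocket *label*: d1 = SER174(+, Loop B') to SER145(-, Loop E'') and
    d2 = LYS189(+, Loop F') to SER145(-, Loop E''), both Calpha-Calpha.
    """

    label: str
    loop_b_distance: np.ndarray
    loop_f_distance: np.ndarray
    correlation: Optional[float]  # None when undefined (zero variance)

    def __post_init__(self) -> None:
        if len(self.loop_b_distance) != len(self.loop_f_distance):
            raise ValidationError("push-pull series length mismatch")
        if ((self.loop_b_distance <= 0).any()
                or (self.loop_f_distance <= 0).any()):
            raise ValidationError("push-pull distances must be positive")


def pushpull_analysis(frames: Sequence[Frame], topology: PentamerTopology,
                      loop_b_res: tuple[int, str] = (174, "SER"),
                      loop_f_res: tuple[int, str] = (189, "LYS"),
                      loop_e_res: tuple[int, str] = (145, "SER"),
                      ) -> dict[str, PushPullSeries]:
    """Push-pull distance series and correlation for all five triplets.

    Triplet *x* spans subunits (i, i+1, i+2) where i is the principal subunit
    of pocket x; Loop B'/Loop F' belong to subunit i+1 and Loop E'' to
    subunit i+2 (ring direction follows the topology convention).
    """
    frames = list(frames)
    if not frames:
        raise ValidationError("empty trajectory")
    system = frames[0].system
    step = -1 if topology.ring_reversed else 1
    out = {}
    for p in topology.pocket_specs():
        s1 = (p.principal_subunit + step) % 5      # the ' subunit
        s2 = (p.principal_subunit + 2 * step) % 5  # the '' subunit
        i_b = system.atom_index(s1, loop_b_res[0], "CA")
        i_f = system.atom_index(s1, loop_f_res[0], "CA")
        i_e = system.atom_index(s2, loop_e_res[0], "CA")
        d1 = np.array([np.linalg.norm(f.coords[i_b] - f.coords[i_e])
                       for f in frames])
        d2 = np.array([np.linalg.norm(f.coords[i_f] - f.coords[i_e])
                       for f in frames])
        try:
            corr = loopc_correlation(d1, d2)
        except ValidationError:
            corr = None
        out[p.label] = PushPullSeries(label=p.label, loop_b_distance=d1,
                                      loop_f_distance=d2, correlation=corr)
    return out


def conserved_pair_hbonds(frames: Sequence[Frame], topology: PentamerTopology,
                          pairs: Optional[Sequence[tuple[str, str]]] = None,
                          criteria: InteractionCriteria = InteractionCriteria(),
                          ) -> pd.DataFrame:
    """Hydrogen-bond occurrence for conserved intersubunit residue pairs.

    Each pair is (principal-side residue, complementary-side residue), e.g.
    ``("GLU119", "ARG147")``; occurrence is evaluated per pocket using the
    standard criteria with either residue allowed to donate.
    """
    if pairs is None:
        pairs = [("GLU119", "ARG147"), ("LYS49", "ASP96"),
                 ("ASN219", "ASN58"), ("THR220", "ARG135"),
                 ("ASN219", "LYS189")]
    frames = list(frames)
    if not frames:
        raise ValidationError("empty trajectory")
    system = frames[0].system

    def parse(text: str) -> tuple[str, int]:
        name = "".join(c for c in text if c.isalpha()).upper()
        return name, int("".join(c for c in text if c.isdigit()))

    rows = []
    for p in topology.pocket_specs():
        for prin_text, comp_text in pairs:
            (pn, pr), (cn, cr) = parse(prin_text), parse(comp_text)
            atoms_p = system.residue_atom_indices(p.principal_subunit, pr)
            atoms_c = system.residue_atom_indices(p.complementary_subunit, cr)
            hits = 0
            for frame in frames:
                pol_p = polar_atom_indices(frame, atoms_p)
                pol_c = polar_atom_indices(frame, atoms_c)
                acc_p = acceptor_atom_indices(frame, atoms_p, criteria)
                acc_c = acceptor_atom_indices(frame, atoms_c, criteria)
                recs = (detect_hbonds(frame, pol_p, acc_c, criteria)
                        or detect_hbonds(frame, pol_c, acc_p, criteria))
                if recs:
                    hits += 1
            rows.append({
                "pocket": p.label,
                "pair": f"{prin_text}-{comp_text}",
                "occurrence_pct": 100.0 * hits / len(frames),
            })
    return pd.DataFrame(rows)
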