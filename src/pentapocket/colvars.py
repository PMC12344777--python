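"""Metadynamics collective variables for ligand (un)binding.

Two CVs describe ligand ejection from an orthosteric pocket: the distance
between the mass-weighted centres of the binding residues and of the ligand,
and a ligand-solvation coordination number

    sum_ij  (1 - (d_ij/d0)^6) / (1 - (d_ij/d0)^10)

over ligand carbon / water oxygen pairs within a hard 10 A cutoff, with
d0 = 2.5 A.  Each pair term is a smooth switch from 1 (contact) to 0
(separation); its removable singularity at d_ij = d0 has the limit 6/10.
Only the CVs themselves live here -- bias deposition belongs to an external
enhanced-sampling engine.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from scipy.spatial import cKDTree

from .core import Frame, ValidationError

__all__ = ["SolvationParams", "com_distance", "solvation_coordination",
           "switching_term"]


@dataclass(frozen=True)
class SolvationParams:
    """Parameters of the solvation coordination CV."""

    d0: float = 2.5                 # switching midpoint, A
    numerator_exponent: int = 6
    denominator_exponent: int = 10
    cutoff: float = 10.0            # hard pair-inclusion threshold, A

    def __post_init__(self) -> None:
        if self.d0 <= 0:
            raise ValidationError("d0 must be positive")
        if self.cutoff <= self.d0:
            raise ValidationError("cutoff must exceed d0")
        n, m = self.numerator_exponent, self.denominator_exponent
        if n <= 0 or m <= 0 or n % 2 or m % 2 or m <= n:
            raise ValidationError(
                "exponents must be positive even integers with "
                "denominator > numerator")


def com_distance(frame: Frame, ligand_atoms: Iterable[int],
                 site_atoms: Iterable[int]) -> float:
    """Distance between the mass-weighted centroids of two selections (A)."""
    lig = np.asarray(list(ligand_atoms), dtype=int)
    site = np.asarray(list(site_atoms), dtype=int)
    if lig.size == 0 or site.size == 0:
        raise ValidationError("empty selection for COM distance")
    masses = frame.system.masses

    def com(idx):
        m = masses[idx]
        if m.sum() <= 0:
            raise ValidationError("selection has zero total mass")
        return (frame.coords[idx] * m[:, None]).sum(axis=0) / m.sum()

    return float(np.linalg.norm(com(lig) - com(site)))


def switching_term(d: np.ndarray, params: SolvationParams) -> np.ndarray:
    """Rational switching term per pair distance, with the d = d0 limit."""
    x = np.asarray(d, dtype=float) / params.d0
    n, m = params.numerator_exponent, params.denominator_exponent
    num = 1.0 - x ** n
    den = 1.0 - x ** m
    limit = n / m
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(np.abs(den) < 1e-14, limit, num / np.where(den == 0, 1, den))
    return out


def solvation_coordination(frame: Frame,
                           params: SolvationParams = SolvationParams(),
                           ligand_atoms: Optional[Iterable[int]] = None,
                           ) -> float:
    """Solvation coordination of the ligand carbons by water oxygens.

    Sums the switching term over all (ligand carbon, water oxygen) pairs
    with d_ij within the hard cutoff.  With no water in range the sum is 0.
    """
    system = frame.system
    if ligand_atoms is None:
        lig = system.role_indices("ligand")
    else:
        lig = np.asarray(list(ligand_atoms), dtype=int)
    carbons = lig[system.elements[lig] == "C"]
    oxygens = system.water_oxygens
    if carbons.size == 0:
        raise ValidationError("no ligand carbon atoms for solvation CV")
    if oxygens.size == 0:
        return 0.0
    tree = cKDTree(frame.coords[oxygens])
    total = 0.0
    for c in carbons:
        near = tree.query_ball_point(frame.coords[c], params.cutoff)
        if not near:
            continue
        d = np.linalg.norm(frame.coords[oxygens[near]] - frame.coords[c],
                           axis=1)
        d = d[d <= params.cutoff]
        total += float(np.sum(switching_term(d, params)))
    return total
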