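"""Structural feature analyses: side-chain torsions, contacts, termini.

These operations run on :class:`~ramdpath.trajectory_io.Structure` frames
(PDB-derived, Å) or on raw coordinate arrays, and cover the post-processing a
receptor-ligand unbinding study performs on its trajectories: chi-angle
shifts of gate residues between initial and final frames, minimum-distance
time series between residue pairs with contact calls, and the inter-chain
C-termini distance that distinguishes active from inactive receptor
conformations.

Contact cutoffs are package conventions (raw distances are always emitted):
0.35 nm for hydrogen-bond-like donor-acceptor heavy-atom contacts, 0.45 nm
for salt bridges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from .trajectory_io import NM_PER_ANGSTROM, Structure, min_interatomic_distance

__all__ = [
    "CHI1_ATOMS",
    "HBOND_CUTOFF_NM",
    "SALT_BRIDGE_CUTOFF_NM",
    "dihedral",
    "circular_mean",
    "chi_angle_shift",
    "ContactSeries",
    "contact_series",
    "ctermini_distance",
]

# default chi1 atom-name map (N-CA-CB-CG); configurable for toy beads
CHI1_ATOMS: Tuple[str, str, str, str] = ("N", "CA", "CB", "CG")

HBOND_CUTOFF_NM = 0.35
SALT_BRIDGE_CUTOFF_NM = 0.45


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle in degrees, IUPAC convention, range (-180, 180].

    Computed from the two planes (p1,p2,p3) and (p2,p3,p4): looking down the
    p2->p3 axis, a clockwise rotation of p4 relative to p1 is positive.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-10 * max(1.0, np.linalg.norm(b1) * b2n) or \
       np.linalg.norm(n2) < 1e-10 * max(1.0, np.linalg.norm(b3) * b2n):
        raise ValueError("dihedral undefined: three consecutive points are collinear")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / b2n)
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang <= -180.0 else ang


def circular_mean(angles_deg: Sequence[float]) -> float:
    """Circular mean of angles in degrees, in (-180, 180]."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    m = math.degrees(math.atan2(np.sin(a).mean(), np.cos(a).mean()))
    return 180.0 if m <= -180.0 else m


def _wrap(angle: float) -> float:
    wrapped = (angle + 180.0) % 360.0 - 180.0
    return 180.0 if wrapped == -180.0 else wrapped


def _chi1(structure: Structure, chain_id: str, residue_number: int,
          atom_names: Sequence[str]) -> float:
    res = structure.select(chain_id=chain_id, residue_number=residue_number)
    pts = []
    for name in atom_names:
        sel = res.select(atom_names=[name])
        if len(sel) == 0:
            raise ValueError(
                f"residue {chain_id}:{residue_number} is missing atom {name!r} needed for chi1")
        pts.append(sel.atoms[0].position)
    return dihedral(*pts)


def chi_angle_shift(initial: Structure, final_frames: Sequence[Structure],
                    chain_id: str, residue_number: int,
                    atom_names: Sequence[str] = CHI1_ATOMS,
                    ) -> Tuple[float, List[float], float]:
    """Chi1 shift of one residue between the initial and the final frames.

    Returns ``(chi1_initial, chi1_final_per_frame, circular_shift)`` in
    degrees; the shift is the circular mean of the final-frame angles minus
    the initial angle, wrapped to (-180, 180].
    """
    if not final_frames:
        raise ValueError("need at least one final frame")
    chi_init = _chi1(initial, chain_id, residue_number, atom_names)
    chi_final = [_chi1(f, chain_id, residue_number, atom_names) for f in final_frames]
    shift = _wrap(circular_mean([c - chi_init for c in chi_final]))
    return chi_init, chi_final, shift


@dataclass
class ContactSeries:
    pair_label: str
    distances: np.ndarray   # nm, per frame
    contacts: np.ndarray    # bool, per frame
    cutoff: float           # nm

    @property
    def contact_fraction(self) -> float:
        return float(self.contacts.mean())


def contact_series(frames: Sequence[Structure], selector_a: Tuple[str, int],
                   selector_b: Tuple[str, int], cutoff: float = HBOND_CUTOFF_NM,
                   ) -> ContactSeries:
    """Per-frame minimum heavy-atom distance between two residues + calls.

    ``selector_a``/``selector_b`` are (chain_id, residue_number) pairs; frame
    coordinates are Å (PDB) and the series is reported in nm.
    """
    dists = []
    for i, frame in enumerate(frames):
        a = frame.select(chain_id=selector_a[0], residue_number=selector_a[1],
                         heavy_only=True)
        b = frame.select(chain_id=selector_b[0], residue_number=selector_b[1],
                         heavy_only=True)
        if len(a) == 0 or len(b) == 0:
            raise ValueError(f"empty residue selection in frame {i}: "
                             f"{selector_a if len(a) == 0 else selector_b}")
        dists.append(min_interatomic_distance(a.coordinates(), b.coordinates())
                     * NM_PER_ANGSTROM)
    distances = np.asarray(dists)
    label = f"{selector_a[0]}:{selector_a[1]}-{selector_b[0]}:{selector_b[1]}"
    return ContactSeries(pair_label=label, distances=distances,
                         contacts=distances <= cutoff, cutoff=cutoff)


def ctermini_distance(structure: Structure, chain_a: str, chain_b: str) -> float:
    """CA-CA distance (Å) between the last resolved residues of two chains.

    Crystal structures rarely resolve true termini, so "C-terminus" is
    operationalized as the highest-numbered residue of the chain that has a
    CA atom.
    """
    cas = []
    for chain in (chain_a, chain_b):
        sel = structure.select(chain_id=chain, atom_names=["CA"])
        if len(sel) == 0:
            raise ValueError(f"chain {chain!r} absent or has no CA atoms")
        last = max(sel.atoms, key=lambda a: a.residue_number)
        cas.append(last.position)
    return float(np.linalg.norm(cas[0] - cas[1]))
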