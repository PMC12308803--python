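#!/usr/bin/env python
"""Structural-feature and free-energy-profile demonstrations.

(a) An unforced (equilibrium) Langevin trajectory in the cationic-like
    binding well is featurized as ligand-to-gate-bead distances; TICA at the
    10 ps protocol lag and a Boltzmann-inversion profile of the leading
    component characterize the bound basin (the unbinding transitions
    themselves are driven, not equilibrium, events in this workflow).
(b) A synthetic gate-residue rotation shows the chi1-shift machinery: the
    final frames are rotated 90 degrees about the CA-CB axis.
(c) A synthetic approach series shows contact calls at the hydrogen-bond
    cutoff (0.35 nm).
Writes results/fes_bound_basin.csv.
"""

import csv
import math
from pathlib import Path

import numpy as np

from ramdpath.ramd_engine import LangevinParams, RAMDParams, run_ramd_trajectory
from ramdpath.structure_features import chi_angle_shift, contact_series
from ramdpath.tica_fes import features_from_arrays, free_energy_profile, tica
from ramdpath.toy_system import build_archetype
from ramdpath.trajectory_io import Atom, Structure

SEED = 2026
ROOT = Path(__file__).resolve().parents[1]

def bound_basin_profile(results: Path) -> None:
    system = build_archetype("cationic_like", SEED)
    ramd = RAMDParams(force_magnitude=0.0, max_time=200.0, save_stride=5)
    traj = run_ramd_trajectory(system, ramd, LangevinParams(), seed=SEED)
    gates = np.stack([system.markers["gate_external"], system.markers["gate_internal"]])
    lig = traj.positions[:, None, :]
    series = features_from_arrays(lig, np.broadcast_to(gates, (len(lig), 2, 3)),
                                  frame_interval=0.01)
    model = tica(series, lag=10.0)
    profile = free_energy_profile(model.projection[:, 0], temperature=313.0, n_bins=40)
    occupied = profile.counts > 0
    span = profile.bin_centers[0][occupied]
    print(f"(a) bound basin: {series.data.shape[0]} frames, "
          f"TICA lag 10 ps leading eigenvalue {model.eigenvalues[0]:+.3f} "
          f"(the basin relaxes far below the protocol lag); occupied profile "
          f"spans {span.min():+.2f}..{span.max():+.2f} with "
          f"{np.nanmax(profile.free_energy):.1f} kJ/mol relief")
    with open(results / "fes_bound_basin.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["bin_center", "free_energy_kJ_mol", "count"])
        for c, f, n in zip(profile.bin_centers[0], profile.free_energy, profile.counts):
            writer.writerow([f"{c:.6f}", "" if np.isnan(f) else f"{f:.6f}", int(n)])

def gate_residue(chi1_deg: float) -> Structure:
    """Synthetic Tyr-like gate residue with a prescribed chi1 (test-style)."""
    n, ca, cb = np.array([1.0, 0.0, -0.5]), np.zeros(3), np.array([0.0, 0.0, 1.5])
    a = math.radians(chi1_deg)
    cg = cb + 1.4 * np.array([math.cos(a), math.sin(a), 0.0])
    return Structure([Atom(i + 1, nm, "TYR", "A", 353, p, nm[0]) for i, (nm, p) in
                      enumerate([("N", n), ("CA", ca), ("CB", cb), ("CG", cg)])])

def main() -> None:
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    bound_basin_profile(results)

    initial = gate_residue(-60.0)
    finals = [gate_residue(-60.0 + 90.0 + d) for d in (-4.0, 0.0, 4.0)]
    chi0, _, shift = chi_angle_shift(initial, finals, "A", 353)
    print(f"(b) synthetic gate rotation: chi1 {chi0:+.1f} deg -> shift {shift:+.1f} deg")

    def pair_frame(d_nm):
        return Structure([Atom(1, "OE1", "GLU", "A", 427, np.zeros(3), "O"),
                          Atom(2, "OH", "TYR", "B", 567,
                               np.array([10.0 * d_nm, 0.0, 0.0]), "O")])
    dists = np.linspace(0.6, 0.25, 15)
    series = contact_series([pair_frame(d) for d in dists], ("A", 427), ("B", 567))
    print(f"(c) synthetic approach: contact fraction {series.contact_fraction:.2f} "
          f"at cutoff {series.cutoff} nm (forms in the last frames)")

if __name__ == "__main__":
    main()
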