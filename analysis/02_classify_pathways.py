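#!/usr/bin/env python
"""Classify every simulated trajectory into its egress pathway.

Final-frames minimum-distance rule against the external/internal marker
beads, then pathway probabilities with bootstrap standard errors and the
chi-square preference test against a random 50:50 split.  Expected pattern:
the agonist-like system leaves externally only, the cationic-like system
internally only, and the neutral-like system through both routes.
Reads scratch/trajectories/ (run 01 first); writes
results/path_assignments.csv and results/pathway_stats.json.
"""

import csv
import json
from pathlib import Path

from ramdpath.path_classifier import (ClassifierConfig, classify_protocol,
                                      path_probabilities, preference_test)
from ramdpath.trajectory_io import read_pdb, read_trajectory

SEED = 2026
ROOT = Path(__file__).resolve().parents[1]

def load_system_dir(sysdir: Path):
    trajs = [read_trajectory(p)[0] for p in sorted(sysdir.glob("*.tsv"))]
    fixture = read_pdb(sysdir / "markers.pdb")
    markers = {"external": fixture.select(residue_name="EXM").coordinates(unit="nm"),
               "internal": fixture.select(residue_name="INM").coordinates(unit="nm")}
    return trajs, markers

def main() -> None:
    trajdir = ROOT / "scratch" / "trajectories"
    if not trajdir.exists():
        raise SystemExit("no trajectories found - run analysis/01_simulate_protocols.py first")
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    stats = {}
    all_rows = []
    for sysdir in sorted(p for p in trajdir.iterdir() if p.is_dir()):
        trajs, markers = load_system_dir(sysdir)
        assignments = classify_protocol(trajs, markers, ClassifierConfig())
        for a in assignments:
            row = a.as_dict()
            row["system"] = sysdir.name
            all_rows.append(row)
        probs = path_probabilities(assignments, seed=SEED)
        chi2, p = preference_test((probs.counts["external"], probs.counts["internal"]))
        stats[sysdir.name] = {
            "counts": probs.counts, "p_external": probs.p_external,
            "p_internal": probs.p_internal, "se": probs.se_external,
            "chi2": chi2, "chi2_p_value": p,
        }
        print(f"{sysdir.name:14s} P(ext)={probs.p_external:5.2f}+/-{probs.se_external:4.2f} "
              f"P(int)={probs.p_internal:5.2f}  ambiguous={probs.counts['ambiguous']:2d} "
              f"chi2 p={p:9.3g}")
    with open(results / "path_assignments.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(all_rows[0]))
        writer.writeheader()
        writer.writerows(all_rows)
    with open(results / "pathway_stats.json", "w") as fh:
        json.dump(stats, fh, indent=2, sort_keys=True)
    print(f"\nwrote {results / 'path_assignments.csv'} and pathway_stats.json")

if __name__ == "__main__":
    main()
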