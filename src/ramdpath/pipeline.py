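"""End-to-end orchestration: simulate -> classify -> statistics -> report.

The pipeline mirrors the workflow shape of a tauRAMD unbinding study: for
each configured system it runs the replica-structured protocol, classifies
every trajectory, computes pathway probabilities with bootstrap errors and
the 50:50 preference test, builds the residence-time summary, and finally
runs a one-way ANOVA across systems.  Every stochastic stage is seeded from
the single run seed; re-running a config yields byte-identical JSON output.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import yaml

from . import kinetics_stats, path_classifier
from .path_classifier import ClassifierConfig
from .ramd_engine import LangevinParams, ProtocolResult, RAMDParams, run_protocol
from .toy_system import ARCHETYPES, ToySystem, apply_modification, build_archetype, write_fixture_pdb
from .trajectory_io import write_trajectory

__all__ = ["RunConfig", "run_pipeline", "mutant_experiment", "run_system"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    systems: List[str] = field(default_factory=lambda: ["agonist_like", "cationic_like", "neutral_like"])
    seed: Optional[int] = None
    n_replicas: int = 5
    n_runs: int = 20
    ramd: RAMDParams = field(default_factory=RAMDParams)
    langevin: LangevinParams = field(default_factory=LangevinParams)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    n_bootstrap: int = 2000
    equil_steps: int = 10_000
    outdir: str = "ramdpath_out"
    save_trajectories: bool = True
    make_figure: bool = True

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("config must set an explicit seed before any compute")
        for name in self.systems:
            if name not in ARCHETYPES:
                raise ValueError(f"unknown system archetype {name!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, klass in (("ramd", RAMDParams), ("langevin", LangevinParams),
                           ("classifier", ClassifierConfig)):
            if key in d and isinstance(d[key], dict):
                d[key] = klass(**d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _marker_sets(system: ToySystem) -> Dict[str, np.ndarray]:
    return {"external": system.markers["external_marker"][None, :],
            "internal": system.markers["internal_marker"][None, :]}


def run_system(system: ToySystem, config: RunConfig, seed_offset: int = 0) -> dict:
    """Protocol + classification + statistics for one system; returns report."""
    base_seed = int(config.seed) + seed_offset
    result = run_protocol(system, config.ramd, config.langevin,
                          n_replicas=config.n_replicas, n_runs=config.n_runs,
                          base_seed=base_seed, equil_steps=config.equil_steps)
    assignments = path_classifier.classify_protocol(
        result.trajectories, _marker_sets(system), config.classifier)
    probs = path_classifier.path_probabilities(
        assignments, n_bootstrap=config.n_bootstrap, seed=base_seed + 1)
    chi2, p = path_classifier.preference_test(
        (probs.counts["external"], probs.counts["internal"]))
    records = kinetics_stats.extract_dissociation_times(
        result, d_diss=config.ramd.dissociation_distance, max_time=config.ramd.max_time)
    summary = kinetics_stats.ligand_summary(
        records, label=system.label, n_bootstrap=config.n_bootstrap, seed=base_seed + 2)
    report = {
        "label": system.label,
        "n_trajectories": len(result.trajectories),
        "n_censored": sum(not t.dissociated for t in result.trajectories),
        "counts": probs.counts,
        "p_external": probs.p_external,
        "p_internal": probs.p_internal,
        "se_external": probs.se_external,
        "se_internal": probs.se_internal,
        "chi2": chi2,
        "chi2_p_value": p,
        "residence": summary.as_dict(),
        "base_seed": base_seed,
    }
    report["_result"] = result
    report["_assignments"] = assignments
    report["_records"] = records
    return report


def _persist_system(report: dict, outdir: Path, manifest: List[dict],
                    save_trajectories: bool) -> None:
    label = report["label"]
    sysdir = outdir / label
    sysdir.mkdir(parents=True, exist_ok=True)
    result: ProtocolResult = report.pop("_result")
    assignments = report.pop("_assignments")
    report.pop("_records")
    if save_trajectories:
        trajdir = sysdir / "trajectories"
        trajdir.mkdir(exist_ok=True)
        for t in result.trajectories:
            path = trajdir / f"r{t.replica_id}_run{t.run_id}.tsv"
            write_trajectory(t, path, label=label)
        manifest.append({"artifact": str(trajdir), "kind": "trajectories",
                         "seed": report["base_seed"]})
    csv_path = sysdir / "path_assignments.csv"
    with open(csv_path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["trajectory_id", "d_external", "d_internal",
                                                "margin", "label", "replica_id"])
        writer.writeheader()
        for a in assignments:
            writer.writerow(a.as_dict())
    json_path = sysdir / "summary.json"
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    manifest.append({"artifact": str(csv_path), "kind": "path_assignments",
                     "seed": report["base_seed"]})
    manifest.append({"artifact": str(json_path), "kind": "summary",
                     "seed": report["base_seed"]})


def _probability_figure(reports: List[dict], path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [r["label"] for r in reports]
    p_ext = [r["p_external"] for r in reports]
    p_int = [r["p_internal"] for r in reports]
    se = [r["se_external"] for r in reports]
    fig, ax = plt.subplots(figsize=(1.8 * len(labels) + 2, 4))
    x = np.arange(len(labels))
    ax.bar(x, p_ext, color="#348ABD", label="external", yerr=se, capsize=3)
    ax.bar(x, p_int, bottom=p_ext, color="#A60628", label="internal")
    ax.set_xticks(x, labels, rotation=20, ha="right")
    ax.set_ylabel("pathway probability")
    ax.set_ylim(0, 1.05)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full workflow for every configured system; returns the report."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: List[dict] = []
    reports: List[dict] = []
    groups: Dict[str, List[float]] = {}

    for i, name in enumerate(config.systems):
        system = build_archetype(name, seed=int(config.seed))
        fixture = outdir / f"{name}_markers.pdb"
        write_fixture_pdb(system, fixture)
        manifest.append({"artifact": str(fixture), "kind": "fixture_pdb",
                         "seed": int(config.seed)})
        report = run_system(system, config, seed_offset=1000 * i)
        groups[name] = [r.dissociation_time for r in report["_records"] if not r.censored]
        _persist_system(report, outdir, manifest, config.save_trajectories)
        reports.append(report)
        logger.info("system %s: p_ext=%.3f p_int=%.3f chi2_p=%.3g", name,
                    report["p_external"], report["p_internal"], report["chi2_p_value"])

    full: dict = {"systems": reports, "config_seed": int(config.seed)}
    if len(groups) >= 2 and all(len(v) >= 2 for v in groups.values()):
        f_stat, p = kinetics_stats.anova_across_ligands(groups)
        full["anova"] = {"F": f_stat, "p_value": p, "groups": sorted(groups)}
    if config.make_figure:
        figpath = outdir / "pathway_probabilities.png"
        _probability_figure(reports, figpath)
        manifest.append({"artifact": str(figpath), "kind": "figure",
                         "seed": int(config.seed)})

    report_path = outdir / "report.json"
    with open(report_path, "w") as fh:
        json.dump(full, fh, indent=2, sort_keys=True)
    manifest.append({"artifact": str(report_path), "kind": "report",
                     "seed": int(config.seed)})
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return full


_MODIFICATIONS = ("remove_gate_bond", "remove_all_anchor_interactions")


def mutant_experiment(config: RunConfig, modification: str) -> dict:
    """Compare the neutral_like base system against a modified ("mutant") one.

    ``remove_gate_bond`` keeps mixed exits (the compensating tether still
    impedes internal egress); ``remove_all_anchor_interactions`` flips the
    system to near-exclusive internal egress.
    """
    config.validate()
    if modification is not None and modification not in _MODIFICATIONS:
        raise ValueError(f"unknown modification {modification!r}")
    base = build_archetype("neutral_like", seed=int(config.seed))
    # no modification: the "mutant" is the unmodified base (identity control)
    mutant = base if modification is None else apply_modification(base, modification)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: List[dict] = []
    reports = []
    mutant_offset = 0 if modification is None else 5000
    for offset, system in ((0, base), (mutant_offset, mutant)):
        rep = run_system(system, config, seed_offset=offset)
        _persist_system(rep, outdir, manifest, config.save_trajectories)
        reports.append(rep)
    comparison = {
        "modification": modification,
        "base": reports[0],
        "mutant": reports[1],
        "internal_fraction_base": reports[0]["p_internal"],
        "internal_fraction_mutant": reports[1]["p_internal"],
    }
    with open(outdir / "mutant_report.json", "w") as fh:
        json.dump(comparison, fh, indent=2, sort_keys=True)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return comparison
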