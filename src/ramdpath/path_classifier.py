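"""Unbinding-pathway classification and pathway statistics.

Each dissociation trajectory is assigned to the external or internal egress
route from the minimum distance, over the final frames of the run, between the
ligand and a representative marker of each route — the trajectory belongs to
the route whose marker it ends up closest to.  Two machine flags replace the
manual curation such data normally receives: *ambiguous* when the two
distances are within a tolerance of each other, and *outlier* when both
distances are implausibly large.  Flagged trajectories are excluded from
probabilities but always reported.

Pathway probabilities carry bootstrap standard errors, and a one-sample
chi-square test (no continuity correction) measures preference against the
random 50:50 split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .ramd_engine import Trajectory
from .trajectory_io import min_interatomic_distance

__all__ = [
    "ClassifierConfig",
    "PathAssignment",
    "classify",
    "classify_protocol",
    "path_probabilities",
    "PathProbabilities",
    "preference_test",
]


@dataclass
class ClassifierConfig:
    n_final_frames: int = 10
    ambiguity_tolerance: float = 0.5   # nm
    outlier_distance: float = 10.0     # nm

    def __post_init__(self) -> None:
        if self.n_final_frames < 1:
            raise ValueError("n_final_frames must be >= 1")
        if self.ambiguity_tolerance < 0 or self.outlier_distance <= 0:
            raise ValueError("tolerances must be non-negative")


@dataclass
class PathAssignment:
    trajectory_id: str
    d_external: float   # nm
    d_internal: float   # nm
    label: str          # external | internal | ambiguous | outlier
    margin: float       # |d_external - d_internal|
    replica_id: int = 0

    def as_dict(self) -> dict:
        return {
            "trajectory_id": self.trajectory_id,
            "d_external": self.d_external,
            "d_internal": self.d_internal,
            "margin": self.margin,
            "label": self.label,
            "replica_id": self.replica_id,
        }


def classify(traj: Trajectory, markers: Mapping[str, np.ndarray],
             cfg: ClassifierConfig = ClassifierConfig()) -> PathAssignment:
    """Assign one trajectory by the final-frames minimum-distance rule.

    ``markers`` maps path name ("external"/"internal") to a point set (nm).
    """
    for key in ("external", "internal"):
        if key not in markers:
            raise ValueError(f"markers must contain {key!r}")
    if traj.n_frames < cfg.n_final_frames:
        raise ValueError(
            f"trajectory has {traj.n_frames} frames; classifier needs >= {cfg.n_final_frames}")
    tail = traj.positions[-cfg.n_final_frames:]
    d_ext = min_interatomic_distance(tail, markers["external"])
    d_int = min_interatomic_distance(tail, markers["internal"])
    margin = abs(d_ext - d_int)
    if min(d_ext, d_int) > cfg.outlier_distance:
        label = "outlier"
    elif margin <= cfg.ambiguity_tolerance:
        label = "ambiguous"
    else:
        label = "external" if d_ext < d_int else "internal"
    return PathAssignment(
        trajectory_id=f"r{traj.replica_id}_run{traj.run_id}",
        d_external=d_ext, d_internal=d_int, label=label, margin=margin,
        replica_id=traj.replica_id)


def classify_protocol(trajectories: Iterable[Trajectory],
                      markers: Mapping[str, np.ndarray],
                      cfg: ClassifierConfig = ClassifierConfig()) -> List[PathAssignment]:
    return [classify(t, markers, cfg) for t in trajectories]


@dataclass
class PathProbabilities:
    p_external: float
    p_internal: float
    se_external: float
    se_internal: float
    counts: Dict[str, int]     # external/internal/ambiguous/outlier
    n_resolved: int


def path_probabilities(assignments: Sequence[PathAssignment], n_bootstrap: int = 2000,
                       seed: int = 0, stratify_by_replica: bool = False) -> PathProbabilities:
    """Pathway probabilities over resolved trajectories with bootstrap SEs.

    The bootstrap resamples trajectories with replacement (flat by default;
    within replicas when ``stratify_by_replica``); the SE is the standard
    deviation of the external proportion over the resamples.
    """
    counts = {"external": 0, "internal": 0, "ambiguous": 0, "outlier": 0}
    for a in assignments:
        counts[a.label] += 1
    resolved = [a for a in assignments if a.label in ("external", "internal")]
    n = len(resolved)
    if n == 0:
        raise ValueError("no resolved (non-ambiguous, non-outlier) assignments")
    is_ext = np.array([a.label == "external" for a in resolved], dtype=float)
    p_ext = float(is_ext.mean())

    rng = np.random.Generator(np.random.PCG64(seed))
    if stratify_by_replica:
        groups = [np.array([x.label == "external" for x in resolved
                            if x.replica_id == r], dtype=float)
                  for r in sorted({a.replica_id for a in resolved})]
        boots = np.empty(n_bootstrap)
        for i in range(n_bootstrap):
            picks = [g[rng.integers(0, len(g), len(g))] for g in groups if len(g)]
            boots[i] = np.concatenate(picks).mean()
    else:
        idx = rng.integers(0, n, size=(n_bootstrap, n))
        boots = is_ext[idx].mean(axis=1)
    se = float(boots.std(ddof=0))
    return PathProbabilities(
        p_external=p_ext, p_internal=1.0 - p_ext,
        se_external=se, se_internal=se,
        counts=counts, n_resolved=n)


def preference_test(counts: Tuple[int, int]) -> Tuple[float, float]:
    """One-sample chi-square against the random 50:50 split (1 dof).

    No continuity correction:  chi2 = 2 * (n_ext - n/2)^2 / (n/2).
    """
    n_ext, n_int = counts
    if n_ext < 0 or n_int < 0:
        raise ValueError("counts must be non-negative")
    n = n_ext + n_int
    if n == 0:
        raise ValueError("need at least one resolved trajectory")
    expected = n / 2.0
    chi2 = (n_ext - expected) ** 2 / expected + (n_int - expected) ** 2 / expected
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p
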