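"""Pairwise-distance features, TICA, and histogram free-energy profiles.

TICA (time-lagged independent component analysis) finds the linear
projections of a feature time series that decorrelate slowest: with
mean-free data ``X``, instantaneous covariance ``C0`` and symmetrized lagged
covariance ``Ct = (C(tau) + C(tau)^T) / 2``, it solves the generalized
eigenproblem ``Ct v = lambda C0 v``.  The symmetrized (reversible) estimator
is used, as is standard for equilibrium trajectories; eigenvalues then
approximate autocorrelations exp(-tau / t_i) of the underlying slow modes.

Free-energy profiles are Boltzmann inversions of sampling histograms,
``F_i = -kB T ln(c_i / c_max)``, minimum at zero, with empty bins marked
unreachable rather than zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import linalg

from .ramd_engine import KB
from .trajectory_io import NM_PER_ANGSTROM, Structure

__all__ = [
    "FeatureSeries",
    "TICAModel",
    "FreeEnergyProfile",
    "pairwise_distance_features",
    "features_from_arrays",
    "tica",
    "free_energy_profile",
    "find_minima",
]

logger = logging.getLogger(__name__)


@dataclass
class FeatureSeries:
    data: np.ndarray            # (n_frames, n_features)
    labels: List[str]
    frame_interval: float       # ps

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 2:
            raise ValueError("feature series needs >= 2 frames")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("feature series contains non-finite values")
        if self.data.shape[1] != len(self.labels):
            raise ValueError("one label per feature required")


def features_from_arrays(coords_a: np.ndarray, coords_b: np.ndarray,
                         frame_interval: float, labels_a: Sequence[str] | None = None,
                         labels_b: Sequence[str] | None = None) -> FeatureSeries:
    """All pairwise distances between two atom groups over time.

    ``coords_a``: (n_frames, n_a, 3); ``coords_b``: (n_frames, n_b, 3); the
    result has n_a * n_b features in the unit of the inputs.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.ndim != 3 or b.ndim != 3 or a.shape[0] != b.shape[0]:
        raise ValueError("coordinate arrays must be (n_frames, n_atoms, 3) with equal n_frames")
    if a.shape[1] == 0 or b.shape[1] == 0:
        raise ValueError("both selections must be non-empty")
    diff = a[:, :, None, :] - b[:, None, :, :]
    dists = np.linalg.norm(diff, axis=-1).reshape(a.shape[0], -1)
    la = labels_a if labels_a is not None else [f"a{i}" for i in range(a.shape[1])]
    lb = labels_b if labels_b is not None else [f"b{j}" for j in range(b.shape[1])]
    labels = [f"{x}-{y}" for x in la for y in lb]
    series = FeatureSeries(data=dists, labels=labels, frame_interval=frame_interval)
    scale = np.maximum(np.abs(series.data).max(axis=0), 1.0)
    zero_var = np.nonzero(series.data.std(axis=0) <= 1e-12 * scale)[0]
    if zero_var.size:
        logger.warning("zero-variance features: %s", [labels[i] for i in zero_var])
    return series


def pairwise_distance_features(frames: Sequence[Structure], selector_a: Tuple[str, int],
                               selector_b: Tuple[str, int], frame_interval: float,
                               ) -> FeatureSeries:
    """Pairwise non-hydrogen atom distances (nm) between two residues."""
    coords_a, coords_b = [], []
    la = lb = None
    for i, frame in enumerate(frames):
        a = frame.select(chain_id=selector_a[0], residue_number=selector_a[1], heavy_only=True)
        b = frame.select(chain_id=selector_b[0], residue_number=selector_b[1], heavy_only=True)
        if len(a) == 0 or len(b) == 0:
            raise ValueError(f"empty selection in frame {i}")
        if la is None:
            la = [f"{selector_a[0]}:{selector_a[1]}:{at.name}" for at in a.atoms]
            lb = [f"{selector_b[0]}:{selector_b[1]}:{at.name}" for at in b.atoms]
        coords_a.append(a.coordinates() * NM_PER_ANGSTROM)
        coords_b.append(b.coordinates() * NM_PER_ANGSTROM)
    return features_from_arrays(np.asarray(coords_a), np.asarray(coords_b),
                                frame_interval, la, lb)


@dataclass
class TICAModel:
    lag: float                  # ps
    mean: np.ndarray
    eigenvalues: np.ndarray     # descending
    components: np.ndarray      # (n_features, n_components), C0-orthonormal
    projection: np.ndarray      # (n_frames, n_components)

    def transform(self, data: np.ndarray) -> np.ndarray:
        return (np.asarray(data, dtype=float) - self.mean) @ self.components


def tica(series: FeatureSeries, lag: float = 10.0,
         regularization: float = 1e-10) -> TICAModel:
    """Symmetrized-covariance TICA at lag time ``lag`` (ps).

    The generalized eigenproblem is solved after flooring the eigenvalues of
    ``C0`` at ``regularization`` times its largest eigenvalue (near-duplicate
    distance features make ``C0`` ill-conditioned).
    """
    ratio = lag / series.frame_interval
    lag_frames = int(round(ratio))
    if abs(ratio - lag_frames) > 1e-9 or lag_frames < 1:
        raise ValueError("lag must be a positive integer multiple of the frame interval")
    n = series.data.shape[0]
    if n <= lag_frames + 2:
        raise ValueError("series too short for this lag")

    x = series.data - series.data.mean(axis=0)
    x0, xt = x[:-lag_frames], x[lag_frames:]
    m = x0.shape[0]
    c0 = (x0.T @ x0 + xt.T @ xt) / (2.0 * m)
    ct_raw = x0.T @ xt / m
    ct = 0.5 * (ct_raw + ct_raw.T)

    # regularization floor on C0's spectrum
    evals, evecs = linalg.eigh(c0)
    floor = regularization * max(evals.max(), np.finfo(float).tiny)
    if np.any(evals < floor):
        logger.warning("C0 is rank-deficient/ill-conditioned; flooring %d eigenvalues",
                       int(np.sum(evals < floor)))
        evals = np.maximum(evals, floor)
        c0 = (evecs * evals) @ evecs.T

    lam, v = linalg.eigh(ct, c0)
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    v = v[:, order]
    # scipy normalizes v^T C0 v = I already; enforce sign convention
    v = v * np.sign(v[np.abs(v).argmax(axis=0), np.arange(v.shape[1])])
    return TICAModel(lag=lag, mean=series.data.mean(axis=0), eigenvalues=lam,
                     components=v, projection=x @ v)


@dataclass
class FreeEnergyProfile:
    bin_centers: Tuple[np.ndarray, ...]   # one array per dimension
    free_energy: np.ndarray               # kJ/mol, NaN where unreachable
    counts: np.ndarray
    temperature: float

    @property
    def occupied(self) -> np.ndarray:
        return self.counts > 0


def free_energy_profile(values, temperature: float = 313.0, n_bins: int = 50,
                        ) -> FreeEnergyProfile:
    """Boltzmann inversion of a 1D or 2D sampling histogram.

    ``F_i = -kB T ln(c_i / c_max)`` on occupied bins; the minimum is 0 by
    construction and empty bins are NaN (unreachable), never 0.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim == 1:
        v = v[:, None]
    if v.ndim != 2 or v.shape[1] not in (1, 2):
        raise ValueError("values must be 1D or 2D samples")
    if v.shape[0] < 100:
        raise ValueError("need >= 100 samples for a meaningful profile")

    if v.shape[1] == 1:
        counts, edges = np.histogram(v[:, 0], bins=n_bins)
        centers = (0.5 * (edges[:-1] + edges[1:]),)
    else:
        counts, ex, ey = np.histogram2d(v[:, 0], v[:, 1], bins=n_bins)
        centers = (0.5 * (ex[:-1] + ex[1:]), 0.5 * (ey[:-1] + ey[1:]))
    if np.count_nonzero(counts) == 1:
        logger.warning("all samples fall in a single bin; profile is trivial")
    free = np.full(counts.shape, np.nan)
    occ = counts > 0
    free[occ] = -KB * temperature * np.log(counts[occ] / counts.max())
    return FreeEnergyProfile(bin_centers=centers, free_energy=free,
                             counts=np.asarray(counts), temperature=temperature)


def find_minima(profile: FreeEnergyProfile, min_count: int = 5) -> List[Tuple[int, ...]]:
    """Local minima of the profile over bins with >= min_count samples.

    A bin is a local minimum when its free energy is strictly below every
    occupied neighbor (4-neighborhood in 2D); sparse bins are masked out.
    """
    f = profile.free_energy
    eligible = profile.counts >= min_count
    minima: List[Tuple[int, ...]] = []
    if f.ndim == 1:
        for i in range(f.shape[0]):
            if not eligible[i]:
                continue
            neighbors = [j for j in (i - 1, i + 1) if 0 <= j < f.shape[0] and eligible[j]]
            if neighbors and all(f[i] < f[j] for j in neighbors):
                minima.append((i,))
    else:
        for i in range(f.shape[0]):
            for j in range(f.shape[1]):
                if not eligible[i, j]:
                    continue
                neigh = [(i + di, j + dj) for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1))
                         if 0 <= i + di < f.shape[0] and 0 <= j + dj < f.shape[1]
                         and eligible[i + di, j + dj]]
                if neigh and all(f[i, j] < f[a, b] for a, b in neigh):
                    minima.append((i, j))
    return minima
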