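"""Structure and trajectory I/O.

PDB is read and written in fixed-column ATOM/HETATM format (coordinates in Å,
the format's unit); trajectories round-trip through TSV tables with a
``#``-prefixed metadata header.  Everything outside the I/O boundary works in
nm; conversion happens here and only here.

Distances are plain Euclidean — the toy systems are non-periodic, so no
minimum-image convention is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import cdist

from .ramd_engine import Trajectory

__all__ = [
    "Atom",
    "Structure",
    "read_pdb",
    "write_pdb",
    "write_trajectory",
    "read_trajectory",
    "min_interatomic_distance",
    "NM_PER_ANGSTROM",
]

NM_PER_ANGSTROM = 0.1


@dataclass
class Atom:
    serial: int
    name: str
    residue_name: str
    chain_id: str
    residue_number: int
    position: np.ndarray  # Å
    element: str
    altloc: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError("atom coordinates must be finite")


@dataclass
class Structure:
    """A parsed PDB structure (coordinates in Å)."""

    atoms: List[Atom]

    def __post_init__(self) -> None:
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("atom serials must be unique")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def chains(self) -> List[str]:
        seen: Dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id)
        return list(seen)

    def coordinates(self, unit: str = "angstrom") -> np.ndarray:
        coords = np.array([a.position for a in self.atoms], dtype=float)
        if unit == "nm":
            return coords * NM_PER_ANGSTROM
        if unit == "angstrom":
            return coords
        raise ValueError(f"unknown unit {unit!r}")

    def select(self, chain_id: str | None = None, residue_number: int | None = None,
               residue_name: str | None = None, atom_names: Sequence[str] | None = None,
               heavy_only: bool = False) -> "Structure":
        out = []
        for a in self.atoms:
            if chain_id is not None and a.chain_id != chain_id:
                continue
            if residue_number is not None and a.residue_number != residue_number:
                continue
            if residue_name is not None and a.residue_name != residue_name:
                continue
            if atom_names is not None and a.name not in atom_names:
                continue
            if heavy_only and a.element.upper() == "H":
                continue
            out.append(a)
        return Structure(out)

    def residues(self, chain_id: str) -> List[int]:
        """Residue numbers present in a chain, sorted."""
        return sorted({a.residue_number for a in self.atoms if a.chain_id == chain_id})


def _parse_atom_line(line: str, lineno: int) -> Atom:
    if len(line.rstrip("\n")) < 54:
        raise ValueError(f"line {lineno}: ATOM record shorter than the fixed coordinate columns")
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip() or " "
        resnum = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise ValueError(f"line {lineno}: malformed fixed-column ATOM record ({exc})") from None
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = "".join(c for c in name if c.isalpha())[:1]
    return Atom(serial=serial, name=name, residue_name=resname, chain_id=chain,
                residue_number=resnum, position=np.array([x, y, z]), element=element,
                altloc=altloc)


def read_pdb(path) -> Structure:
    """Parse ATOM/HETATM records; first altloc kept, everything else ignored."""
    atoms: List[Atom] = []
    seen_alt: set = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not (line.startswith("ATOM") or line.startswith("HETATM")):
                continue
            atom = _parse_atom_line(line, lineno)
            if atom.altloc:
                key = (atom.chain_id, atom.residue_number, atom.name)
                if key in seen_alt:
                    continue
                seen_alt.add(key)
            atoms.append(atom)
    if not atoms:
        raise ValueError(f"no ATOM/HETATM records found in {path}")
    return Structure(atoms)


def write_pdb(structure: Structure, path) -> None:
    lines = []
    for a in structure.atoms:
        name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
        lines.append(
            f"ATOM  {a.serial:5d} {name}{a.altloc or ' '}{a.residue_name:>3s} "
            f"{a.chain_id}{a.residue_number:4d}    "
            f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}"
        )
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# Trajectory tables
# --------------------------------------------------------------------------

_META_KEYS = ("label", "replica_id", "run_id", "rng_seed", "dissociated",
              "dissociation_time", "ground_truth_channel")


def write_trajectory(traj: Trajectory, path, label: str = "") -> None:
    """TSV with '#key=value' metadata header; positions in nm, 1e-6 precision."""
    if traj.n_frames == 0:
        raise ValueError("refusing to write an empty trajectory")
    meta = {
        "label": label,
        "replica_id": traj.replica_id,
        "run_id": traj.run_id,
        "rng_seed": traj.rng_seed,
        "dissociated": int(traj.dissociated),
        "dissociation_time": "" if traj.dissociation_time is None else repr(traj.dissociation_time),
        "ground_truth_channel": traj.ground_truth_channel,
    }
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"#{k}={v}\n")
        fh.write("frame\ttime_ps\tbead_id\tx_nm\ty_nm\tz_nm\n")
        for i, (t, p) in enumerate(zip(traj.times, traj.positions)):
            fh.write(f"{i}\t{t:.6f}\t0\t{p[0]:.6f}\t{p[1]:.6f}\t{p[2]:.6f}\n")


def read_trajectory(path) -> Tuple[Trajectory, str]:
    """Inverse of :func:`write_trajectory`; returns (trajectory, label)."""
    meta: Dict[str, str] = {}
    frames: List[int] = []
    times: List[float] = []
    coords: List[List[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                k, _, v = line[1:].partition("=")
                meta[k] = v
                continue
            if line.startswith("frame") or not line:
                continue
            parts = line.split("\t")
            frames.append(int(parts[0]))
            times.append(float(parts[1]))
            coords.append([float(parts[3]), float(parts[4]), float(parts[5])])
    missing = [k for k in _META_KEYS if k not in meta]
    if missing:
        raise ValueError(f"trajectory table {path} is missing metadata keys: {missing}")
    if frames != list(range(len(frames))):
        raise ValueError(f"trajectory table {path} has non-contiguous frames")
    dtime = meta["dissociation_time"]
    traj = Trajectory(
        positions=np.asarray(coords), times=np.asarray(times),
        replica_id=int(meta["replica_id"]), run_id=int(meta["run_id"]),
        dissociated=bool(int(meta["dissociated"])),
        dissociation_time=None if dtime == "" else float(dtime),
        ground_truth_channel=meta["ground_truth_channel"],
        rng_seed=int(meta["rng_seed"]),
    )
    return traj, meta["label"]


def min_interatomic_distance(a, b) -> float:
    """Minimum Euclidean distance between two point sets (same unit in = out)."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both point sets must be non-empty")
    return float(cdist(a, b).min())
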