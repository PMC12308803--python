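"""Synthetic two-channel binding-site landscapes.

This module builds the toy stand-in for a receptor-ligand complex used by the
unbinding simulator: a single attractive binding well enclosed by a repulsive
spherical shell ("the protein surface") that is open along exactly two
directions — an *external* and an *internal* exit channel.  Each channel
carries its own Gaussian gate barrier, emulating the steric gate residues that
flank the two egress routes of the real receptor, and an optional breakable
harmonic tether emulates an ionic anchor interaction between the ligand and a
binding-site side chain.

All lengths are in nm, energies in kJ/mol, so forces are kJ/mol/nm.  The zero
of energy is the ligand at infinite separation; the potential at the well
center is exactly ``-well_depth``.

Functional form
---------------
``E(x) = E_well + E_shell + E_tether`` with

* well: inverted Gaussian, ``-D exp(-r^2 / 2 s_w^2)`` with ``r = |x - c|``;
* shell: ``H(x_hat) * exp(-(r - R)^2 / 2 w^2)`` where the angular height
  ``H`` equals ``wall_height`` away from the channels and dips to each
  channel's ``barrier_height`` within an angular Gaussian of half-width
  ``channel_width / R`` around the channel axis;
* tether: ``1/2 k (d - rest)^2`` times a smooth cosine switch that turns the
  interaction off as ``d`` approaches ``breakable_at`` (a breakable anchor).

Everything is analytic, so forces are exact gradients; a guard zone of 1e-9 nm
around the well center avoids the (exponentially suppressed, < 1e-12 kJ/mol/nm)
directional ambiguity of the shell term at r = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional

import numpy as np

__all__ = [
    "ChannelSpec",
    "TetherSpec",
    "SeptumSpec",
    "ToySystem",
    "ARCHETYPES",
    "build_archetype",
    "apply_modification",
    "potential_energy",
    "force",
    "write_fixture_pdb",
]

_CENTER_GUARD = 1e-9  # nm; below this radius the shell term is direction-free


@dataclass
class ChannelSpec:
    """One exit channel: a gap in the confining shell with its own gate."""

    role: str                     # "external" | "internal"
    axis_direction: np.ndarray    # unit vector from the well center
    barrier_height: float         # kJ/mol, gate term at the channel mouth
    channel_width: float = 0.35   # nm; sets the angular half-width of the gap
    exit_distance: float = 2.0    # nm; beyond this the ligand has left by this channel

    def __post_init__(self) -> None:
        if self.role not in ("external", "internal"):
            raise ValueError(f"channel role must be external/internal, got {self.role!r}")
        a = np.asarray(self.axis_direction, dtype=float)
        n = np.linalg.norm(a)
        if not np.isfinite(n) or n == 0:
            raise ValueError("channel axis must be a finite non-zero vector")
        self.axis_direction = a / n
        if self.barrier_height < 0:
            raise ValueError("barrier_height must be >= 0")
        if self.channel_width <= 0:
            raise ValueError("channel_width must be > 0")


@dataclass
class TetherSpec:
    """Breakable harmonic anchor (ionic-interaction stand-in)."""

    anchor: np.ndarray
    spring_constant: float        # kJ/mol/nm^2
    rest_length: float            # nm
    breakable_at: float           # nm; zero force beyond this separation
    switch_width: float = 0.15    # nm; cosine taper width ending at breakable_at

    def __post_init__(self) -> None:
        self.anchor = np.asarray(self.anchor, dtype=float)
        if self.spring_constant < 0:
            raise ValueError("spring_constant must be >= 0")
        if self.breakable_at <= self.rest_length:
            raise ValueError("breakable_at must exceed rest_length")
        if not 0 < self.switch_width <= self.breakable_at - self.rest_length:
            raise ValueError("switch_width must lie in (0, breakable_at - rest_length]")


@dataclass
class SeptumSpec:
    """Repulsive slab on the plane separating the two egress routes.

    Outside the binding site the receptor body lies between the two exit
    channels; without it a dissociating ligand could drift from one route's
    far field into the other's.  The slab is a Gaussian in the coordinate
    along ``normal`` and carries compact-support cosine switches in the
    radial distance, so it vanishes identically inside the binding site and
    far beyond the dissociation distance.
    """

    normal: np.ndarray            # unit vector; the slab sits on normal . x = 0
    height: float = 400.0         # kJ/mol
    width: float = 0.3            # nm, Gaussian half-thickness
    r_on: tuple = (1.0, 1.3)      # radial switch-on interval, nm
    r_off: tuple = (7.0, 7.5)     # radial switch-off interval, nm

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        self.normal = n / np.linalg.norm(n)
        if self.height < 0 or self.width <= 0:
            raise ValueError("septum height must be >= 0 and width > 0")


@dataclass
class ToySystem:
    """Geometry + potential of the synthetic binding site."""

    label: str
    well_center: np.ndarray
    well_depth: float             # kJ/mol
    well_width: float             # nm
    channels: List[ChannelSpec]
    markers: Dict[str, np.ndarray]
    tether: Optional[TetherSpec] = None
    temperature: float = 313.0    # K
    wall_height: float = 400.0    # kJ/mol, shell height away from channels
    wall_width: float = 0.12      # nm, radial thickness of the shell
    shell_radius: float = 1.0     # nm
    septum: Optional["SeptumSpec"] = None

    def __post_init__(self) -> None:
        self.well_center = np.asarray(self.well_center, dtype=float)
        self.markers = {k: np.asarray(v, dtype=float) for k, v in self.markers.items()}
        roles = sorted(ch.role for ch in self.channels)
        if roles != ["external", "internal"]:
            raise ValueError("a ToySystem needs exactly two channels: external and internal")
        a, b = (ch.axis_direction for ch in self.channels)
        angle = math.degrees(math.acos(float(np.clip(np.dot(a, b), -1.0, 1.0))))
        if angle < 60.0:
            raise ValueError(f"channel axes must be >= 60 deg apart (got {angle:.1f})")
        for ch in self.channels:
            marker = self.markers.get(f"{ch.role}_marker")
            if marker is None:
                raise ValueError(f"missing marker for {ch.role} channel")
            rel = marker - self.well_center
            t = float(np.dot(rel, ch.axis_direction))
            off_axis = float(np.linalg.norm(rel - t * ch.axis_direction))
            if t <= 0 or off_axis >= ch.channel_width:
                raise ValueError(f"{ch.role}_marker must sit inside its channel")

    def channel(self, role: str) -> ChannelSpec:
        for ch in self.channels:
            if ch.role == role:
                return ch
        raise KeyError(role)


# --------------------------------------------------------------------------
# Archetypes
# --------------------------------------------------------------------------

# Shared geometry: external/internal channel axes 105 degrees apart, mirror
# images through the z=0 plane, so the "symmetric" archetype is symmetric by
# construction and all archetypes are directly comparable.
_THETA = math.radians(52.5)
_AXIS_EXTERNAL = np.array([math.sin(_THETA), 0.0, math.cos(_THETA)])
_AXIS_INTERNAL = np.array([math.sin(_THETA), 0.0, -math.cos(_THETA)])

_WELL_DEPTH = 30.0
_WELL_WIDTH = 0.35
_SHELL_RADIUS = 1.0
_EXIT_DISTANCE = 2.0

# Gate heights (kJ/mol), calibrated once against the default random-force
# protocol (376.56 kJ/mol/nm) and frozen: 10 is freely passable, 70 is a
# slow gate that the protocol squeezes through after repeated attempts, 500
# is impassable (its maximum restoring force far exceeds the random force).
_GATE_EASY = 10.0
_GATE_SLOW = 70.0
_GATE_BLOCK = 500.0

_WIDTH_EXTERNAL = 0.35
_WIDTH_INTERNAL = 0.35

ARCHETYPES = ("agonist_like", "cationic_like", "neutral_like", "symmetric")


def _base_markers() -> Dict[str, np.ndarray]:
    return {
        "reference_atom": np.zeros(3),
        "external_marker": _EXIT_DISTANCE * _AXIS_EXTERNAL,
        "internal_marker": _EXIT_DISTANCE * _AXIS_INTERNAL,
        "gate_external": _SHELL_RADIUS * _AXIS_EXTERNAL,
        "gate_internal": _SHELL_RADIUS * _AXIS_INTERNAL,
    }


def build_archetype(name: str, seed: int = 0) -> ToySystem:
    """Build one of the four ligand-class archetypes.

    ``agonist_like``: internal gate blocked (barrier ratio >= 5), one slow
    external route — the single-pathway, long-residence class.
    ``cationic_like``: external gate blocked, easy internal route, plus a
    breakable tether toward the internal-channel side (the ionic anchor).
    ``neutral_like``: two equal slow gates — both routes used.
    ``symmetric``: two equal easy gates, mirror-symmetric through z = 0.

    Construction is deterministic; ``seed`` is accepted for interface
    uniformity with the stochastic stages and recorded nowhere.
    """
    if name not in ARCHETYPES:
        raise ValueError(f"unknown archetype {name!r}; choose from {ARCHETYPES}")

    def channels(b_ext: float, b_int: float,
                 w_ext: float = _WIDTH_EXTERNAL,
                 w_int: float = _WIDTH_INTERNAL) -> List[ChannelSpec]:
        return [
            ChannelSpec("external", _AXIS_EXTERNAL, b_ext, channel_width=w_ext),
            ChannelSpec("internal", _AXIS_INTERNAL, b_int, channel_width=w_int),
        ]

    septum = SeptumSpec(normal=np.array([0.0, 0.0, 1.0]))
    tether = None
    if name == "agonist_like":
        chans = channels(_GATE_SLOW, _GATE_BLOCK)
    elif name == "cationic_like":
        chans = channels(_GATE_BLOCK, _GATE_EASY)
        # anchored at its own rest length from the well center so the bound
        # state energy is exactly -well_depth
        tether = TetherSpec(
            anchor=0.5 * _AXIS_INTERNAL,
            spring_constant=200.0,
            rest_length=0.5,
            breakable_at=1.2,
        )
    elif name == "neutral_like":
        chans = channels(_GATE_SLOW, _GATE_SLOW)
    else:  # symmetric: equal gates *and* equal widths (exact mirror images)
        chans = channels(_GATE_EASY, _GATE_EASY,
                         w_ext=_WIDTH_EXTERNAL, w_int=_WIDTH_EXTERNAL)

    return ToySystem(
        label=name,
        well_center=np.zeros(3),
        well_depth=_WELL_DEPTH,
        well_width=_WELL_WIDTH,
        channels=chans,
        markers=_base_markers(),
        tether=tether,
        septum=septum,
    )


def apply_modification(system: ToySystem, modification: str) -> ToySystem:
    """Mutate a neutral_like system the way the receptor point mutants do.

    ``remove_gate_bond``: the hydrogen-bond gate on the internal channel is
    removed, but a compensating breakable ionic tether forms at the internal
    gate position — internal egress is easier yet still impeded (mixed exits).
    ``remove_all_anchor_interactions``: the anchoring side chain is gone
    entirely — no internal gate, no tether (near-exclusive internal egress).
    """
    if system.label != "neutral_like":
        raise ValueError("modifications are defined for the neutral_like archetype only")
    ext = system.channel("external")
    w_int = system.channel("internal").channel_width
    internal_open = ChannelSpec("internal", _AXIS_INTERNAL, 0.0, channel_width=w_int)
    if modification == "remove_gate_bond":
        # the hydrogen-bond gate is gone, but a compensating ionic interaction
        # forms at the same mouth: a weaker residual gate plus a weak breakable
        # tether on the internal-channel side (anchored at its rest length, so
        # the bound-state energy is unchanged) -> internal egress is easier
        # than wild type yet still impeded, and both routes stay in play
        residual_gate = ChannelSpec("internal", _AXIS_INTERNAL, 55.0,
                                    channel_width=w_int)
        tether = TetherSpec(
            anchor=0.5 * _AXIS_INTERNAL,
            spring_constant=300.0,
            rest_length=0.5,
            breakable_at=1.0,
        )
        return replace(system, label="neutral_like+remove_gate_bond",
                       channels=[ext, residual_gate], tether=tether)
    if modification == "remove_all_anchor_interactions":
        return replace(system, label="neutral_like+remove_all_anchor_interactions",
                       channels=[ext, internal_open], tether=None)
    raise ValueError(f"unknown modification {modification!r}")


# --------------------------------------------------------------------------
# Potential and force
# --------------------------------------------------------------------------

def potential_energy(system: ToySystem, position) -> np.ndarray | float:
    """Total potential energy (kJ/mol) at ``position`` (shape (..., 3))."""
    x = np.asarray(position, dtype=float)
    scalar = x.ndim == 1
    x = np.atleast_2d(x)
    if not np.all(np.isfinite(x)):
        raise ValueError("position must be finite")

    rel = x - system.well_center
    r = np.linalg.norm(rel, axis=-1)
    e = -system.well_depth * np.exp(-0.5 * (r / system.well_width) ** 2)

    # shell with angular gaps
    g = np.exp(-0.5 * ((r - system.shell_radius) / system.wall_width) ** 2)
    h = np.full_like(r, system.wall_height)
    safe_r = np.where(r > _CENTER_GUARD, r, 1.0)
    for ch in system.channels:
        u = np.clip(rel @ ch.axis_direction / safe_r, -1.0, 1.0)
        psi = np.arccos(u)
        sigma = ch.channel_width / system.shell_radius
        gap = np.exp(-0.5 * (psi / sigma) ** 2)
        gap = np.where(r > _CENTER_GUARD, gap, 0.0)
        h = h + (ch.barrier_height - system.wall_height) * gap
    e = e + g * h

    if system.tether is not None:
        t = system.tether
        d = np.linalg.norm(x - t.anchor, axis=-1)
        s = _switch(d, t.breakable_at, t.switch_width)
        e = e + 0.5 * t.spring_constant * (d - t.rest_length) ** 2 * s

    if system.septum is not None:
        sp = system.septum
        z = rel @ sp.normal
        sigma = _rise(r, *sp.r_on) * (1.0 - _rise(r, *sp.r_off))
        e = e + sp.height * np.exp(-0.5 * (z / sp.width) ** 2) * sigma

    return float(e[0]) if scalar else e


def force(system: ToySystem, position) -> np.ndarray:
    """Force = -grad(potential_energy), kJ/mol/nm, shape (..., 3)."""
    x = np.asarray(position, dtype=float)
    scalar = x.ndim == 1
    x = np.atleast_2d(x)
    if not np.all(np.isfinite(x)):
        raise ValueError("position must be finite")

    rel = x - system.well_center
    r = np.linalg.norm(rel, axis=-1)
    safe_r = np.where(r > _CENTER_GUARD, r, 1.0)
    rhat = rel / safe_r[..., None]

    # well: dE/dr = D * r / s^2 * exp(-r^2/2s^2)
    s2 = system.well_width ** 2
    dEdr_well = system.well_depth * (r / s2) * np.exp(-0.5 * r ** 2 / s2)
    f = -dEdr_well[..., None] * rhat

    # shell
    w2 = system.wall_width ** 2
    g = np.exp(-0.5 * (r - system.shell_radius) ** 2 / w2)
    dg_dr = -(r - system.shell_radius) / w2 * g
    h = np.full_like(r, system.wall_height)
    grad_h = np.zeros_like(x)
    for ch in system.channels:
        u = np.clip(rel @ ch.axis_direction / safe_r, -1.0, 1.0)
        psi = np.arccos(u)
        sigma = ch.channel_width / system.shell_radius
        gap = np.exp(-0.5 * (psi / sigma) ** 2)
        h = h + (ch.barrier_height - system.wall_height) * gap
        # dH/dx = (b - H_wall) * dA/dpsi * dpsi/dx; psi/sin(psi) -> 1 on axis
        sin_psi = np.sqrt(np.maximum(1.0 - u ** 2, 0.0))
        ratio = np.where(sin_psi > 1e-8, psi / np.where(sin_psi > 1e-8, sin_psi, 1.0), 1.0)
        # near the anti-axis (psi ~ pi) the gap factor is ~exp(-pi^2/2 sigma^2) ~ 0
        coef = (ch.barrier_height - system.wall_height) * (-gap / sigma ** 2) * ratio
        dpsi_dir = -(ch.axis_direction - u[..., None] * rhat) / safe_r[..., None]
        grad_h = grad_h + coef[..., None] * dpsi_dir
    grad_shell = (h * dg_dr)[..., None] * rhat + g[..., None] * grad_h
    grad_shell[r <= _CENTER_GUARD] = 0.0
    f = f - grad_shell

    if system.tether is not None:
        t = system.tether
        drel = x - t.anchor
        d = np.linalg.norm(drel, axis=-1)
        safe_d = np.where(d > _CENTER_GUARD, d, 1.0)
        dhat = drel / safe_d[..., None]
        s = _switch(d, t.breakable_at, t.switch_width)
        ds = _switch_deriv(d, t.breakable_at, t.switch_width)
        dEdd = t.spring_constant * (d - t.rest_length) * s \
            + 0.5 * t.spring_constant * (d - t.rest_length) ** 2 * ds
        dEdd = np.where(d > _CENTER_GUARD, dEdd, 0.0)
        f = f - dEdd[..., None] * dhat

    if system.septum is not None:
        sp = system.septum
        z = rel @ sp.normal
        gauss = np.exp(-0.5 * (z / sp.width) ** 2)
        sigma = _rise(r, *sp.r_on) * (1.0 - _rise(r, *sp.r_off))
        dsigma = (_rise_deriv(r, *sp.r_on) * (1.0 - _rise(r, *sp.r_off))
                  - _rise(r, *sp.r_on) * _rise_deriv(r, *sp.r_off))
        grad = (sp.height * sigma * gauss * (-z / sp.width ** 2))[..., None] * sp.normal \
            + (sp.height * gauss * dsigma)[..., None] * rhat
        grad[r <= _CENTER_GUARD] = 0.0
        f = f - grad

    return f[0] if scalar else f


def _rise(r, a, b):
    """C1 cosine ramp: 0 below a, 1 above b."""
    t = np.clip((np.asarray(r, dtype=float) - a) / (b - a), 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * t))


def _rise_deriv(r, a, b):
    r = np.asarray(r, dtype=float)
    t = (r - a) / (b - a)
    inside = (t > 0.0) & (t < 1.0)
    out = np.zeros_like(r, dtype=float)
    out[inside] = 0.5 * np.pi / (b - a) * np.sin(np.pi * t[inside])
    return out


def _switch(d, cutoff, width):
    """C1 cosine switch: 1 below cutoff-width, 0 above cutoff."""
    d = np.asarray(d, dtype=float)
    t = np.clip((d - (cutoff - width)) / width, 0.0, 1.0)
    return 0.5 * (1.0 + np.cos(np.pi * t))


def _switch_deriv(d, cutoff, width):
    d = np.asarray(d, dtype=float)
    t = (d - (cutoff - width)) / width
    inside = (t > 0.0) & (t < 1.0)
    out = np.zeros_like(d)
    out[inside] = -0.5 * np.pi / width * np.sin(np.pi * t[inside])
    return out


# --------------------------------------------------------------------------
# Fast scalar path for the integrator
# --------------------------------------------------------------------------

def pack_system(system: ToySystem) -> tuple:
    """Flatten the landscape parameters for the scalar force kernel."""
    chans = []
    for ch in system.channels:
        ax = ch.axis_direction
        sigma = ch.channel_width / system.shell_radius
        chans.append((ax[0], ax[1], ax[2], ch.barrier_height, sigma))
    if system.tether is not None:
        t = system.tether
        teth = (1.0, t.anchor[0], t.anchor[1], t.anchor[2], t.spring_constant,
                t.rest_length, t.breakable_at, t.switch_width)
    else:
        teth = (0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 1.0, 0.5)
    if system.septum is not None:
        sp = system.septum
        sept = (1.0, sp.normal[0], sp.normal[1], sp.normal[2], sp.height, sp.width,
                sp.r_on[0], sp.r_on[1], sp.r_off[0], sp.r_off[1])
    else:
        sept = (0.0,) + (0.0,) * 9
    c = system.well_center
    return (c[0], c[1], c[2], system.well_depth, system.well_width,
            system.wall_height, system.wall_width, system.shell_radius,
            tuple(chans), teth, sept)


def force_scalar(px: float, py: float, pz: float, packed: tuple):
    """Scalar force; algebraically identical to :func:`force` (unit-tested)."""
    (cx, cy, cz, depth, ww, hwall, wwall, rshell, chans, teth, sept) = packed
    rx, ry, rz = px - cx, py - cy, pz - cz
    r2 = rx * rx + ry * ry + rz * rz
    r = math.sqrt(r2)
    if r <= _CENTER_GUARD:
        return 0.0, 0.0, 0.0
    inv_r = 1.0 / r
    hx, hy, hz = rx * inv_r, ry * inv_r, rz * inv_r

    s2 = ww * ww
    dEdr = depth * (r / s2) * math.exp(-0.5 * r2 / s2)
    fx, fy, fz = -dEdr * hx, -dEdr * hy, -dEdr * hz

    w2 = wwall * wwall
    dr = r - rshell
    g = math.exp(-0.5 * dr * dr / w2)
    if g > 1e-18:
        dg_dr = -dr / w2 * g
        h = hwall
        ghx = ghy = ghz = 0.0
        for (ax, ay, az, b, sigma) in chans:
            u = hx * ax + hy * ay + hz * az
            if u > 1.0:
                u = 1.0
            elif u < -1.0:
                u = -1.0
            psi = math.acos(u)
            gap = math.exp(-0.5 * (psi / sigma) ** 2)
            h += (b - hwall) * gap
            sin_psi = math.sqrt(max(1.0 - u * u, 0.0))
            ratio = psi / sin_psi if sin_psi > 1e-8 else 1.0
            coef = (b - hwall) * (-gap / (sigma * sigma)) * ratio
            dx = -(ax - u * hx) * inv_r
            dy = -(ay - u * hy) * inv_r
            dz = -(az - u * hz) * inv_r
            ghx += coef * dx
            ghy += coef * dy
            ghz += coef * dz
        fx -= h * dg_dr * hx + g * ghx
        fy -= h * dg_dr * hy + g * ghy
        fz -= h * dg_dr * hz + g * ghz

    if teth[0] > 0.5:
        _, axp, ayp, azp, k, rest, brk, sw = teth
        dx, dy, dz = px - axp, py - ayp, pz - azp
        d = math.sqrt(dx * dx + dy * dy + dz * dz)
        if _CENTER_GUARD < d < brk:
            t = (d - (brk - sw)) / sw
            if t <= 0.0:
                s, ds = 1.0, 0.0
            else:
                s = 0.5 * (1.0 + math.cos(math.pi * t))
                ds = -0.5 * math.pi / sw * math.sin(math.pi * t)
            dEdd = k * (d - rest) * s + 0.5 * k * (d - rest) ** 2 * ds
            inv_d = 1.0 / d
            fx -= dEdd * dx * inv_d
            fy -= dEdd * dy * inv_d
            fz -= dEdd * dz * inv_d

    if sept[0] > 0.5:
        _, nx_, ny_, nz_, hsep, wsep, on_a, on_b, off_a, off_b = sept
        z = rx * nx_ + ry * ny_ + rz * nz_
        gauss = math.exp(-0.5 * (z / wsep) ** 2)
        if gauss > 1e-18 and r > on_a:
            # sigma(r) = rise(on) * (1 - rise(off)) with C1 cosine ramps
            t_on = (r - on_a) / (on_b - on_a)
            if t_on >= 1.0:
                up, dup = 1.0, 0.0
            else:
                up = 0.5 * (1.0 - math.cos(math.pi * t_on))
                dup = 0.5 * math.pi / (on_b - on_a) * math.sin(math.pi * t_on)
            t_off = (r - off_a) / (off_b - off_a)
            if t_off <= 0.0:
                down, ddown = 1.0, 0.0
            elif t_off >= 1.0:
                down, ddown = 0.0, 0.0
            else:
                down = 0.5 * (1.0 + math.cos(math.pi * t_off))
                ddown = -0.5 * math.pi / (off_b - off_a) * math.sin(math.pi * t_off)
            sigma = up * down
            dsigma = dup * down + up * ddown
            if sigma > 0.0 or dsigma != 0.0:
                coef_n = hsep * sigma * gauss * (-z / (wsep * wsep))
                coef_r = hsep * gauss * dsigma
                fx -= coef_n * nx_ + coef_r * hx
                fy -= coef_n * ny_ + coef_r * hy
                fz -= coef_n * nz_ + coef_r * hz

    return fx, fy, fz


# --------------------------------------------------------------------------
# Fixture PDB
# --------------------------------------------------------------------------

_ROLE_RESNAMES = {
    "reference_atom": "REF",
    "external_marker": "EXM",
    "internal_marker": "INM",
    "gate_external": "GEX",
    "gate_internal": "GIN",
}


def write_fixture_pdb(system: ToySystem, path) -> None:
    """Write the marker/gate beads as one-atom residues (coordinates in Å)."""
    lines = [f"REMARK   6 ramdpath toy system {system.label}"]
    for i, (role, pos) in enumerate(sorted(system.markers.items()), start=1):
        resname = _ROLE_RESNAMES.get(role, role[:3].upper())
        xa, ya, za = (10.0 * pos).tolist()  # nm -> Angstrom
        lines.append(
            f"ATOM  {i:5d}  CA  {resname:>3s} A{i:4d}    "
            f"{xa:8.3f}{ya:8.3f}{za:8.3f}{1.00:6.2f}{0.00:6.2f}          "
            f" C"
        )
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
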