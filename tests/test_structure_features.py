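"""Torsion angles, contact series, and termini distances."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ramdpath.structure_features import (chi_angle_shift, circular_mean,
                                         contact_series, ctermini_distance,
                                         dihedral)
from ramdpath.trajectory_io import Atom, Structure


def projection_dihedral(p1, p2, p3, p4):
    """Independent oracle: project the outer bonds onto the plane normal to
    the central bond and measure the signed angle between the projections."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    axis = (p3 - p2) / np.linalg.norm(p3 - p2)
    u = (p1 - p2) - np.dot(p1 - p2, axis) * axis
    v = (p4 - p3) - np.dot(p4 - p3, axis) * axis
    ang = math.degrees(math.atan2(np.dot(np.cross(u, v), axis), np.dot(u, v)))
    return 180.0 if ang <= -180.0 else ang


class TestDihedral:
    def test_planar_cis_is_zero(self):
        assert dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]) == pytest.approx(0.0)

    def test_planar_trans_is_180(self):
        assert dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]) == pytest.approx(180.0)

    def test_matches_projection_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            pts = rng.normal(size=(4, 3))
            assert dihedral(*pts) == pytest.approx(projection_dihedral(*pts), abs=1e-8)

    def test_matches_mdanalysis(self):
        from MDAnalysis.lib.distances import calc_dihedrals
        rng = np.random.default_rng(12)
        for _ in range(50):
            p = rng.normal(size=(4, 3))
            ref = math.degrees(float(calc_dihedrals(p[0][None], p[1][None],
                                                    p[2][None], p[3][None])[0]))
            diff = (dihedral(*p) - ref + 180.0) % 360.0 - 180.0
            assert abs(diff) < 1e-3  # reference computes in float32

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(13)
        pts = rng.normal(size=(4, 3))
        base = dihedral(*pts)
        for i in range(20):
            rot = Rotation.random(random_state=i).as_matrix()
            shift = rng.normal(size=3)
            moved = pts @ rot.T + shift
            assert dihedral(*moved) == pytest.approx(base, abs=1e-8)

    def test_reversal_symmetry(self):
        # the signed torsion is invariant under reversing the atom order
        # (b1,b2,b3 -> -b3,-b2,-b1 leaves both atan2 arguments unchanged)
        rng = np.random.default_rng(14)
        for _ in range(50):
            pts = rng.normal(size=(4, 3))
            assert dihedral(*pts[::-1]) == pytest.approx(dihedral(*pts), abs=1e-8)

    def test_mirror_antisymmetry(self):
        # reflection flips the sign of the torsion
        rng = np.random.default_rng(15)
        for _ in range(50):
            pts = rng.normal(size=(4, 3))
            a = dihedral(*pts)
            if abs(abs(a) - 180.0) < 1e-6:
                continue
            mirrored = pts * np.array([1.0, 1.0, -1.0])
            assert dihedral(*mirrored) == pytest.approx(-a, abs=1e-8)

    def test_collinear_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            dihedral([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])


def residue_structure(chi1_deg, chain="A", resnum=353):
    """One Tyr-like residue with an exact chi1 torsion (N-CA-CB-CG)."""
    n = np.array([1.0, 0.0, -0.5])
    ca = np.zeros(3)
    cb = np.array([0.0, 0.0, 1.5])
    a = math.radians(chi1_deg)
    # placing CG so that the N-CA-CB-CG torsion equals chi1_deg exactly
    u = np.array([1.0, 0.0, 0.0])   # reference direction: N projected off the CB axis
    v = np.array([0.0, 1.0, 0.0])
    cg = cb + 1.4 * (math.cos(a) * u + math.sin(a) * v)
    if dihedral(n, ca, cb, cg) != pytest.approx(chi1_deg if chi1_deg != -180 else 180, abs=1e-6):
        # sign convention differs from construction; mirror the y component
        cg = cb + 1.4 * (math.cos(a) * u - math.sin(a) * v)
    atoms = [Atom(i + 1, name, "TYR", chain, resnum, pos, name[0])
             for i, (name, pos) in enumerate(
                 [("N", n), ("CA", ca), ("CB", cb), ("CG", cg)])]
    return Structure(atoms)


class TestChiAngleShift:
    def test_identical_frames_no_shift(self):
        s = residue_structure(60.0)
        chi_init, chi_final, shift = chi_angle_shift(s, [s, s, s], "A", 353)
        assert shift == pytest.approx(0.0, abs=1e-9)
        assert chi_init == pytest.approx(chi_final[0], abs=1e-9)

    def test_constructed_90_degree_rotation(self):
        init = residue_structure(30.0)
        final = residue_structure(120.0)
        _, _, shift = chi_angle_shift(init, [final], "A", 353)
        assert abs(abs(shift) - 90.0) < 1e-6

    def test_wraps_through_180(self):
        init = residue_structure(170.0)
        final = residue_structure(-170.0)
        _, _, shift = chi_angle_shift(init, [final], "A", 353)
        assert abs(shift) == pytest.approx(20.0, abs=1e-6)

    def test_missing_atom_named_in_error(self):
        s = residue_structure(10.0)
        s_missing = Structure([a for a in s.atoms if a.name != "CG"])
        with pytest.raises(ValueError, match="CG"):
            chi_angle_shift(s_missing, [s], "A", 353)

    def test_circular_mean_wraps(self):
        assert circular_mean([179.0, -179.0]) == pytest.approx(180.0, abs=1e-9)


def two_bead_frame(distance_nm, chain_b="B"):
    a = Atom(1, "OE1", "GLU", "A", 427, np.zeros(3), "O")
    b = Atom(2, "NH1", "ARG", chain_b, 569, np.array([10.0 * distance_nm, 0, 0]), "N")
    h = Atom(3, "HA", "GLU", "A", 427, np.array([0.1, 0.1, 0.1]), "H")
    return Structure([a, b, h])


class TestContactSeries:
    def test_constant_contact(self):
        series = contact_series([two_bead_frame(0.25)] * 5, ("A", 427), ("B", 569),
                                cutoff=0.35)
        assert series.contact_fraction == 1.0
        np.testing.assert_allclose(series.distances, 0.25)

    def test_constant_no_contact(self):
        series = contact_series([two_bead_frame(0.50)] * 5, ("A", 427), ("B", 569),
                                cutoff=0.35)
        assert series.contact_fraction == 0.0

    def test_alternating_half(self):
        frames = [two_bead_frame(0.3), two_bead_frame(0.5)] * 4
        series = contact_series(frames, ("A", 427), ("B", 569), cutoff=0.35)
        assert series.contact_fraction == pytest.approx(0.5)

    def test_fraction_monotone_in_cutoff(self):
        rng = np.random.default_rng(3)
        frames = [two_bead_frame(d) for d in rng.uniform(0.2, 0.7, 30)]
        fracs = [contact_series(frames, ("A", 427), ("B", 569), cutoff=c).contact_fraction
                 for c in (0.25, 0.35, 0.45, 0.6)]
        assert fracs == sorted(fracs)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            contact_series([two_bead_frame(0.3)], ("A", 427), ("C", 1))

    def test_contacts_consistent_with_cutoff(self):
        frames = [two_bead_frame(d) for d in (0.1, 0.34, 0.36, 0.9)]
        series = contact_series(frames, ("A", 427), ("B", 569), cutoff=0.35)
        np.testing.assert_array_equal(series.contacts, series.distances <= 0.35)


def chain_with_ca(chain, resnums, positions):
    return [Atom(hash((chain, r)) % 10_000 + i, "CA", "GLY", chain, r,
                 np.asarray(p, float), "C")
            for i, (r, p) in enumerate(zip(resnums, positions))]


class TestCTerminiDistance:
    def test_constructed_30_angstrom(self):
        atoms = (chain_with_ca("A", [1], [[0, 0, 0]])
                 + chain_with_ca("B", [1], [[30.0, 0, 0]]))
        for i, a in enumerate(atoms):
            a.serial = i + 1
        assert ctermini_distance(Structure(atoms), "A", "B") == pytest.approx(30.0)

    def test_uses_highest_numbered_residue(self):
        atoms = (chain_with_ca("A", [1, 7, 3], [[0, 0, 0], [0, 0, 5.0], [9, 9, 9]])
                 + chain_with_ca("B", [2], [[0, 0, 0]]))
        for i, a in enumerate(atoms):
            a.serial = i + 1
        assert ctermini_distance(Structure(atoms), "A", "B") == pytest.approx(5.0)

    def test_same_chain_gives_zero(self):
        atoms = chain_with_ca("A", [1], [[1, 2, 3]])
        assert ctermini_distance(Structure(atoms), "A", "A") == 0.0

    def test_missing_chain_rejected(self):
        atoms = chain_with_ca("A", [1], [[0, 0, 0]])
        with pytest.raises(ValueError, match="chain 'B'"):
            ctermini_distance(Structure(atoms), "A", "B")
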