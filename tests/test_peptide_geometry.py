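import numpy as np
import pytest

from helixcst import (
    HBondCriteria,
    HelixFrame,
    angle_to_axis,
    detect_hbonds,
    dihedral,
    fit_helix_axis,
    helix_tilt,
    ramachandran,
    residue_azimuth,
    residue_frames,
)
from helixcst.formats_io import AtomSite, StructureModel
from helixcst.synthetic_data import HelixSpec, build_helix
from .conftest import random_rotation, rigid_motion


class TestDihedral:
    def test_planar_trans_is_180(self):
        assert dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]) == pytest.approx(180.0)

    def test_planar_cis_is_0(self):
        assert dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]) == pytest.approx(0.0)

    def test_collinear_triple_undefined(self):
        with pytest.raises(ValueError, match="collinear"):
            dihedral([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError, match="coincide"):
            dihedral([0, 0, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0])


class TestRamachandran:
    def test_generator_phi_psi_recovered(self, alm_model):
        frames = ramachandran(alm_model)
        for fr in frames:
            if fr.residue_class == "cap":
                assert fr.phi is None and fr.psi is None
                continue
            if fr.phi is not None:
                assert fr.phi == pytest.approx(-57.0, abs=0.1)
            if fr.index < 20:
                assert fr.psi == pytest.approx(-47.0, abs=0.1)

    def test_termini_undefined(self, ala12):
        frames = {fr.index: fr for fr in ramachandran(ala12)}
        assert frames[12].psi is None          # no following N
        assert frames[1].phi is not None       # acetyl cap provides C'

    def test_c_terminal_aminoalcohol_psi_undefined(self, alm_model):
        frames = {fr.index: fr for fr in ramachandran(alm_model)}
        assert frames[20].psi is None
        assert frames[20].phi is not None

    def test_invariant_under_rigid_motion(self, ala12):
        moved, _, _ = rigid_motion(ala12, seed=5)
        a = {fr.index: (fr.phi, fr.psi) for fr in ramachandran(ala12)}
        b = {fr.index: (fr.phi, fr.psi) for fr in ramachandran(moved)}
        for i in a:
            for x, y in zip(a[i], b[i]):
                if x is not None:
                    assert y == pytest.approx(x, abs=1e-8)


class TestHydrogenBonds:
    def test_ideal_alpha_helix_all_interior_i_to_i_plus_4(self, ala12):
        bonds = detect_hbonds(ala12)
        donors = {b.donor: b for b in bonds}
        for i in range(5, 13):  # donors with an acceptor 4 back (cap is 0)
            assert i in donors, f"donor {i} unbonded"
            assert donors[i].span == 4
        assert all(b.span == 4 for b in bonds)

    def test_unsatisfiable_criteria_give_empty_set(self, ala12):
        assert detect_hbonds(ala12, HBondCriteria(max_distance=0.0, min_angle=180.0)) == []

    def test_310_helix_gives_i_to_i_plus_3(self):
        model = build_helix(HelixSpec(sequence=("ALA",) * 8, phi=-49.0, psi=-26.0))
        bonds = detect_hbonds(model)
        assert bonds, "no hydrogen bonds found in 3_10 helix"
        assert any(b.span == 3 for b in bonds)

    def test_missing_h_without_reconstruction_errors(self, ala12):
        frames = residue_frames(ala12)
        for fr in frames:
            fr.H = None
        with pytest.raises(ValueError, match="lack amide H"):
            detect_hbonds(frames, reconstruct_h=False)

    def test_invariant_under_rigid_motion(self, ala12):
        moved, _, _ = rigid_motion(ala12, seed=9)
        a = {(b.donor, b.acceptor) for b in detect_hbonds(ala12)}
        b = {(b.donor, b.acceptor) for b in detect_hbonds(moved)}
        assert a == b


def _ca_trace(model, chain="A"):
    return [model.atom(chain, i, "CA").coords
            for i in model.residue_indices(chain)
            if model.get_atom(chain, i, "CA") is not None]


class TestHelixAxis:
    def test_ideal_helix_axis_and_radius(self, ala12):
        ca = np.asarray(_ca_trace(ala12))
        frame = fit_helix_axis(ca)
        # residuals vanish on an ideal helix
        rel = ca - frame.anchor
        dists = np.linalg.norm(rel - np.outer(rel @ frame.axis, frame.axis), axis=1)
        assert np.ptp(dists) < 1e-6
        assert frame.radius == pytest.approx(2.28, abs=0.05)
        rises = np.diff(rel @ frame.axis)
        assert np.mean(rises) == pytest.approx(1.5, abs=0.1)

    def test_axis_points_n_to_c(self, ala12):
        ca = _ca_trace(ala12)
        frame = fit_helix_axis(ca)
        assert np.dot(frame.axis, ca[-1] - ca[0]) > 0

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_equivariance_under_rotation(self, ala12, seed):
        ca = np.asarray(_ca_trace(ala12))
        axis0 = fit_helix_axis(ca).axis
        R = random_rotation(seed)
        axis1 = fit_helix_axis(ca @ R.T).axis
        ang = np.degrees(np.arccos(np.clip(np.dot(axis1, R @ axis0), -1, 1)))
        assert ang < 0.1

    def test_flat_circle_limit_axis_is_normal(self):
        ang = np.radians([0, 90, 180, 270])
        pts = np.stack([3 * np.cos(ang), 3 * np.sin(ang), np.zeros(4)], axis=1)
        frame = fit_helix_axis(pts)
        assert abs(frame.axis[2]) == pytest.approx(1.0, abs=1e-6)
        assert frame.radius == pytest.approx(3.0, abs=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            fit_helix_axis(np.zeros((3, 3)))

    def test_collinear_points_rejected(self):
        pts = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="degenerate|collinear"):
            fit_helix_axis(pts)


class TestAzimuth:
    def test_ideal_helix_increments_near_100_degrees(self, ala12):
        frame = fit_helix_axis(_ca_trace(ala12))
        rho = residue_azimuth(ala12, frame)
        idx = sorted(i for i in rho if np.isfinite(rho[i]))
        incs = [(rho[b] - rho[a]) % 360 for a, b in zip(idx, idx[1:]) if b - a == 1]
        assert incs, "no consecutive azimuths"
        for inc in incs:
            assert inc == pytest.approx(100.0, abs=1.0)

    def test_reference_residue_is_zero(self, ala12):
        frame = fit_helix_axis(_ca_trace(ala12))
        rho = residue_azimuth(ala12, frame, reference_residue=3)
        assert rho[3] == pytest.approx(0.0, abs=1e-9)

    def test_prescribed_azimuths_recovered(self):
        """Synthetic cylinder with carbonyl vectors at prescribed azimuths."""
        model = StructureModel()
        true_rho = {}
        for i in range(1, 9):
            phase = np.radians(100.0 * (i - 1))
            ca = np.array([2.3 * np.cos(phase), 2.3 * np.sin(phase), 1.5 * i])
            c = ca + np.array([0.4 * np.cos(phase), 0.4 * np.sin(phase), 0.8])
            rho_i = (100.0 * (i - 1) + 20.0) % 360.0
            r = np.radians(rho_i)
            o = c + 1.23 * np.array([np.cos(r), np.sin(r), 0.0])
            true_rho[i] = rho_i
            for name, pos in (("CA", ca), ("C", c), ("O", o)):
                model.add(AtomSite(element=name[0], name=name, coords=pos,
                                   residue_index=i, residue_name="ALA"))
        frame = HelixFrame(axis=[0, 0, 1], anchor=[0, 0, 0], radius=2.3)
        rho = residue_azimuth(model, frame, site_vector="CO", reference_residue=1)
        offset = true_rho[1]
        for i in true_rho:
            expected = (true_rho[i] - offset) % 360.0
            assert rho[i] == pytest.approx(expected, abs=0.5)


class TestTilt:
    def test_parallel_axis_zero(self):
        frame = HelixFrame(axis=[0, 0, 1], anchor=[0, 0, 0], radius=2.3)
        assert helix_tilt(frame, np.array([0, 0, 1.0])) == pytest.approx(0.0)

    def test_perpendicular_axis_ninety(self):
        frame = HelixFrame(axis=[1, 0, 0], anchor=[0, 0, 0], radius=2.3)
        assert helix_tilt(frame, np.array([0, 0, 1.0])) == pytest.approx(90.0)

    @pytest.mark.parametrize("theta", [8.0, 30.0, 77.5])
    def test_constructed_angle_recovered(self, theta):
        t = np.radians(theta)
        frame = HelixFrame(axis=[np.sin(t), 0, np.cos(t)], anchor=[0, 0, 0], radius=2.3)
        assert helix_tilt(frame, np.array([0, 0, 1.0])) == pytest.approx(theta, abs=1e-9)

    def test_zero_normal_rejected(self):
        frame = HelixFrame(axis=[0, 0, 1], anchor=[0, 0, 0], radius=2.3)
        with pytest.raises(ValueError, match="zero"):
            helix_tilt(frame, np.zeros(3))


class TestAngleToAxis:
    def test_aligned_and_perpendicular(self):
        frame = HelixFrame(axis=[0, 0, 1], anchor=[0, 0, 0], radius=2.3)
        assert angle_to_axis(np.array([0, 0, 1.0]), frame) == pytest.approx(0.0)
        assert angle_to_axis(np.array([1, 0, 0.0]), frame) == pytest.approx(90.0)

    def test_planted_eigenvector_angle(self):
        """A least-shielded direction planted 6.4 deg off the axis reads back 6.4."""
        frame = HelixFrame(axis=[0, 0, 1], anchor=[0, 0, 0], radius=2.3)
        t = np.radians(6.4)
        v = np.array([np.sin(t), 0, np.cos(t)])
        assert angle_to_axis(v, frame) == pytest.approx(6.4, abs=1e-9)
        assert angle_to_axis(-v, frame) == pytest.approx(6.4, abs=1e-9)
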