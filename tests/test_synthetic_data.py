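import numpy as np
import pytest

from helixcst import (
    CALIBRATION_15N,
    detect_hbonds,
    fit_helix_axis,
    principal_frame,
    ramachandran,
    read_magres,
    read_structure,
    residue_azimuth,
    shielding_to_shift,
)
from helixcst.peptide_geometry import residue_frames
from helixcst.synthetic_data import (
    ALM_E18_SEQUENCE,
    HelixSpec,
    TensorPlantSpec,
    build_helix,
    plant_tensors,
    write_fixture_bundle,
)
from helixcst.tensor_orientation import orientation_angles_15N, plane_N


def _ca_trace(model):
    chain = model.chains()[0]
    return [model.atom(chain, i, "CA").coords
            for i in model.residue_indices(chain)
            if model.get_atom(chain, i, "CA") is not None]


class TestBuildHelix:
    def test_alpha_helix_rise_and_twist(self, ala12):
        frame = fit_helix_axis(_ca_trace(ala12))
        ca = np.asarray(_ca_trace(ala12))
        rises = np.diff((ca - frame.anchor) @ frame.axis)
        assert np.mean(rises) == pytest.approx(1.5, abs=0.1)
        rho = residue_azimuth(ala12, frame)
        idx = sorted(rho)
        incs = [(rho[b] - rho[a]) % 360 for a, b in zip(idx, idx[1:]) if b - a == 1]
        assert np.mean(incs) == pytest.approx(100.0, abs=1.0)

    def test_achieved_dihedrals_match_spec(self):
        model = build_helix(HelixSpec(sequence=("ALA",) * 6, phi=-62.0, psi=-41.0))
        for fr in ramachandran(model):
            if fr.phi is not None:
                assert fr.phi == pytest.approx(-62.0, abs=0.1)
            if fr.psi is not None:
                assert fr.psi == pytest.approx(-41.0, abs=0.1)

    def test_minimal_two_residue_chain(self):
        model = build_helix(HelixSpec(sequence=("ALA", "GLY")))
        assert model.get_atom("A", 1, "CA") is not None
        assert model.get_atom("A", 2, "N") is not None
        assert model.get_atom("A", 2, "CB") is None  # Gly has no sidechain stub

    def test_proline_has_no_amide_h(self, alm_model):
        assert alm_model.get_atom("A", 2, "H") is None
        assert alm_model.get_atom("A", 14, "H") is None
        assert alm_model.get_atom("A", 3, "H") is not None

    def test_terminal_phenylalaninol_lacks_carbonyl_oxygen(self, alm_model):
        assert alm_model.get_atom("A", 20, "O") is None
        assert alm_model.get_atom("A", 20, "C") is not None

    def test_noise_is_seed_reproducible(self):
        spec = dict(sequence=("ALA",) * 5, coordinate_noise_sd=0.05)
        a = build_helix(HelixSpec(**spec, seed=7))
        b = build_helix(HelixSpec(**spec, seed=7))
        c = build_helix(HelixSpec(**spec, seed=8))
        assert all(np.allclose(x.coords, y.coords) for x, y in zip(a.atoms, b.atoms))
        assert not all(np.allclose(x.coords, y.coords) for x, y in zip(a.atoms, c.atoms))

    def test_unknown_residue_code_rejected(self):
        with pytest.raises(Exception, match="XXX|unknown"):
            build_helix(HelixSpec(sequence=("ALA", "XXX")))


class TestPlantTensors:
    def test_zero_targets_align_with_bond_and_normal(self, alm_model):
        spec = TensorPlantSpec(sites={5: ((200.0, 150.0, 100.0), (0.0, 0.0, 0.0))})
        records, _ = plant_tensors(alm_model, spec)
        frames = {fr.index: fr for fr in residue_frames(alm_model)}
        plane = plane_N(frames[5])
        pf = principal_frame(records[0].matrix)
        assert abs(np.dot(pf.xi3, plane.in_plane_bond)) == pytest.approx(1.0, abs=1e-9)
        assert abs(np.dot(pf.xi2, plane.normal)) == pytest.approx(1.0, abs=1e-9)

    def test_infeasible_angle_combination_rejected(self, alm_model):
        # beta < alpha cannot be realized: alpha bounds beta from below
        spec = TensorPlantSpec(sites={5: ((200.0, 150.0, 100.0), (30.0, 10.0, 45.0))})
        with pytest.raises(ValueError, match="infeasible"):
            plant_tensors(alm_model, spec)

    def test_noisy_recovery_is_unbiased(self, alm_model):
        """Mean recovered angles over many noise seeds match the planted truth."""
        target = (10.0, 25.0, 40.0)
        frames = {fr.index: fr for fr in residue_frames(alm_model)}
        recovered = []
        for seed in range(60):
            spec = TensorPlantSpec(sites={8: ((150.0, 100.0, 30.0), target)},
                                   tensor_noise_sd=2.0, seed=seed)
            records, _ = plant_tensors(alm_model, spec)
            ang = orientation_angles_15N(
                principal_frame(records[0].matrix), plane_N(frames[8])
            )
            recovered.append((ang.alpha, ang.beta, ang.gamma))
        mean = np.mean(recovered, axis=0)
        sem = np.std(recovered, axis=0, ddof=1) / np.sqrt(len(recovered))
        for m, s, t in zip(mean, sem, target):
            assert abs(m - t) < max(4 * s, 0.5)

    def test_truth_is_pre_noise(self, alm_model):
        spec = TensorPlantSpec(sites={8: ((150.0, 100.0, 30.0), (4.2, 12.9, 51.5))},
                               tensor_noise_sd=5.0, seed=3)
        _, truth = plant_tensors(alm_model, spec)
        assert (truth[8].alpha, truth[8].beta, truth[8].gamma) == (4.2, 12.9, 51.5)


class TestFixtureBundle:
    def test_bundle_round_trips_through_formats_io(self, alm_model, tmp_path):
        sites = {i: ((150.0 + i, 100.0, 30.0), (3.0, 14.0, 20.0)) for i in (5, 8, 10)}
        records, truth = plant_tensors(alm_model, TensorPlantSpec(sites=sites))
        paths = write_fixture_bundle(alm_model, records, tmp_path / "b", truth=truth)
        model = read_structure(paths["structure"])
        back = read_magres(paths["magres"], model=model)
        assert len(back) == 3
        import pandas as pd

        tdf = pd.read_csv(paths["truth"])
        assert set(tdf.residue) == {5, 8, 10}
        assert np.allclose(tdf.alpha, 3.0)
        assert np.isfinite(tdf.rho).all() and np.isfinite(tdf.tau).all()

    def test_empty_tensor_spec_gives_structure_only_bundle(self, ala12, tmp_path):
        paths = write_fixture_bundle(ala12, [], tmp_path / "s")
        assert paths["structure"].exists()
        import pandas as pd

        assert len(pd.read_csv(paths["truth"])) == 0


class TestFullPipelineClosure:
    def test_zero_noise_fixture_reproduces_every_planted_quantity(self, tmp_path):
        """Structure -> files -> re-read -> every stage recovers the ground truth."""
        model = build_helix(HelixSpec())
        table_angles = {5: (4.3, 13.1, 31.3), 8: (4.2, 12.9, 51.5)}
        sigma = {5: (151.0, 140.1, 22.4), 8: (150.7, 140.0, 28.7)}
        spec = TensorPlantSpec(
            sites={i: (sigma[i], table_angles[i]) for i in table_angles}
        )
        records, truth = plant_tensors(model, spec)
        paths = write_fixture_bundle(model, records, tmp_path / "bundle", truth=truth)

        m2 = read_structure(paths["structure"])
        recs2 = read_magres(paths["magres"], model=m2)
        # dihedrals
        for fr in ramachandran(m2):
            if fr.phi is not None:
                assert fr.phi == pytest.approx(-57.0, abs=0.1)
        # hydrogen bonds all i -> i+4
        assert {b.span for b in detect_hbonds(m2)} == {4}
        # helix frame and azimuth spacing
        frame = fit_helix_axis(_ca_trace(m2))
        rho = residue_azimuth(m2, frame)
        idx = sorted(i for i in rho if np.isfinite(rho[i]))
        incs = [(rho[b] - rho[a]) % 360 for a, b in zip(idx, idx[1:]) if b - a == 1]
        assert np.mean(incs) == pytest.approx(100.0, abs=1.0)
        # tensors: principal values, calibrated shifts, orientation angles
        frames = {fr.index: fr for fr in residue_frames(m2)}
        for rec in recs2:
            idx = rec.site_key[1]
            pf = principal_frame(rec.matrix)
            assert pf.sigma == pytest.approx(sigma[idx], abs=1e-4)
            shift = shielding_to_shift(pf.sigma, CALIBRATION_15N)
            expected = tuple(CALIBRATION_15N.slope * s + CALIBRATION_15N.intercept
                             for s in sigma[idx])
            assert shift.eps == pytest.approx(expected, abs=1e-4)
            ang = orientation_angles_15N(pf, plane_N(frames[idx]))
            # PDB coordinate rounding costs ~0.01 deg; planting itself is exact
            assert (ang.alpha, ang.beta, ang.gamma) == pytest.approx(
                table_angles[idx], abs=0.05
            )
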