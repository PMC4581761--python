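"""Shrake-Rupley SASA: analytic anchors, invariances, and differencing."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gfdyn.sasa import (atom_sasa, default_radii, sasa_difference,
                        sasa_structure, sasa_trajectory, sphere_points)
from gfdyn.structure_io import Trajectory
from gfdyn.synthetic import (Occluder, SyntheticSpec, build_toy_complex,
                             sample_trajectory)


class TestAtomSasa:
    def test_single_sphere_analytic(self):
        """Lone carbon: SASA = 4 pi (1.70 + 1.40)^2, within 1% at 960 dots."""
        out = atom_sasa(np.zeros((1, 3)), np.array([1.70]), probe=1.4,
                        n_points=960)
        exact = 4 * np.pi * 3.10 ** 2
        assert out[0] == pytest.approx(exact, rel=0.01)

    def test_fully_caged_atom_is_zero(self):
        centre = np.zeros((1, 3))
        cage = 3.0 * sphere_points(40)
        coords = np.vstack([centre, cage])
        radii = np.array([1.5] + [2.5] * 40)
        out = atom_sasa(coords, radii, probe=1.4, n_points=960)
        assert out[0] == 0.0

    def test_non_overlapping_additivity(self):
        coords = np.array([[0.0, 0, 0], [50.0, 0, 0]])
        out = atom_sasa(coords, np.array([1.7, 1.7]), n_points=960)
        single = atom_sasa(np.zeros((1, 3)), np.array([1.7]), n_points=960)[0]
        assert out.sum() == pytest.approx(2 * single, rel=1e-12)

    def test_convergence_with_point_count(self):
        """One- and two-sphere results track the analytic values inside an
        envelope that tightens with the dot count.  (A lone sphere is exact
        at any count: every dot is accessible.)"""
        exact1 = 4 * np.pi * 3.1 ** 2
        # two equal spheres, centre distance d: each loses a cap of height
        # h = R - d/2 on the expanded sphere of radius R
        R, d = 3.1, 2.0
        exact2 = 2 * (4 * np.pi * R ** 2 - 2 * np.pi * R * (R - d / 2))
        bounds = {96: 0.01, 960: 0.005, 9600: 0.001}
        for n, bound in bounds.items():
            s1 = atom_sasa(np.zeros((1, 3)), np.array([1.7]), n_points=n)[0]
            assert s1 == pytest.approx(exact1, rel=1e-9)
            coords = np.array([[0.0, 0, 0], [d, 0, 0]])
            s2 = atom_sasa(coords, np.array([1.7, 1.7]), n_points=n).sum()
            assert abs(s2 - exact2) / exact2 <= bound

    def test_occlusion_never_increases_sasa(self, rng):
        coords = rng.normal(size=(10, 3)) * 3.0
        radii = np.full(10, 1.6)
        base = atom_sasa(coords, radii, n_points=960)
        crowded = np.vstack([coords, rng.normal(size=(5, 3)) * 3.0])
        out = atom_sasa(crowded, np.full(15, 1.6), n_points=960)
        assert np.all(out[:10] <= base + 1e-9)


class TestStructureSasa:
    def test_rigid_motion_invariance(self, bridged_system, rng):
        """Totals within 0.5% under random rigid motions; per-residue
        values within the coarser per-atom quadrature scatter."""
        model, _ = bridged_system
        base = sasa_structure(model, n_points=1920)
        for state in (5, 6):
            R = Rotation.random(random_state=state).as_matrix()
            moved = model.coords @ R.T + rng.normal(size=3) * 20
            prof = sasa_structure(model, coords=moved, n_points=1920)
            assert prof.total_sasa == pytest.approx(base.total_sasa, rel=5e-3)
            np.testing.assert_allclose(prof.mean_sasa, base.mean_sasa,
                                       rtol=0.03, atol=1.0)

    def test_total_is_sum_of_residues(self, bridged_system):
        model, _ = bridged_system
        prof = sasa_structure(model)
        assert prof.total_sasa == pytest.approx(prof.mean_sasa.sum(), rel=1e-6)

    def test_missing_element_radius_named(self, bridged_system):
        model, _ = bridged_system
        with pytest.raises(KeyError, match="N"):
            sasa_structure(model, radii={"C": 1.7, "O": 1.52})

    def test_independent_implementation_agreement(self):
        """Totals match biotite's Shrake-Rupley on a ~50-atom complex
        within 2%."""
        biotite_struc = pytest.importorskip("biotite.structure")
        spec = SyntheticSpec(n_ligand_residues=6, n_receptor_residues=6, seed=3)
        model, _ = build_toy_complex(spec)
        arr = biotite_struc.AtomArray(model.n_atoms)
        for i, a in enumerate(model.atoms):
            arr.coord[i] = a.coords
            arr.chain_id[i] = a.chain_id
            arr.res_id[i] = a.residue_seq
            arr.res_name[i] = a.residue_name
            arr.atom_name[i] = a.name
            arr.element[i] = a.element
        radii = default_radii()
        vdw = np.array([radii[a.element] for a in model.atoms])
        theirs = float(biotite_struc.sasa(arr, probe_radius=1.4,
                                          point_number=960,
                                          vdw_radii=vdw).sum())
        ours = sasa_structure(model).total_sasa
        assert ours == pytest.approx(theirs, rel=0.02)


class TestTrajectorySasa:
    def test_static_equals_structure(self, bridged_system):
        model, _ = bridged_system
        frames = np.repeat(model.coords[None], 8, axis=0)
        traj = Trajectory(model, frames, 10.0)
        prof = sasa_trajectory(traj, skip_fraction=0.125, n_points=240)
        ref = sasa_structure(model, n_points=240)
        np.testing.assert_allclose(prof.mean_sasa, ref.mean_sasa, atol=1e-9)

    def test_window_skips_first_half(self, bridged_system):
        model, _ = bridged_system
        # frames 0-4 collapsed to a point cloud with different SASA than 5-9
        open_f = model.coords
        shut_f = model.coords * 0.5
        frames = np.array([shut_f] * 5 + [open_f] * 5)
        traj = Trajectory(model, frames, 10.0)
        prof = sasa_trajectory(traj, skip_fraction=0.5, n_points=240)
        ref = sasa_structure(model, n_points=240)
        np.testing.assert_allclose(prof.mean_sasa, ref.mean_sasa, atol=1e-9)

    def test_duty_cycle_average(self, bridged_system):
        """Alternating open/shut geometry averages by its duty cycle."""
        model, _ = bridged_system
        open_f = model.coords
        shut_f = model.coords * 0.6
        frames = np.array([open_f, open_f, open_f, shut_f] * 3)
        traj = Trajectory(model, frames, 10.0)
        prof = sasa_trajectory(traj, skip_fraction=0.0, n_points=240)
        po = sasa_structure(model, n_points=240).mean_sasa
        ps = sasa_structure(model, coords=shut_f, n_points=240).mean_sasa
        np.testing.assert_allclose(prof.mean_sasa, 0.75 * po + 0.25 * ps,
                                   atol=1e-9)

    def test_bad_skip_rejected(self, bridged_trajectory):
        with pytest.raises(ValueError):
            sasa_trajectory(bridged_trajectory, skip_fraction=1.0)


class TestSasaDifference:
    def test_self_difference_zero(self, bridged_system):
        model, _ = bridged_system
        prof = sasa_structure(model, n_points=240)
        d = sasa_difference(prof, prof)
        np.testing.assert_allclose(d.delta, 0.0)
        assert not d.highlighted.any()

    def test_boundary_is_strict(self):
        from gfdyn.sasa import SasaProfile
        rids = [("A", 1, "")]
        a = SasaProfile(rids, np.array([100.0]))
        b = SasaProfile(rids, np.array([60.0]))
        d = sasa_difference(a, b, cutoff=40.0)
        assert d.delta[0] == pytest.approx(40.0)
        assert not d.highlighted.any()

    def test_planted_occlusion_highlighted(self):
        """A large pseudo-glycan drops its attachment residue's SASA by
        more than 40 A^2; a small one stays under the cutoff."""
        base, _ = build_toy_complex(SyntheticSpec(seed=1))
        prof_base = sasa_structure(base)
        large, _ = build_toy_complex(
            SyntheticSpec(occluders=[Occluder("A", 5, 3)], seed=1))
        d_large = sasa_difference(sasa_structure(large), prof_base)
        assert d_large.highlighted_residues() == [("A", 5, "")]
        small, _ = build_toy_complex(
            SyntheticSpec(occluders=[Occluder("A", 5, 1)], seed=1))
        d_small = sasa_difference(sasa_structure(small), prof_base)
        assert d_small.highlighted_residues() == []
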