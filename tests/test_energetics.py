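"""MM kernels, Generalized-Born limits, ledger identities, oracle checks."""

import numpy as np
import pytest

from gfdyn.energetics import (COULOMB_CONSTANT, EnergyModelConfig,
                              binding_components, bonded_energy,
                              gb_born_radii, gb_polar_energy, mmgbsa_summary,
                              nonbonded_energy, nonpolar_energy,
                              snapshot_energy, snapshot_indices)
from gfdyn.structure_io import ForceFieldTable, Trajectory
from gfdyn.synthetic import (PlantedBridge, SyntheticSpec, build_toy_complex,
                             sample_trajectory)


def _ff(n, charge=0.0, sigma=3.0, eps=0.1, gb_r=2.0, **bonded):
    return ForceFieldTable(np.full(n, charge), np.full(n, sigma),
                           np.full(n, eps), np.full(n, gb_r),
                           np.full(n, 0.8), **bonded)


class TestBonded:
    def test_bond_at_rest_length_zero(self):
        ff = _ff(2, bonds=[(0, 1, 100.0, 1.5)])
        coords = np.array([[0.0, 0, 0], [1.5, 0, 0]])
        assert bonded_energy(coords, ff) == pytest.approx(0.0, abs=1e-12)

    def test_stretched_bond_hand_value(self):
        """k_b = 100, stretch 0.1 A -> exactly 1.0 kcal/mol."""
        ff = _ff(4, bonds=[(0, 1, 100.0, 1.5)])
        coords = np.array([[0.0, 0, 0], [1.6, 0, 0], [0, 5, 0], [0, 0, 5.0]])
        assert bonded_energy(coords, ff) == pytest.approx(1.0, abs=1e-10)

    def test_dihedral_cosine_extrema(self):
        barrier = 3.0
        ff_trans = _ff(4, dihedrals=[(0, 1, 2, 3, barrier, 1, 0.0)])
        trans = np.array([[0.0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]])
        cis = np.array([[0.0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]])
        assert bonded_energy(trans, ff_trans) == pytest.approx(0.0, abs=1e-10)
        assert bonded_energy(cis, ff_trans) == pytest.approx(2 * barrier, abs=1e-10)

    def test_collinear_dihedral_rejected(self):
        ff = _ff(4, dihedrals=[(0, 1, 2, 3, 1.0, 1, 0.0)])
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError, match="dihedral"):
            bonded_energy(line, ff)


class TestNonbonded:
    def test_coulomb_constant_definition(self):
        ff = _ff(2, charge=1.0, eps=0.0)
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        ele, _ = nonbonded_energy(coords, ff)
        assert ele == pytest.approx(COULOMB_CONSTANT, abs=1e-9)

    def test_lj_minimum_closed_form(self):
        eps = 0.25
        ff = ForceFieldTable(np.zeros(2), np.array([3.0, 3.4]),
                             np.full(2, eps), np.full(2, 2.0), np.full(2, 0.8))
        sigma_ij = 3.2
        r_min = 2 ** (1 / 6) * sigma_ij
        coords = np.array([[0.0, 0, 0], [r_min, 0, 0]])
        _, vdw = nonbonded_energy(coords, ff)
        assert vdw == pytest.approx(-eps, abs=1e-10)

    def test_zero_charge_keeps_vdw(self):
        ff = _ff(2, charge=1.0)
        coords = np.array([[0.0, 0, 0], [3.2, 0, 0]])
        ele0, vdw0 = nonbonded_energy(coords, ff)
        ff2 = _ff(2, charge=0.0)
        ele1, vdw1 = nonbonded_energy(coords, ff2)
        assert ele0 != 0 and ele1 == 0
        assert vdw0 == pytest.approx(vdw1)

    def test_exclusions_and_14_scaling(self):
        # 4-atom chain: 0-1-2-3 bonded, angle 0-1-2 and 1-2-3, dihedral 0-1-2-3
        ff = _ff(4, charge=0.5, eps=0.0,
                 bonds=[(0, 1, 1.0, 1.0), (1, 2, 1.0, 1.0), (2, 3, 1.0, 1.0)],
                 angles=[(0, 1, 2, 1.0, 2.0), (1, 2, 3, 1.0, 2.0)],
                 dihedrals=[(0, 1, 2, 3, 0.0, 1, 0.0)])
        coords = np.array([[0.0, 0, 0], [1, 0, 0], [1, 1, 0], [2, 1, 0]])
        ele, _ = nonbonded_energy(coords, ff)
        # only the 1-4 pair (0,3) survives, scaled by 1/1.2
        r14 = np.linalg.norm(coords[3] - coords[0])
        expected = (1 / 1.2) * COULOMB_CONSTANT * 0.25 / r14
        assert ele == pytest.approx(expected, rel=1e-12)

    def test_coincident_atoms_rejected(self):
        ff = _ff(2, charge=1.0)
        with pytest.raises(ZeroDivisionError):
            nonbonded_energy(np.zeros((2, 3)), ff)


class TestGeneralizedBorn:
    def test_single_ion_born_closed_form(self):
        ff = _ff(1, charge=1.0, gb_r=2.0)
        e = gb_polar_energy(np.zeros((1, 3)), ff)
        born = -0.5 * COULOMB_CONSTANT * (1 - 1 / 80.0) / 2.0
        assert e == pytest.approx(born, rel=1e-3)

    def test_zero_charge_zero_energy(self):
        ff = _ff(3, charge=0.0)
        assert gb_polar_energy(np.eye(3) * 4, ff) == 0.0

    def test_distant_ions_separable(self):
        ff = _ff(2, charge=1.0, gb_r=2.0)
        coords = np.array([[0.0, 0, 0], [1.0e4, 0, 0]])
        e = gb_polar_energy(coords, ff)
        born = -0.5 * COULOMB_CONSTANT * (1 - 1 / 80.0) / 2.0
        assert e == pytest.approx(2 * born, rel=1e-3)

    def test_monotone_in_solvent_dielectric(self):
        ff = _ff(2, charge=1.0, gb_r=2.0)
        coords = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        energies = [gb_polar_energy(coords, ff,
                                    EnergyModelConfig(solvent_dielectric=d))
                    for d in (2.0, 10.0, 80.0, 1000.0)]
        assert all(a > b for a, b in zip(energies, energies[1:]))

    def test_rigid_motion_invariance(self, rng):
        from scipy.spatial.transform import Rotation
        coords = rng.normal(size=(6, 3)) * 3.0
        ff = _ff(6, charge=0.4)
        base = gb_polar_energy(coords, ff)
        R = Rotation.random(random_state=3).as_matrix()
        moved = coords @ R.T + np.array([10.0, -4.0, 2.0])
        assert gb_polar_energy(moved, ff) == pytest.approx(base, abs=1e-9)

    def test_descreening_grows_born_radii(self):
        """A buried atom is less solvent-exposed, so its effective Born
        radius exceeds the isolated (intrinsic) one."""
        ff = _ff(2, charge=1.0, gb_r=2.0)
        lone = gb_born_radii(np.array([[0.0, 0, 0], [50.0, 0, 0]]), ff)
        close = gb_born_radii(np.array([[0.0, 0, 0], [3.0, 0, 0]]), ff)
        assert lone[0] == pytest.approx(2.0, rel=1e-6)
        assert close[0] > lone[0]

    def test_obc_variant_also_recovers_distant_limit(self):
        ff = _ff(2, charge=1.0, gb_r=2.0)
        coords = np.array([[0.0, 0, 0], [1.0e4, 0, 0]])
        cfg = EnergyModelConfig(gb_model="OBC-II")
        e = gb_polar_energy(coords, ff, cfg)
        # OBC applies a 0.09 A offset: the isolated radius is R - offset
        born = -COULOMB_CONSTANT * (1 - 1 / 80.0) / (2.0 - 0.09)
        assert e == pytest.approx(born, rel=2e-3)


class TestNonpolar:
    def test_intercept_is_beta(self):
        assert nonpolar_energy(0.0) == pytest.approx(0.92)

    def test_direct_evaluation(self):
        assert nonpolar_energy(1000.0) == pytest.approx(6.34)

    def test_linearity(self, rng):
        cfg = EnergyModelConfig()
        for s in rng.uniform(10, 5000, size=20):
            e1 = nonpolar_energy(s, cfg) - cfg.beta
            e2 = nonpolar_energy(2 * s, cfg) - cfg.beta
            assert e2 == pytest.approx(2 * e1, rel=1e-12)

    def test_negative_sasa_rejected(self):
        with pytest.raises(ValueError):
            nonpolar_energy(-1.0)

    def test_entropy_request_rejected(self):
        with pytest.raises(ValueError, match="entropy"):
            EnergyModelConfig(include_entropy=True)


def _naive_mm_energy(coords, ff, config):
    """Independent O(n^2) loop oracle for the gas-phase MM energy."""
    excl = set()
    for i, j, *_ in ff.bonds:
        excl.add(frozenset((i, j)))
    for i, _, k, *_ in ff.angles:
        excl.add(frozenset((i, k)))
    one_four = set()
    for i, _, _, l, *_ in ff.dihedrals:
        if frozenset((i, l)) not in excl:
            one_four.add(frozenset((i, l)))
    ele = vdw = 0.0
    n = ff.n_atoms
    for i in range(n):
        for j in range(i + 1, n):
            key = frozenset((i, j))
            if key in excl:
                continue
            se = config.scale_ele_14 if key in one_four else 1.0
            sl = config.scale_lj_14 if key in one_four else 1.0
            r = float(np.linalg.norm(coords[i] - coords[j]))
            ele += se * config.coulomb_constant * ff.charge[i] * ff.charge[j] / r
            sig = 0.5 * (ff.lj_sigma[i] + ff.lj_sigma[j])
            eps = np.sqrt(ff.lj_epsilon[i] * ff.lj_epsilon[j])
            sr6 = (sig / r) ** 6
            vdw += sl * 4 * eps * (sr6 ** 2 - sr6)
    bonded = 0.0
    for i, j, kb, r0 in ff.bonds:
        bonded += kb * (np.linalg.norm(coords[i] - coords[j]) - r0) ** 2
    for i, j, k, ka, t0 in ff.angles:
        v1, v2 = coords[i] - coords[j], coords[k] - coords[j]
        th = np.arccos(np.clip(np.dot(v1, v2)
                               / (np.linalg.norm(v1) * np.linalg.norm(v2)),
                               -1, 1))
        bonded += ka * (th - t0) ** 2
    for i, j, k, l, v, per, ph in ff.dihedrals:
        b1, b2, b3 = coords[j] - coords[i], coords[k] - coords[j], coords[l] - coords[k]
        n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
        m1 = np.cross(n1, b2 / np.linalg.norm(b2))
        phi = np.arctan2(np.dot(m1, n2), np.dot(n1, n2))
        bonded += v * (1 + np.cos(per * phi - ph))
    return bonded, ele, vdw


class TestSnapshotAssembly:
    def test_oracle_equivalence_on_toy_complex(self):
        """Vectorised kernels match the naive O(n^2) loops to 1e-10 on a
        <100-atom fixture."""
        spec = SyntheticSpec(n_ligand_residues=8, n_receptor_residues=10,
                             planted_bridges=[PlantedBridge(3, 3, 0.8)],
                             seed=6)
        model, ff = build_toy_complex(spec)
        assert model.n_atoms <= 100
        cfg = EnergyModelConfig()
        coords = model.coords
        bonded_o, ele_o, vdw_o = _naive_mm_energy(coords, ff, cfg)
        assert bonded_energy(coords, ff) == pytest.approx(bonded_o, abs=1e-10)
        ele, vdw = nonbonded_energy(coords, ff, cfg)
        assert ele == pytest.approx(ele_o, abs=1e-10)
        assert vdw == pytest.approx(vdw_o, abs=1e-10)

    def test_ledger_identities_exact(self, bridged_system):
        model, ff = bridged_system
        c = snapshot_energy(model, model.coords, ff)
        assert c.gbsol == pytest.approx(c.gb_polar + c.nonpolar, abs=1e-9)
        assert c.gbtot == pytest.approx(
            c.internal + c.electrostatic + c.vdw + c.gbsol, abs=1e-9)

    def test_composition_matches_kernels(self, bridged_system):
        from gfdyn.sasa import sasa_structure
        model, ff = bridged_system
        cfg = EnergyModelConfig()
        c = snapshot_energy(model, model.coords, ff, cfg)
        assert c.internal == pytest.approx(bonded_energy(model.coords, ff))
        ele, vdw = nonbonded_energy(model.coords, ff, cfg)
        assert (c.electrostatic, c.vdw) == (pytest.approx(ele), pytest.approx(vdw))
        assert c.gb_polar == pytest.approx(gb_polar_energy(model.coords, ff, cfg))
        sasa_tot = sasa_structure(model, n_points=cfg.sasa_n_points,
                                  exclude_resnames=()).total_sasa
        assert c.nonpolar == pytest.approx(nonpolar_energy(sasa_tot, cfg))

    def test_uncharged_zero_gamma_beta(self, bridged_system):
        model, ff = bridged_system
        ff0 = ForceFieldTable(np.zeros_like(ff.charge), ff.lj_sigma,
                              ff.lj_epsilon, ff.gb_radius, ff.gb_scale,
                              ff.bonds, ff.angles, ff.dihedrals)
        cfg = EnergyModelConfig(gamma=0.0, beta=0.0)
        c = snapshot_energy(model, model.coords, ff0, cfg)
        assert c.gbtot == pytest.approx(c.internal + c.vdw, abs=1e-9)


class TestSummary:
    def test_snapshot_protocol_count(self):
        """A 40 ns-equivalent trajectory sampled at 1 ns gives exactly 40
        snapshots."""
        idx = snapshot_indices(400, 100.0, 1000.0)
        assert idx.shape == (40,)
        assert idx[0] == 9 and idx[-1] == 399

    def test_static_trajectory_zero_sd(self, bridged_system):
        model, ff = bridged_system
        frames = np.repeat(model.coords[None], 20, axis=0)
        traj = Trajectory(model, frames, 100.0)
        cfg = EnergyModelConfig(sasa_n_points=240)
        summ = mmgbsa_summary(traj, ff, cfg, snapshot_interval=500.0)
        assert summ.n_snapshots == 4
        assert all(sd == pytest.approx(0.0, abs=1e-9)
                   for sd in summ.sd.values())
        m = summ.mean
        assert m.gbtot == pytest.approx(
            m.internal + m.electrostatic + m.vdw + m.gbsol, abs=1e-9)

    def test_binding_mode_bonded_cancellation(self, bridged_system):
        """Single-trajectory binding difference: internal energy cancels
        exactly; with far-separated neutral chains all deltas vanish."""
        model, ff = bridged_system
        delta = binding_components(model, model.coords, ff,
                                   EnergyModelConfig(sasa_n_points=240))
        assert delta.internal == pytest.approx(0.0, abs=1e-9)

        # detach the receptor far away and turn all charges off
        mask = np.array([[a.chain_id == "R"] for a in model.atoms])
        far = model.coords + np.array([0.0, 500.0, 0.0]) * mask
        ff0 = ForceFieldTable(np.zeros_like(ff.charge), ff.lj_sigma,
                              ff.lj_epsilon, ff.gb_radius, ff.gb_scale,
                              ff.bonds, ff.angles, ff.dihedrals)
        cfg = EnergyModelConfig(gamma=0.0, beta=0.0, sasa_n_points=240)
        d0 = binding_components(model, far, ff0, cfg)
        assert d0.internal == 0.0
        assert d0.vdw == pytest.approx(0.0, abs=1e-6)
        assert d0.electrostatic == pytest.approx(0.0, abs=1e-9)
        assert d0.gbtot == pytest.approx(0.0, abs=1e-3)

    def test_binding_mode_summary_shape(self, bridged_spec, bridged_system):
        model, ff = bridged_system
        traj = sample_trajectory(model, bridged_spec)
        cfg = EnergyModelConfig(sasa_n_points=96)
        out = mmgbsa_summary(traj, ff, cfg, snapshot_interval=4000.0,
                             mode="binding")
        assert set(out) == {"complex", "receptor", "ligand", "delta"}
        assert out["delta"].mean.internal == pytest.approx(0.0, abs=1e-9)
        n = out["complex"].n_snapshots
        assert out["delta"].n_snapshots == n > 0
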