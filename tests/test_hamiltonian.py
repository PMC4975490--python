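"""Multi-basin Hamiltonian assembly, energies and forces."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gomotor import (ForceFieldParams, assemble, build_bonded, forces,
                     potential_energy, read_topology, write_topology)
from gomotor.hamiltonian import (EnergyModel, TermSet, angle_between,
                                 dihedral_angle)
from gomotor.pipeline import TOGGLES
from gomotor.structure import CAlphaStructure


def _chain(coords):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    return CAlphaStructure(coords=coords, chain_ids=np.full(n, "A"),
                           res_numbers=np.arange(1, n + 1),
                           res_names=np.full(n, "GLY"))


def _single_term_model(ts, n, chains=None):
    m = EnergyModel(n_beads=n,
                    chain_ids=np.full(n, "A") if chains is None else chains,
                    term_sets={"preMH": ts}, active={"preMH"},
                    params=ForceFieldParams())
    m.repulsive_pairs = np.zeros((0, 2), dtype=int)
    return m


class TestForceFieldParams:
    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            ForceFieldParams(k_bond=0.0)
        with pytest.raises(ValueError):
            ForceFieldParams(eps_h=-1.0)

    def test_reduced_unit_conversion(self):
        red = ForceFieldParams().reduced()
        # 20 kcal/(mol A^2) = 2000 kcal/(mol nm^2); eps_h = 1 kcal/mol
        assert red["k_bond"] == pytest.approx(2000.0)
        assert red["sigma"] == pytest.approx(0.4)
        # doubling eps_h halves every reduced stiffness
        red2 = ForceFieldParams(eps_h=2.0).reduced()
        assert red2["k_bond"] == pytest.approx(1000.0)


class TestBuildBonded:
    def test_term_counts_for_five_beads(self, toy_structures):
        pre, _post, _part = toy_structures
        topo = build_bonded(pre, np.arange(1, 6))
        assert len(topo.bonds) == 4
        assert len(topo.angles) == 3
        assert len(topo.dihedrals) == 2

    def test_collinear_triple_has_angle_pi(self):
        st = _chain([[0, 0, 0], [0.4, 0, 0], [0.8, 0, 0]])
        topo = build_bonded(st, np.arange(1, 4))
        assert topo.theta0[0] == pytest.approx(np.pi)

    def test_planar_cis_quad_has_zero_dihedral(self):
        st = _chain([[0, 0, 0], [0.4, 0, 0], [0.4, 0.4, 0], [0, 0.4, 0]])
        topo = build_bonded(st, np.arange(1, 5))
        assert topo.phi0[0] == pytest.approx(0.0, abs=1e-12)

    def test_noncontiguous_group_raises(self, toy_structures):
        pre, _post, _part = toy_structures
        with pytest.raises(ValueError, match="contiguous"):
            build_bonded(pre, np.array([1, 2, 4]))

    def test_signed_dihedral_convention(self):
        # a right-handed twist gives a positive angle in (-pi, pi]
        p = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [1, 1, 1]], float)
        assert dihedral_angle(*p) == pytest.approx(np.pi / 2)
        assert dihedral_angle(*p[::-1]) == pytest.approx(np.pi / 2)
        assert angle_between(p[0], p[1], p[2]) == pytest.approx(np.pi / 2)


class TestPairPotentials:
    def test_native_contact_minimum_depth_and_force(self):
        ts = TermSet(pairs=np.array([[1, 2]]), pair_r0=np.array([0.6]),
                     pair_eps=np.array([1.0]))
        m = _single_term_model(ts, 2)
        x = np.array([[0.0, 0, 0], [0.6, 0, 0]])
        e, bd = potential_energy(m, x)
        assert e == pytest.approx(-1.0)
        f = forces(m, x)
        np.testing.assert_allclose(f, 0.0, atol=1e-10)
        # energy rises on both sides of r0 and vanishes at large r
        for r in (0.5, 0.7):
            x2 = np.array([[0.0, 0, 0], [r, 0, 0]])
            assert potential_energy(m, x2)[0] > -1.0
        far = np.array([[0.0, 0, 0], [60.0, 0, 0]])
        assert potential_energy(m, far)[0] == pytest.approx(0.0, abs=1e-10)

    def test_repulsion_equals_eps_l_at_sigma(self):
        m = EnergyModel(n_beads=2, chain_ids=np.array(["A", "B"]),
                        term_sets={}, active=set(), params=ForceFieldParams())
        x = np.array([[0.0, 0, 0], [0.4, 0, 0]])
        e, bd = potential_energy(m, x)
        assert bd["repulsion"] == pytest.approx(1.0)


class TestAssembly:
    def test_native_pre_structure_energy(self, toy_system):
        sys_ = toy_system
        model = assemble(sys_.pre, sys_.post, sys_.partition, sys_.maps,
                         toggles=("preMH", "preConv", "preConvMH"))
        _e, bd = potential_energy(model, sys_.pre.coords)
        n_contacts = (len(sys_.maps["preMH"]) + len(sys_.maps["preConv"])
                      + len(sys_.maps["preConvMH"]))
        bonded_plus_contacts = bd["preMH"] + bd["preConv"] + bd["preConvMH"]
        # at the native geometry every bonded term is exactly zero and every
        # contact sits at its minimum of -eps_h
        assert bonded_plus_contacts == pytest.approx(-n_contacts, abs=1e-8)

    def test_leading_toggles_carry_no_post_terms(self, toy_system):
        sys_ = toy_system
        model = assemble(sys_.pre, sys_.post, sys_.partition, sys_.maps,
                         toggles=TOGGLES["leading"])
        active = model.active_term_sets()
        assert "postConv" not in active and "postConvMH" not in active

    def test_all_toggles_add_exactly_the_post_terms(self, toy_system):
        sys_ = toy_system

        def n_pairs(toggles):
            model = assemble(sys_.pre, sys_.post, sys_.partition, sys_.maps,
                             toggles=toggles)
            return sum(len(ts.pairs) for ts in model.active_term_sets().values())

        pre_only = n_pairs(("preMH", "preConv", "preConvMH"))
        all_on = n_pairs(("preMH", "preConv", "postConv", "preConvMH",
                          "postConvMH"))
        expected_extra = len(sys_.maps["postConv"]) + len(sys_.maps["postConvMH"])
        assert all_on - pre_only == expected_extra

    def test_pi_removal_drops_exactly_the_subset(self, toy_system):
        sys_ = toy_system
        kw = dict(toggles=TOGGLES["powerstroke_with_pi"],
                  pi_subset=sys_.pi_subset)
        with_pi = assemble(sys_.pre, sys_.post, sys_.partition, sys_.maps,
                           pi_removed=False, **kw)
        without = assemble(sys_.pre, sys_.post, sys_.partition, sys_.maps,
                           pi_removed=True, **kw)
        drop = len(with_pi.term_sets["preMH"].pairs) \
            - len(without.term_sets["preMH"].pairs)
        assert drop == len(sys_.pi_subset)

    def test_missing_map_for_active_toggle_raises(self, toy_system):
        sys_ = toy_system
        maps = {k: v for k, v in sys_.maps.items() if k != "postConvMH"}
        with pytest.raises(ValueError, match="postConvMH"):
            assemble(sys_.pre, sys_.post, sys_.partition, maps,
                     toggles=TOGGLES["trailing"])

    def test_repulsion_excludes_native_and_bonded(self, toy_system):
        sys_ = toy_system
        model = assemble(sys_.pre, sys_.post, sys_.partition, sys_.maps,
                         toggles=TOGGLES["powerstroke_with_pi"])
        rep = {tuple(p) for p in model.repulsive_pairs.tolist()}
        for ts in model.active_term_sets().values():
            for i, j in ts.pairs.reshape(-1, 2):
                assert (int(i), int(j)) not in rep
        # chain neighbours |i-j| <= 3 never repel
        assert all(j - i > 3 or sys_.pre.chain_ids[i - 1] != sys_.pre.chain_ids[j - 1]
                   for i, j in rep)
        # the frozen filament has no internal terms
        actin = set(sys_.partition["actin"].tolist())
        assert not any(i in actin and j in actin for i, j in rep)

    def test_toggle_bookkeeping_is_local(self, toy_system):
        sys_ = toy_system
        model = assemble(sys_.pre, sys_.post, sys_.partition, sys_.maps,
                         toggles=TOGGLES["powerstroke_with_pi"])
        before = {t: ts.n_terms() for t, ts in model.active_term_sets().items()}
        model.set_toggles(set(TOGGLES["powerstroke_with_pi"]) - {"postConvMH"})
        after = model.active_term_sets()
        assert "postConvMH" not in after
        for tag, ts in after.items():
            assert ts.n_terms() == before[tag]


class TestForces:
    def test_analytic_forces_match_central_differences(self, toy_system):
        sys_ = toy_system
        model = assemble(sys_.pre, sys_.post, sys_.partition, sys_.maps,
                         toggles=TOGGLES["powerstroke_with_pi"])
        model.frozen[:] = False       # probe every bead
        rng = np.random.default_rng(0)
        x = sys_.pre.coords + 0.03 * rng.standard_normal(sys_.pre.coords.shape)
        f = forces(model, x)
        eps = 1e-6
        for _ in range(20):
            i = rng.integers(0, model.n_beads)
            k = rng.integers(0, 3)
            xp, xm = x.copy(), x.copy()
            xp[i, k] += eps
            xm[i, k] -= eps
            fnum = -(potential_energy(model, xp)[0]
                     - potential_energy(model, xm)[0]) / (2 * eps)
            assert f[i, k] == pytest.approx(fnum, rel=1e-6, abs=1e-7)

    def test_internal_forces_have_zero_net_force_and_torque(self, toy_system):
        sys_ = toy_system
        model = assemble(sys_.pre, sys_.post, sys_.partition, sys_.maps,
                         toggles=TOGGLES["powerstroke_with_pi"])
        model.frozen[:] = False
        rng = np.random.default_rng(1)
        x = sys_.pre.coords + 0.03 * rng.standard_normal(sys_.pre.coords.shape)
        f = forces(model, x)
        np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(np.cross(x, f).sum(axis=0), 0.0, atol=1e-8)

    def test_energy_invariant_under_rigid_transform(self, toy_system):
        sys_ = toy_system
        model = assemble(sys_.pre, sys_.post, sys_.partition, sys_.maps,
                         toggles=TOGGLES["powerstroke_with_pi"])
        rng = np.random.default_rng(2)
        x = sys_.pre.coords + 0.03 * rng.standard_normal(sys_.pre.coords.shape)
        e0, _ = potential_energy(model, x)
        R = Rotation.random(random_state=3).as_matrix()
        e1, _ = potential_energy(model, x @ R.T + np.array([1.0, 2.0, 3.0]))
        assert e1 == pytest.approx(e0, abs=1e-9)

    def test_frozen_beads_report_zero_force(self, toy_system):
        sys_ = toy_system
        model = assemble(sys_.pre, sys_.post, sys_.partition, sys_.maps,
                         toggles=TOGGLES["trailing"])
        f = forces(model, sys_.pre.coords)
        np.testing.assert_allclose(f[model.frozen], 0.0)

    def test_nonfinite_coordinates_rejected(self, toy_system):
        sys_ = toy_system
        model = assemble(sys_.pre, sys_.post, sys_.partition, sys_.maps,
                         toggles=TOGGLES["leading"])
        bad = sys_.pre.coords.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            potential_energy(model, bad)
        with pytest.raises(ValueError, match="non-finite"):
            forces(model, bad)


class TestTopologyFile:
    def test_roundtrip_preserves_energies(self, toy_system, tmp_path):
        sys_ = toy_system
        model = assemble(sys_.pre, sys_.post, sys_.partition, sys_.maps,
                         toggles=TOGGLES["powerstroke_with_pi"],
                         pi_subset=sys_.pi_subset, pi_removed=True)
        path = tmp_path / "model.top"
        write_topology(model, path)
        back = read_topology(path)
        assert back.active == model.active
        assert back.pi_removed
        rng = np.random.default_rng(4)
        x = sys_.pre.coords + 0.02 * rng.standard_normal(sys_.pre.coords.shape)
        e0, bd0 = potential_energy(model, x)
        e1, bd1 = potential_energy(back, x)
        assert e1 == pytest.approx(e0, rel=1e-9)
        for tag in bd0:
            assert bd1[tag] == pytest.approx(bd0[tag], rel=1e-9, abs=1e-9)
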