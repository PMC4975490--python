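"""Contact-map extraction against explicit brute-force oracles."""

import numpy as np
import pytest

from gomotor import (ContactMap, exclusive_contacts, interface_contacts,
                     make_toy_ligand, native_contacts, pi_mediated_contacts,
                     remove_contacts, shared_contacts)
from gomotor.structure import CAlphaStructure


def _structure(coords, chains=None):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    return CAlphaStructure(
        coords=coords,
        chain_ids=np.full(n, "A") if chains is None else np.asarray(chains),
        res_numbers=np.arange(1, n + 1),
        res_names=np.full(n, "GLY"))


def brute_force_native(structure, group, cutoff=0.8, min_seq_sep=3):
    """O(N^2) python-loop reference enumeration."""
    group = sorted(int(g) for g in group)
    out = set()
    for ai, i in enumerate(group):
        for j in group[ai + 1:]:
            if j - i <= min_seq_sep:
                continue
            d = np.linalg.norm(structure.coords[i - 1] - structure.coords[j - 1])
            if d < cutoff:
                out.add((i, j))
    return out


class TestNativeContacts:
    def test_extended_chain_has_no_contacts(self):
        coords = np.zeros((12, 3))
        coords[:, 0] = 0.38 * np.arange(12)
        st = _structure(coords)
        assert len(native_contacts(st, np.arange(1, 13))) == 0

    def test_pair_below_cutoff_at_separation_four(self):
        coords = np.array([[0, 0, 0], [1.5, 0, 0], [3.0, 0, 0],
                           [4.5, 0, 0], [0.79, 0, 0]])
        st = _structure(coords)
        cmap = native_contacts(st, np.arange(1, 6))
        assert cmap.pair_set() == {(1, 5)}
        assert cmap.r0[0] == pytest.approx(0.79)

    def test_separation_three_is_excluded(self):
        # strict (j - i) > 3: the same distance at separation 3 yields nothing
        coords = np.array([[0, 0, 0], [1.5, 0, 0], [3.0, 0, 0], [0.79, 0, 0]])
        st = _structure(coords)
        assert len(native_contacts(st, np.arange(1, 5))) == 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_random_cloud(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        coords = rng.normal(scale=0.8, size=(n, 3))
        st = _structure(coords)
        cmap = native_contacts(st, np.arange(1, n + 1))
        assert cmap.pair_set() == brute_force_native(st, np.arange(1, n + 1))

    def test_matches_brute_force_on_toy_motor(self, toy_system):
        mh = toy_system.partition["MH"]
        cmap = toy_system.maps["preMH"]
        assert cmap.pair_set() == brute_force_native(toy_system.pre, mh)

    def test_empty_group_raises(self, toy_system):
        with pytest.raises(ValueError, match="empty"):
            native_contacts(toy_system.pre, np.array([], dtype=int))


class TestInterfaceContacts:
    def test_distant_groups_give_empty_map(self):
        st = _structure([[0, 0, 0], [0.4, 0, 0], [5, 0, 0], [5.4, 0, 0]])
        cmap = interface_contacts(st, np.array([1, 2]), np.array([3, 4]))
        assert len(cmap) == 0

    def test_single_cross_pair(self):
        st = _structure([[0, 0, 0], [10, 0, 0], [20, 0, 0],
                         [30, 0, 0], [40, 0, 0], [0.5, 0, 0]],
                        chains=["A"] * 5 + ["B"])
        cmap = interface_contacts(st, np.arange(1, 6), np.array([6]))
        assert cmap.pair_set() == {(1, 6)}
        assert cmap.r0[0] == pytest.approx(0.5)

    def test_same_chain_pairs_respect_sequence_separation(self):
        # beads 3 and 5 are 0.5 nm apart but only 2 apart in sequence
        st = _structure([[0, 0, 0], [9, 0, 0], [18, 0, 0],
                         [27, 0, 0], [18.5, 0, 0]])
        cmap = interface_contacts(st, np.array([1, 2, 3]), np.array([4, 5]))
        assert len(cmap) == 0
        unfiltered = interface_contacts(st, np.array([1, 2, 3]),
                                        np.array([4, 5]), min_seq_sep=0)
        assert unfiltered.pair_set() == {(3, 5)}

    def test_matches_cross_enumeration_on_toy(self, toy_system):
        part = toy_system.partition
        conv, mh = part["converter"], part["MH"]
        got = toy_system.maps["preConvMH"].pair_set()
        expected = set()
        for i in mh:
            for j in conv:
                if abs(int(j) - int(i)) <= 3:
                    continue
                d = np.linalg.norm(toy_system.pre.coords[i - 1]
                                   - toy_system.pre.coords[j - 1])
                if d < 0.8:
                    expected.add((int(i), int(j)))
        assert got == expected

    def test_overlapping_groups_raise(self, toy_system):
        with pytest.raises(ValueError, match="overlap"):
            interface_contacts(toy_system.pre, np.array([1, 2, 3]),
                               np.array([3, 4, 5]))


class TestExclusiveContacts:
    def test_identical_maps_give_empty_difference(self, toy_system):
        a = toy_system.maps["preConvMH"]
        assert len(exclusive_contacts(a, a)) == 0

    def test_disjoint_maps_return_first_unchanged(self):
        a = ContactMap([1, 2], [5, 7], [0.5, 0.6], "toy")
        b = ContactMap([3], [9], [0.4], "toy")
        assert exclusive_contacts(a, b).pair_set() == a.pair_set()

    def test_set_algebra_partitions_the_union(self, toy_system):
        a = toy_system.maps["preConvMH"]
        b = toy_system.maps["postConvMH"]
        ex_a = exclusive_contacts(a, b).pair_set()
        ex_b = exclusive_contacts(b, a).pair_set()
        sh = shared_contacts(a, b).pair_set()
        assert ex_a and ex_b                      # both docks are non-empty
        assert not (ex_a & ex_b)
        assert not (ex_a & sh) and not (ex_b & sh)
        assert ex_a | ex_b | sh == a.pair_set() | b.pair_set()


class TestPiMediated:
    def _pocket_fixture(self):
        # beads 1, 5, 9 sit near the ligand at the origin; (1, 5) form a
        # native contact; bead 9 coordinates but contacts nothing
        coords = np.array([
            [0.3, 0.0, 0.0],    # 1: coordinating
            [5.0, 0.0, 0.0],
            [10.0, 0.0, 0.0],
            [15.0, 0.0, 0.0],
            [0.0, 0.5, 0.0],    # 5: coordinating, contacts bead 1 (d=0.58)
            [20.0, 0.0, 0.0],
            [25.0, 0.0, 0.0],
            [30.0, 0.0, 0.0],
            [-0.7, 0.0, 0.0],   # 9: coordinating, no contact partner
        ])
        st = CAlphaStructure(
            coords=coords, chain_ids=np.full(9, "A"),
            res_numbers=np.arange(1, 10), res_names=np.full(9, "GLY"),
            ligands=[("PO4", "P", np.zeros(3))])
        return st

    def test_hand_enumerated_pocket(self):
        st = self._pocket_fixture()
        native = native_contacts(st, np.arange(1, 10))
        coord, subset = pi_mediated_contacts(st, native, lig_cutoff=0.8)
        assert set(coord.tolist()) == {1, 5, 9}
        assert subset.pair_set() == {(1, 5)}

    def test_distant_ligand_yields_empty_sets(self):
        st = self._pocket_fixture()
        st.ligands = [("PO4", "P", np.array([100.0, 0, 0]))]
        native = native_contacts(st, np.arange(1, 10))
        coord, subset = pi_mediated_contacts(st, native, lig_cutoff=0.8)
        assert coord.size == 0 and len(subset) == 0

    def test_removal_subset_contained_in_native(self, toy_system):
        assert toy_system.pi_subset.pair_set() <= \
            toy_system.maps["preMH"].pair_set()

    def test_any_mode_is_superset_of_both_mode(self, toy_system):
        lig = make_toy_ligand(toy_system.pre,
                              np.arange(35, 39))
        _, sub_both = pi_mediated_contacts(lig, toy_system.maps["preMH"],
                                           mode="both")
        _, sub_any = pi_mediated_contacts(lig, toy_system.maps["preMH"],
                                          mode="any")
        assert sub_both.pair_set() <= sub_any.pair_set()

    def test_missing_phosphate_raises(self, toy_system):
        with pytest.raises(ValueError, match="phosphate"):
            pi_mediated_contacts(toy_system.pre, toy_system.maps["preMH"])


class TestRemoveContacts:
    def test_empty_subset_is_identity(self, toy_system):
        cmap = toy_system.maps["preMH"]
        empty = ContactMap([], [], [], "Pi")
        assert remove_contacts(cmap, empty).pair_set() == cmap.pair_set()

    def test_full_subset_empties_the_map(self, toy_system):
        cmap = toy_system.maps["preConvMH"]
        assert len(remove_contacts(cmap, cmap)) == 0

    def test_random_subset_matches_set_difference(self, toy_system):
        cmap = toy_system.maps["preMH"]
        rng = np.random.default_rng(3)
        keep = rng.random(len(cmap)) < 0.3
        subset = ContactMap(cmap.i[keep], cmap.j[keep], cmap.r0[keep], "Pi")
        out = remove_contacts(cmap, subset)
        assert out.pair_set() == cmap.pair_set() - subset.pair_set()
        assert len(out) == len(cmap) - len(subset)

    def test_foreign_subset_entry_raises(self, toy_system):
        subset = ContactMap([1], [39], [0.5], "Pi")
        if (1, 39) in toy_system.maps["preMH"].pair_set():
            pytest.skip("pair unexpectedly native")
        with pytest.raises(ValueError, match="absent"):
            remove_contacts(toy_system.maps["preMH"], subset)


class TestContactMapType:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="i < j"):
            ContactMap([5], [2], [0.5], "toy")
        with pytest.raises(ValueError, match="below the cutoff"):
            ContactMap([1], [5], [0.9], "toy", cutoff=0.8)
        with pytest.raises(ValueError, match="duplicate"):
            ContactMap([1, 1], [5, 5], [0.5, 0.5], "toy")

    def test_tsv_roundtrip(self, toy_system, tmp_path):
        cmap = toy_system.maps["preConvMH"]
        path = tmp_path / "contacts.tsv"
        cmap.to_tsv(path)
        back = ContactMap.from_tsv(path)
        assert back.pair_set() == cmap.pair_set()
        np.testing.assert_allclose(np.sort(back.r0), np.sort(cmap.r0))
        assert back.tag == cmap.tag

    def test_dense_export_is_symmetric(self, toy_system):
        cmap = toy_system.maps["preMH"]
        dense = cmap.dense(toy_system.pre.n_beads)
        assert dense.sum() == 2 * len(cmap)
        assert (dense == dense.T).all()
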