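"""Fibril monomer extraction, native contacts, and polymorph clustering."""

import numpy as np
import pytest

from fibrilmod.contacts import compute_contact_map
from fibrilmod.errors import EmptyStructureError
from fibrilmod.fibrils import (
    NativeContactSet,
    cluster_fibrils,
    extract_native_contacts,
    load_fibril_structure,
    read_contacts_tsv,
    write_contacts_tsv,
)
from fibrilmod.synthetic import FibrilDesign, generate_fibril_structure
from conftest import make_ensemble


def _write_stack_pdb(path, coords_nm, n_chains=1, z_offset_nm=0.48):
    """CA-trace PDB with identical chains stacked along z (coords in nm)."""
    lines = []
    serial = 1
    for c in range(n_chains):
        chain_id = chr(ord("A") + c)
        for i, xyz in enumerate(coords_nm, 1):
            x, y, z = (xyz + np.array([0, 0, c * z_offset_nm])) * 10.0
            lines.append(
                f"ATOM  {serial:5d}  CA  GLY {chain_id}{i:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
            serial += 1
        lines.append("TER")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


@pytest.fixture
def folded_coords(rng):
    """A small chain with a designed long-range contact."""
    st = generate_fibril_structure(
        FibrilDesign("fx", contacts=[(2, 9)], n_residues=12), seed=11
    )
    return st.coords


class TestLoadFibrilStructure:
    def test_central_and_first_agree_for_identical_chains(self, tmp_path, folded_coords):
        p = tmp_path / "stack.pdb"
        _write_stack_pdb(p, folded_coords, n_chains=2)
        central = load_fibril_structure(p, chain_policy="central")
        first = load_fibril_structure(p, chain_policy="first")
        a = extract_native_contacts(central)
        b = extract_native_contacts(first)
        assert a.contacts == b.contacts

    def test_pdb_and_mmcif_renderings_agree(self, tmp_path, folded_coords):
        import gemmi

        p = tmp_path / "mono.pdb"
        _write_stack_pdb(p, folded_coords, n_chains=1)
        st = gemmi.read_structure(str(p))
        st.setup_entities()
        cif = tmp_path / "mono.cif"
        st.make_mmcif_document().write_file(str(cif))
        from_pdb = extract_native_contacts(load_fibril_structure(p))
        from_cif = extract_native_contacts(load_fibril_structure(cif))
        assert from_pdb.contacts == from_cif.contacts

    def test_absent_explicit_chain_raises(self, tmp_path, folded_coords):
        p = tmp_path / "one.pdb"
        _write_stack_pdb(p, folded_coords)
        with pytest.raises(EmptyStructureError):
            load_fibril_structure(p, chain_policy="Z")

    def test_renumber_offset_applied(self, tmp_path, folded_coords):
        p = tmp_path / "off.pdb"
        _write_stack_pdb(p, folded_coords)
        st = load_fibril_structure(p, renumber_offset=243)
        assert st.residue_numbers[0] == 244
        assert st.resolved_range == (244, 243 + len(folded_coords))


class TestExtractNativeContacts:
    def test_extended_chain_has_no_contacts(self):
        n = 12
        coords = np.zeros((n, 3))
        coords[:, 0] = np.arange(n) * 0.38
        st = generate_fibril_structure(FibrilDesign("ext", contacts=[], n_residues=n),
                                       seed=0)
        st.coords = coords
        assert extract_native_contacts(st).contacts == frozenset()

    def test_side_chain_atoms_decide_contact(self, tmp_path):
        # backbone beads 0.48 nm apart but extra atoms at 0.40 nm: contact present
        lines = []
        serial = 1
        for i in range(1, 9):
            x = 0.0 if i <= 4 else 0.48
            y = (i - 1 if i <= 4 else 8 - i) * 0.38
            for name, dx in (("CA", 0.0), ("CB", 0.04 if i <= 4 else -0.04)):
                lines.append(
                    f"ATOM  {serial:5d}  {name:<3s} GLY A{i:4d}    "
                    f"{(x + dx) * 10:8.3f}{y * 10:8.3f}{0.0:8.3f}  1.00  0.00           C"
                )
                serial += 1
        (tmp_path / "hp.pdb").write_text("\n".join(lines) + "\nEND\n")
        st = load_fibril_structure(tmp_path / "hp.pdb")
        contacts = extract_native_contacts(st).contacts
        # cross-strand CB-CB distance 0.40 < 0.45 for aligned rungs
        assert any(j - i >= 4 for i, j in contacts)
        assert (1, 8) in contacts

    def test_agrees_with_contact_map_on_single_frame(self, folded_coords):
        st = generate_fibril_structure(
            FibrilDesign("ag", contacts=[(2, 9), (3, 12)], n_residues=14), seed=3
        )
        ncs = extract_native_contacts(st)
        ens = make_ensemble(st.coords[None, :, :], [1] * st.n_residues)
        cmap = compute_contact_map(ens)
        assert ncs.contacts == frozenset(p for p, v in cmap.pairs.items() if v > 0)


class TestClustering:
    @staticmethod
    def _ncs(sid, pairs):
        return NativeContactSet(sid, frozenset(pairs))

    def test_identical_sets_form_one_cluster(self):
        a = self._ncs("a", {(1, 5), (2, 8)})
        b = self._ncs("b", {(1, 5), (2, 8)})
        clustering = cluster_fibrils([a, b])
        assert clustering.clusters == [["a", "b"]]

    def test_disjoint_sets_are_singletons(self):
        sets = [self._ncs(s, {(i, i + 5)}) for s, i in zip("abc", (1, 10, 20))]
        with pytest.warns(UserWarning):
            clustering = cluster_fibrils(sets)
        assert clustering.n_clusters == 3

    def test_block_design_recovered(self):
        shared_abc = {(1, 10), (2, 12)}
        shared_de = {(20, 30)}
        sets = [
            self._ncs("A", shared_abc | {(40, 50)}),
            self._ncs("B", shared_abc),
            self._ncs("C", {(2, 12), (60, 70)}),
            self._ncs("D", shared_de | {(41, 51)}),
            self._ncs("E", shared_de),
            self._ncs("F", {(80, 90)}),
            self._ncs("G", {(81, 91)}),
            self._ncs("H", {(82, 92)}),
            self._ncs("I", {(83, 93)}),
        ]
        clustering = cluster_fibrils(sets)
        assert sorted(map(sorted, clustering.clusters)) == [
            ["A", "B", "C"], ["D", "E"], ["F"], ["G"], ["H"], ["I"],
        ]

    def test_order_and_relabel_invariance(self, rng):
        sets = [
            self._ncs("s1", {(1, 10), (2, 12)}),
            self._ncs("s2", {(1, 10)}),
            self._ncs("s3", {(50, 60)}),
        ]
        ref = {frozenset(c) for c in cluster_fibrils(sets).clusters}
        for _ in range(5):
            perm = list(rng.permutation(len(sets)))
            got = {frozenset(c) for c in cluster_fibrils([sets[i] for i in perm]).clusters}
            assert got == ref

    def test_raising_min_shared_never_merges(self):
        sets = [
            self._ncs("a", {(1, 10), (2, 12), (3, 14)}),
            self._ncs("b", {(1, 10), (2, 12)}),
            self._ncs("c", {(1, 10)}),
        ]
        n_prev = cluster_fibrils(sets, min_shared=1).n_clusters
        for ms in (2, 3, 4):
            n = cluster_fibrils(sets, min_shared=ms).n_clusters
            assert n >= n_prev
            n_prev = n

    def test_contacts_tsv_round_trip(self, tmp_path):
        ncs = self._ncs("rt", {(1, 10), (5, 20)})
        write_contacts_tsv(ncs, tmp_path / "c.tsv")
        back = read_contacts_tsv(tmp_path / "c.tsv")
        assert back.contacts == ncs.contacts and back.structure_id == "rt"
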