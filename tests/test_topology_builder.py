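"""Bond graph, enumeration, native geometry, coarse-graining and assembly."""

import itertools
import math

import numpy as np
import pytest

from gosbm.contacts import cutoff_contact_map, map_contacts_to_cg
from gosbm.structure_io import make_fixture
from gosbm.topology_builder import (
    BondGraph,
    EdgeProvenance,
    TopologyError,
    assemble_topology,
    build_bond_graph,
    coarse_grain,
    enumerate_angles,
    enumerate_dihedrals,
    measure_dihedral,
    measure_geometry,
    normalize_energies,
)


def _random_graph(rng, n_atoms, p=0.35):
    g = BondGraph(n_atoms)
    for i in range(n_atoms):
        for j in range(i + 1, n_atoms):
            if rng.random() < p:
                g.add_edge(i, j, EdgeProvenance.RESIDUE_INTERNAL)
    return g


class TestBondGraph:
    def test_ca_chain_has_n_minus_1_inter_residue_edges(self, ca_templates):
        st = make_fixture("ca_helix", 10)
        g = build_bond_graph(st, ca_templates)
        assert len(g.edges) == 9
        assert all(
            g.provenance[e] is EdgeProvenance.INTER_RESIDUE for e in g.edges
        )

    def test_two_chains_give_two_components(self, ca_templates):
        st = make_fixture("two_chain", 10)
        g = build_bond_graph(st, ca_templates)
        assert g.n_components() == 2

    def test_aa_fixture_edges_match_template_blueprint(self, aa_templates):
        """Edge set equals the per-residue bonds plus C-N peptide links."""
        st = make_fixture("aa_peptide", 3)
        g = build_bond_graph(st, aa_templates)
        residues = st.residues()
        name_to_idx = [
            {st.atoms[ai].name: ai for ai in r.atom_indices} for r in residues
        ]
        expected = set()
        for ri, res in enumerate(residues):
            rdef = aa_templates.residues[res.residue_name]
            for a1, a2 in rdef.internal_bonds:
                i, j = name_to_idx[ri][a1], name_to_idx[ri][a2]
                expected.add((min(i, j), max(i, j)))
        for ri in range(len(residues) - 1):
            i, j = name_to_idx[ri]["C"], name_to_idx[ri + 1]["N"]
            expected.add((min(i, j), max(i, j)))
        assert set(g.edges) == expected

    def test_missing_declared_bond_atom_is_an_error(self, aa_templates):
        st = make_fixture("aa_peptide", 2)
        st.atoms = [a for a in st.atoms if not (a.residue_seq == 1 and a.name == "CB")]
        with pytest.raises(TopologyError, match="CB"):
            build_bond_graph(st, aa_templates)

    def test_numbering_gap_with_distant_connect_atoms_breaks_chain(self, ca_templates):
        st = make_fixture("two_chain", 10)
        # fold both chains into one PDB chain with a numbering gap
        n1 = st.chain_breaks[0]
        for k, a in enumerate(st.atoms):
            a.chain_id = "A"
            a.residue_seq = k + 1 if k < n1 else k + 10
        st.chain_breaks = []
        g = build_bond_graph(st, ca_templates)
        assert g.n_components() == 2


class TestEnumeration:
    def test_linear_chain_counts(self):
        g = BondGraph(4)
        for i in range(3):
            g.add_edge(i, i + 1, EdgeProvenance.RESIDUE_INTERNAL)
        assert enumerate_angles(g) == [(0, 1, 2), (1, 2, 3)]
        assert enumerate_dihedrals(g) == [(0, 1, 2, 3)]

    def test_single_bond_and_star(self):
        g = BondGraph(2)
        g.add_edge(0, 1, EdgeProvenance.RESIDUE_INTERNAL)
        assert enumerate_angles(g) == []
        assert enumerate_dihedrals(g) == []
        star = BondGraph(4)
        for leaf in (1, 2, 3):
            star.add_edge(0, leaf, EdgeProvenance.RESIDUE_INTERNAL)
        assert len(enumerate_angles(star)) == 3
        assert enumerate_dihedrals(star) == []

    def test_random_graphs_match_brute_force(self, rng):
        """Exhaustive path enumeration oracle on 200 random graphs <= 8 atoms."""
        for _ in range(200):
            n = int(rng.integers(2, 9))
            g = _random_graph(rng, n)
            adj = g.adjacency
            brute_angles = {
                (i, j, k)
                for i, j, k in itertools.permutations(range(n), 3)
                if i < k and j in adj[i] and j in adj[k] and i in adj[j]
            }
            brute_dihedrals = set()
            for i, j, k, l in itertools.permutations(range(n), 4):
                if i < l and j in adj[i] and k in adj[j] and l in adj[k]:
                    brute_dihedrals.add((i, j, k, l))
            assert set(enumerate_angles(g)) == brute_angles
            assert set(enumerate_dihedrals(g)) == brute_dihedrals


class TestMeasureGeometry:
    def test_distance(self):
        st = make_fixture("dimer")
        assert measure_geometry(st, (0, 1)) == pytest.approx(0.38, abs=1e-12)

    def test_collinear_triple_is_pi(self):
        from gosbm.structure_io import Structure, Atom

        atoms = [
            Atom(i + 1, "CA", "GLY", i + 1, "A", np.array([0.38 * i, 0.0, 0.0]))
            for i in range(3)
        ]
        st = Structure(atoms=atoms)
        assert measure_geometry(st, (0, 1, 2)) == pytest.approx(math.pi)

    def test_planar_four_trans_is_pi_and_mirror_is_zero(self):
        st = make_fixture("planar_four")
        assert abs(measure_geometry(st, (0, 1, 2, 3))) == pytest.approx(math.pi)
        cis = st.copy()
        # reflect the last atom across the central-bond line -> cis, dihedral 0
        cis.atoms[3].position = np.array([0.3, 0.6, 0.0])
        assert measure_geometry(cis, (0, 1, 2, 3)) == pytest.approx(0.0, abs=1e-12)

    def test_dihedral_matches_independent_implementation(self, rng):
        """Cross-check the atan2 dihedral against mdtraj's implementation."""
        import mdtraj
        from mdtraj.core import topology as mdtop

        xyz = rng.standard_normal((20, 4, 3))
        top = mdtop.Topology()
        chain = top.add_chain()
        res = top.add_residue("GLY", chain)
        for i in range(4):
            top.add_atom(f"C{i}", mdtraj.core.element.carbon, res)
        traj = mdtraj.Trajectory(xyz.astype(np.float32), top)
        ref = mdtraj.compute_dihedrals(traj, [[0, 1, 2, 3]], periodic=False)[:, 0]
        ours = np.array([measure_dihedral(frame, 0, 1, 2, 3) for frame in xyz])
        # both use the right-handed IUPAC convention
        delta = np.abs(np.arctan2(np.sin(ours - ref), np.cos(ours - ref)))
        assert delta.max() < 1e-5

    def test_degenerate_dihedral_raises(self):
        xyz = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        with pytest.raises(TopologyError, match="collinear"):
            measure_dihedral(xyz, 0, 1, 2, 3)


class TestCoarseGrain:
    def test_ci2_scale_structure_maps_to_one_bead_per_residue(self, ca_templates):
        st = make_fixture("synthetic_ci2")
        cg = coarse_grain(st, ca_templates)
        assert cg.structure.n_atoms == 64
        assert all(a.name == "CA" for a in cg.structure.atoms)
        # bead positions equal the input CA positions exactly
        ca_pos = np.array([a.position for a in st.atoms if a.name == "CA"])
        np.testing.assert_array_equal(cg.structure.coords(), ca_pos)
        assert [st.atoms[i].name for i in cg.kept_atom_index] == ["CA"] * 64

    def test_already_cg_input_is_identity(self, ca_templates):
        st = make_fixture("ca_helix", 7)
        cg = coarse_grain(st, ca_templates)
        np.testing.assert_array_equal(cg.structure.coords(), st.coords())
        assert cg.structure.n_atoms == st.n_atoms

    def test_missing_designated_atom_is_an_error(self, ca_templates):
        st = make_fixture("aa_peptide", 3)
        st.atoms = [a for a in st.atoms if not (a.residue_seq == 2 and a.name == "CA")]
        with pytest.raises(TopologyError, match="CA"):
            coarse_grain(st, ca_templates)


class TestAssemble:
    def test_helix_bonds_carry_wildcard_rule_parameters(self, helix_topology):
        assert len(helix_topology.bonds) == 9
        for b in helix_topology.bonds:
            assert b.eps == 20000.0
            assert b.r0 == pytest.approx(0.38, abs=1e-9)

    def test_unbranched_chain_counts(self, helix_topology):
        n = helix_topology.n_atoms
        assert len(helix_topology.angles) == n - 2
        assert len(helix_topology.dihedrals) == n - 3

    def test_zero_contacts_is_valid(self, ca_templates):
        st = make_fixture("ca_helix", 5)
        top = assemble_topology(st, ca_templates, None)
        assert top.contacts == []
        top.validate()

    def test_exclusion_invariants(self, ci2_cg):
        top = ci2_cg["topology"]
        contact_pairs = {(c.i, c.j) for c in top.contacts}
        assert contact_pairs <= top.exclusions
        bonded = {(min(b.i, b.j), max(b.i, b.j)) for b in top.bonds}
        assert bonded <= top.exclusions
        assert not (contact_pairs & bonded)
        # depth-3 neighbours along the chain are excluded
        for i in range(top.n_atoms - 3):
            assert (i, i + 2) in top.exclusions
            assert (i, i + 3) in top.exclusions
            if i + 4 < top.n_atoms:
                assert (i, i + 4) not in top.exclusions or (i, i + 4) in contact_pairs

    def test_two_path_coarse_graining_equivalence(self, ca_templates, tmp_path):
        """CG-then-assemble equals assembly on a pre-coarse-grained input.

        Path A coarse-grains in memory; path B round-trips the CG structure
        through a PDB file (as a user supplying an already-CG input would)
        and assembles that.  Parameters agree to PDB coordinate precision.
        """
        from gosbm.structure_io import read_pdb, write_pdb

        st = make_fixture("synthetic_ci2")
        cg = coarse_grain(st, ca_templates)
        atomic = cutoff_contact_map(st)
        cmap = map_contacts_to_cg(atomic, st, cg.structure)
        top_a = assemble_topology(cg.structure, ca_templates, cmap)

        write_pdb(cg.structure, tmp_path / "cg.pdb")
        pre_cg = read_pdb(tmp_path / "cg.pdb")
        cg_b = coarse_grain(pre_cg, ca_templates)  # identity on CG input
        cmap_b = map_contacts_to_cg(atomic, st, cg_b.structure)
        top_b = assemble_topology(cg_b.structure, ca_templates, cmap_b)

        assert [(b.i, b.j) for b in top_a.bonds] == [(b.i, b.j) for b in top_b.bonds]
        assert [(c.i, c.j) for c in top_a.contacts] == [
            (c.i, c.j) for c in top_b.contacts
        ]
        np.testing.assert_allclose(
            [b.r0 for b in top_a.bonds], [b.r0 for b in top_b.bonds], atol=2e-4
        )
        np.testing.assert_allclose(
            [c.r0 for c in top_a.contacts], [c.r0 for c in top_b.contacts], atol=2e-4
        )

    def test_enm_template_has_no_angles_or_dihedrals(self, enm_templates):
        st = make_fixture("aa_peptide", 4)
        contacts = cutoff_contact_map(st)
        top = assemble_topology(st, enm_templates, contacts)
        assert top.angles == [] and top.dihedrals == []
        assert all(c.form.value == "harmonic" for c in top.contacts)

    def test_normalize_energies_hits_ratio_and_total(self, ci2_cg):
        top = normalize_energies(
            ci2_cg["topology"], contact_dihedral_ratio=2.0,
            total_stabilizing_energy=64.0,
        )
        s_c = sum(c.eps for c in top.contacts)
        s_d = sum(d.eps for d in top.dihedrals)
        assert s_c / s_d == pytest.approx(2.0)
        assert s_c + s_d == pytest.approx(64.0)
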