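import numpy as np
import pytest

from boxcc import (ClashError, PerturbationSpec, generate_structure,
                   per_residue_bcc, perturb_structure, simulate_observed_map)
from boxcc.synthetic import add_ligand_pocket, generate_bundle
from boxcc.templates import TEMPLATES


class TestGenerateStructure:
    def test_single_alanine_composition(self):
        st = generate_structure(1, composition=("ALA",), seed=0)
        assert st.n_atoms == 5                       # N, CA, C, O, CB
        assert {a.name for a in st.atoms()} == {"N", "CA", "C", "O", "CB"}
        assert st.spacegroup == "P 1"
        # padded cell: every atom at least ~padding away from the walls
        pts = st.coords()
        assert pts.min() >= 5.9
        edges = np.array([st.cell.a, st.cell.b, st.cell.c])
        assert np.all(edges - pts.max(axis=0) >= 5.9)

    def test_seed_determinism_bitwise(self):
        a = generate_structure(8, seed=11)
        b = generate_structure(8, seed=11)
        assert np.array_equal(a.coords(), b.coords())
        assert [r.name for r in a.residues] == [r.name for r in b.residues]
        c = generate_structure(8, seed=12)
        assert not np.array_equal(a.coords(), c.coords())

    def test_backbone_geometry_of_long_chain(self):
        st = generate_structure(20, seed=1)
        ca = [r.find_atom("CA").pos for r in st.residues]
        d = np.linalg.norm(np.diff(np.array(ca), axis=0), axis=1)
        assert np.all((d > 3.3) & (d < 4.3))         # consecutive CA-CA ~ 3.8 A
        # covalent backbone bonds within template range
        for r in st.residues:
            n, caa, cc = (r.find_atom(x).pos for x in ("N", "CA", "C"))
            assert 1.3 < np.linalg.norm(caa - n) < 1.6
            assert 1.3 < np.linalg.norm(cc - caa) < 1.6

    def test_no_nonbonded_clashes(self):
        st = generate_structure(15, seed=5)
        pts = st.coords()
        from scipy.spatial import cKDTree
        pairs = cKDTree(pts).query_pairs(1.0)
        atom_res = [i for i, r in enumerate(st.residues) for _ in r.atoms]
        assert all(abs(atom_res[i] - atom_res[j]) < 2 for i, j in pairs)

    def test_templates_ship_required_types(self):
        required = {"GLY", "ALA", "SER", "VAL", "LEU", "PHE", "LYS", "MET"}
        assert required <= set(TEMPLATES)
        assert len(TEMPLATES) >= 8

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            generate_structure(0)
        with pytest.raises(ValueError):
            generate_structure(3, composition=("XXX",))


class TestPerturb:
    def test_zero_magnitude_is_identity(self, small_structure):
        out = perturb_structure(small_structure, PerturbationSpec("jitter", 0.0, seed=1))
        assert np.array_equal(out.coords(), small_structure.coords())

    def test_jitter_rmsd_within_20_percent(self, small_structure):
        spec = PerturbationSpec("jitter", 1.0, seed=3)
        out = perturb_structure(small_structure, spec)
        rmsd = np.sqrt(np.mean(np.sum((out.coords() - small_structure.coords()) ** 2, axis=1)))
        assert 0.8 <= rmsd <= 1.2

    def test_sidechain_rotate_keeps_backbone(self, small_structure):
        out = perturb_structure(small_structure,
                                PerturbationSpec("sidechain_rotate", 45.0, seed=2))
        bb = ("N", "CA", "C", "O", "CB")
        for r0, r1 in zip(small_structure.residues, out.residues):
            for a0, a1 in zip(r0.atoms, r1.atoms):
                if a0.name in bb:
                    assert np.array_equal(a0.pos, a1.pos)

    def test_residue_range_targets_only(self, small_structure):
        spec = PerturbationSpec("segment_shift", 2.0, residue_range=(2, 3), seed=4)
        out = perturb_structure(small_structure, spec)
        for r0, r1 in zip(small_structure.residues, out.residues):
            moved = not np.array_equal(r0.atoms[0].pos, r1.atoms[0].pos)
            assert moved == (2 <= r0.seqnum <= 3)

    def test_empty_range_and_bad_mode(self, small_structure):
        with pytest.raises(ValueError):
            perturb_structure(small_structure,
                              PerturbationSpec("jitter", 1.0, residue_range=(99, 120)))
        with pytest.raises(ValueError):
            PerturbationSpec("warp", 1.0)


class TestSimulateObservedMap:
    def test_seed_determinism(self, small_structure):
        a = simulate_observed_map(small_structure, 2.5, seed=3)
        b = simulate_observed_map(small_structure, 2.5, seed=3)
        assert np.array_equal(a.values, b.values)
        assert "seed=3" in a.label

    def test_noiseless_fine_map_matches_direct_synthesis(self, small_structure):
        """With no noise and fine d_min the simulated map correlates > 0.99
        with direct real-space synthesis at the same per-atom B."""
        from boxcc.density import suggest_grid, synthesize_map
        from boxcc.synthetic import BFactorProfile
        prof = BFactorProfile(base=15.0, exposure_scale=25.0)
        bstruct = prof.assign(small_structure)
        dims = suggest_grid(small_structure.cell, 0.4)
        sim = simulate_observed_map(small_structure, 0.9, noise_sigma=0.0,
                                    b_profile=prof, grid_dims=dims)
        direct = synthesize_map(bstruct, dims)
        corr = np.corrcoef(sim.values.ravel(), direct.values.ravel())[0, 1]
        assert corr > 0.99

    def test_truth_scores_lower_against_lower_resolution(self, small_structure):
        """Per-residue bCC of the true coordinates is systematically lower
        against a 4.0 A map than against a 1.5 A map."""
        hi = simulate_observed_map(small_structure, 1.5, seed=6)
        lo = simulate_observed_map(small_structure, 4.0, seed=6)
        bhi = per_residue_bcc(small_structure, hi).bcc
        blo = per_residue_bcc(small_structure, lo).bcc
        assert blo.mean() < bhi.mean()


class TestLigandPocket:
    def test_atom_count_and_geometry(self, small_structure):
        from boxcc.boxes import residue_centroid
        bound = add_ligand_pocket(small_structure, seed=7)
        assert bound.n_atoms - small_structure.n_atoms == 26
        lig = bound.residues[-1]
        assert lig.het and lig.name == "LIG"
        pocket = small_structure.residues[len(small_structure.residues) // 2]
        c = residue_centroid(pocket)
        for a in lig.atoms:
            assert np.all(np.abs(a.pos - c) <= 6.0)   # inside the 12 A box
        # clash-free vs protein
        prot = small_structure.coords(heavy_only=True)
        for a in lig.atoms:
            assert np.linalg.norm(prot - a.pos, axis=1).min() >= 2.5

    def test_custom_composition_and_determinism(self, small_structure):
        spec = {"C": 4, "O": 2}
        b1 = add_ligand_pocket(small_structure, ligand_atom_spec=spec, seed=3)
        b2 = add_ligand_pocket(small_structure, ligand_atom_spec=spec, seed=3)
        lig = b1.residues[-1]
        assert sorted(a.element for a in lig.atoms) == ["C"] * 4 + ["O"] * 2
        assert np.array_equal(b1.coords(), b2.coords())


def test_bundle_is_denser_than_single_helix():
    from boxcc.boxes import residue_centroid
    bundle = generate_bundle(10, 3, seed=21)
    single = generate_structure(10, seed=21)
    def atoms_in_box(st, res):
        c = residue_centroid(res)
        pts = st.coords(heavy_only=True)
        return int(np.sum(np.all(np.abs(pts - c) <= 6.0, axis=1)))
    mid_b = [r for r in bundle.residues if r.chain == "A"][5]
    mid_s = single.residues[5]
    assert atoms_in_box(bundle, mid_b) > 1.25 * atoms_in_box(single, mid_s)
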