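import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from boxcc import (Atom, CellMismatchError, DegenerateBoxError, DensityMap,
                   NoLigandError, Residue, Structure, UnitCell, bcc,
                   extract_box, ligand_delta_bcc, per_residue_bcc,
                   residue_centroid, rotate_voxels, rscc,
                   single_atom_contribution, synthesize_map)
from boxcc.density import suggest_grid
from boxcc.metrics import calculated_map
from boxcc.synthetic import add_ligand_pocket, simulate_observed_map


def _pearson_bruteforce(x, y):
    x = x.ravel()
    y = y.ravel()
    mx, my = x.mean(), y.mean()
    num = ((x - mx) * (y - my)).sum()
    den = np.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())
    return num / den


class TestBcc:
    def test_self_correlation_is_one(self, rng):
        b = rng.normal(size=(24, 24, 24))
        assert bcc(b, b) == pytest.approx(1.0, abs=1e-14)

    def test_matches_bruteforce_on_random_pairs(self, rng):
        for _ in range(20):
            a = rng.normal(size=(24, 24, 24))
            b = rng.normal(size=(24, 24, 24))
            assert bcc(a, b) == pytest.approx(_pearson_bruteforce(a, b), rel=1e-12)

    def test_hand_enumerable_2x2x2(self):
        a = np.arange(8.0).reshape(2, 2, 2)
        b = np.array([1.0, 0.0, 2.0, 1.5, 3.0, 2.0, 4.0, 5.0]).reshape(2, 2, 2)
        assert bcc(a, b) == pytest.approx(_pearson_bruteforce(a, b), rel=1e-14)

    @settings(max_examples=25, derandomize=True)
    @given(scale=st.floats(0.01, 100), shift=st.floats(-10, 10))
    def test_affine_invariance(self, scale, shift):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(6, 6, 6))
        b = rng.normal(size=(6, 6, 6))
        assert bcc(a * scale + shift, b) == pytest.approx(bcc(a, b), rel=1e-9)

    def test_joint_rotation_invariance(self, rng):
        a = rng.normal(size=(8, 8, 8))
        b = rng.normal(size=(8, 8, 8))
        ref = bcc(a, b)
        for k in range(24):
            assert bcc(rotate_voxels(a, k), rotate_voxels(b, k)) == pytest.approx(ref, rel=1e-12)

    def test_degenerate_boxes_raise(self, rng):
        flat = np.zeros((4, 4, 4))
        other = rng.normal(size=(4, 4, 4))
        with pytest.raises(DegenerateBoxError):
            bcc(flat, other)
        with pytest.raises(DegenerateBoxError):
            bcc(other, np.full((4, 4, 4), 3.3))
        with pytest.raises(ValueError):
            bcc(other, rng.normal(size=(5, 5, 5)))


class TestPerResidueBcc:
    def test_self_consistency(self, small_structure, selfconsistent_map):
        """Against a map synthesized with the same B=2 policy every residue
        scores >= 0.99."""
        df = per_residue_bcc(small_structure, selfconsistent_map)
        assert len(df) == len(small_structure.residues)
        assert df.bcc.min() >= 0.99
        assert (df.flag == "").all()

    def test_degradation_with_perturbation(self, small_structure, obs_map):
        from boxcc import PerturbationSpec, perturb_structure
        base = per_residue_bcc(small_structure, obs_map).bcc.mean()
        worse = per_residue_bcc(
            perturb_structure(small_structure, PerturbationSpec("jitter", 1.0, seed=4)),
            obs_map).bcc.mean()
        assert worse < base

    def test_cell_mismatch_rejected(self, small_structure, obs_map):
        other = Structure(UnitCell(11, 11, 11), small_structure.residues)
        with pytest.raises(CellMismatchError):
            per_residue_bcc(other, obs_map)


class TestRscc:
    def test_perfect_model_scores_one_and_mask_oracle(self, small_structure,
                                                      selfconsistent_map):
        obs = selfconsistent_map
        calc = DensityMap(obs.cell, obs.values.copy(), label="calculated")
        res = small_structure.residues[2]
        assert rscc(small_structure, obs, calc, res) == pytest.approx(1.0)

        # brute-force masked Pearson over explicitly enumerated grid points
        noisy = DensityMap(obs.cell, obs.values
                           + np.random.default_rng(1).normal(0, 0.05, obs.shape))
        score = rscc(small_structure, noisy, calc, res, mask_radius=1.5)
        n = np.array(obs.shape)
        idx = np.indices(obs.shape).reshape(3, -1).T
        pts = obs.cell.orthogonalize(idx / n)
        heavy = np.array([a.pos for a in res.heavy_atoms()])
        # periodic minimum-image distance in this orthorhombic cell
        edges = np.array([obs.cell.a, obs.cell.b, obs.cell.c])
        d = np.full(len(pts), np.inf)
        for h in heavy:
            diff = np.abs(pts - h)
            diff = np.minimum(diff, edges - diff)
            d = np.minimum(d, np.sqrt((diff ** 2).sum(1)))
        mask = (d <= 1.5).reshape(obs.shape)
        expected = _pearson_bruteforce(noisy.values[mask], calc.values[mask])
        assert score == pytest.approx(expected, rel=1e-9)

    @pytest.mark.filterwarnings("ignore:grid spacing")
    def test_rscc_stays_high_when_only_surroundings_are_wrong(self):
        """A residue that still fits its own density keeps a high RSCC even
        when its neighbors are misplaced, while its bCC (which sees the
        whole box) drops much further."""
        from boxcc import PerturbationSpec, generate_structure, perturb_structure
        truth = generate_structure(8, seed=33)
        obs = simulate_observed_map(truth, 1.8, seed=2)
        # damage every residue except number 4
        bad = perturb_structure(truth, PerturbationSpec("jitter", 1.5, seed=5,
                                                        residue_range=(1, 3)))
        bad = perturb_structure(bad, PerturbationSpec("jitter", 1.5, seed=6,
                                                      residue_range=(5, 8)))
        dims = obs.shape
        calc_truth = synthesize_map(truth, dims, b_override=15.0)
        calc_bad = synthesize_map(bad, dims, b_override=15.0)
        r_truth = rscc(truth, obs, calc_truth, truth.residues[3])
        r_bad = rscc(bad, obs, calc_bad, bad.residues[3])
        b_truth = per_residue_bcc(truth, obs).bcc[3]
        b_bad = per_residue_bcc(bad, obs).bcc[3]
        assert r_bad > 0.75                      # own footprint still fits
        assert b_truth - b_bad > r_truth - r_bad  # bCC penalizes the box more

    def test_grid_mismatch_rejected(self, small_structure, selfconsistent_map):
        other = DensityMap(selfconsistent_map.cell, np.ones((10, 10, 10)))
        with pytest.raises(ValueError):
            rscc(small_structure, selfconsistent_map, other, small_structure.residues[0])


@pytest.fixture(scope="module")
def with_water():
    """Packed helix bundle (protein-interior atom density) with one
    water oxygen near a buried residue's centroid."""
    from boxcc.synthetic import (add_water_near, generate_bundle,
                                 most_buried_residue)
    st = generate_bundle(10, 4, seed=21)
    res = most_buried_residue(st, seqnum_window=(4, 7))
    stw = add_water_near(st, res, max_offset=1.2, seed=0)
    obs = simulate_observed_map(stw, 1.8, seed=9)
    resw = stw.get_residue(res.chain, res.seqnum)
    return stw, obs, resw


class TestSingleAtomContribution:
    def test_water_oxygen_under_one_percent(self, with_water):
        """One oxygen inside a 12 A protein-environment box changes bCC by
        less than 1%."""
        stw, obs, res = with_water
        key = ("S", stw.residues[-1].seqnum, "O")
        frac = single_atom_contribution(stw, obs, res, key)
        assert 0.0 < frac < 0.01

    def test_contribution_grows_as_box_shrinks(self, with_water):
        stw, obs, res = with_water
        key = ("S", stw.residues[-1].seqnum, "O")
        fracs = [single_atom_contribution(stw, obs, res, key, edge=e)
                 for e in (12.0, 8.0, 4.0)]
        assert fracs[0] < fracs[1] < fracs[2]

    def test_atom_outside_box_warns_and_returns_zero(self, with_water):
        stw, obs, res = with_water
        far = stw.copy()
        far.residues[-1].atoms[0].pos = residue_centroid(res) + 20.0
        key = ("S", stw.residues[-1].seqnum, "O")
        with pytest.warns(UserWarning, match="outside"):
            out = single_atom_contribution(far, obs, far.get_residue(res.chain, res.seqnum), key)
        assert out == 0.0


class TestLigandDelta:
    def test_no_ligand_raises(self, small_structure, obs_map):
        with pytest.raises(NoLigandError):
            ligand_delta_bcc(small_structure, small_structure, obs_map)

    def test_bound_truth_gives_positive_delta(self, small_structure):
        """When the observed map is simulated from the bound truth, every
        contact residue prefers the bound model."""
        bound = add_ligand_pocket(small_structure, seed=11)
        obs = simulate_observed_map(bound, 1.8, seed=12)
        df = ligand_delta_bcc(bound, small_structure, obs)
        assert len(df) >= 1
        assert (df.delta > 0).all()
        assert set(df.columns) >= {"bcc_bound", "bcc_unbound", "delta"}
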