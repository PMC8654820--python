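import numpy as np
import pytest

from boxcc import (DescriptorRecord, augment_rotations, balance_dataset,
                   build_descriptors, extract_box, label_record,
                   residue_centroid, rotate_voxels, synthesize_map)
from boxcc.density import suggest_grid
from boxcc.descriptors import CHANNEL_ELEMENTS, DescriptorBuilder
from boxcc.metrics import CALC_B_ISO
from boxcc.structure import set_uniform_bfactor, strip


@pytest.fixture(scope="module")
def builder(small_structure, obs_map):
    return DescriptorBuilder(small_structure, obs_map, resolution_tag="1.8A")


class TestBuildDescriptors:
    def test_channel_identities_and_shapes(self, builder, small_structure):
        rec = builder.build(small_structure.residues[0])
        assert rec.channels.shape == (5, 24, 24, 24)
        assert rec.channels.dtype == np.float32
        assert rec.amino_acid == small_structure.residues[0].name
        assert rec.label is None

    def test_sulfur_channel_matches_residue_content(self, small_structure, obs_map,
                                                    builder):
        """Channel 4 is nonzero exactly when sulfur atoms fall in the box."""
        has_s = [any(a.element == "S" for a in r.atoms) for r in small_structure.residues]
        for res, s in zip(small_structure.residues, has_s):
            rec = builder.build(res)
            if s:   # a MET/CYS residue centered in its own box
                assert rec.channels[4].max() > 0
        # a residue far from any sulfur has an all-zero channel 4
        s_pos = [a.pos for r in small_structure.residues for a in r.atoms
                 if a.element == "S"]
        for res in small_structure.residues:
            c = residue_centroid(res)
            if s_pos and min(np.linalg.norm(p - c) for p in s_pos) > 12.0:
                assert builder.build(res).channels[4].max() == 0.0

    def test_channel_sum_equals_combined_map_box(self, small_structure, obs_map,
                                                 builder):
        """Linearity: the four element channels sum to the box of the
        all-element calculated map (same grid, same B policy)."""
        prep = set_uniform_bfactor(strip(small_structure), CALC_B_ISO)
        dims = builder.element_maps["C"].shape
        combined = synthesize_map(prep, dims, b_override=CALC_B_ISO)
        res = small_structure.residues[2]
        rec = builder.build(res)
        box = extract_box(combined, residue_centroid(res))
        assert np.allclose(rec.calc_sum(), box.values, atol=1e-6)

    def test_wrapper_matches_builder(self, small_structure, obs_map, builder):
        res = small_structure.residues[1]
        rec1 = build_descriptors(small_structure, obs_map, res)
        rec2 = builder.build(res)
        assert np.array_equal(rec1.channels, rec2.channels)
        with pytest.raises(ValueError):
            from boxcc.structure import Residue, Atom
            ghost = Residue("Z", 99, "ALA", [Atom("CA", "C", [0, 0, 0])])
            build_descriptors(small_structure, obs_map, ghost)


class TestLabelRecord:
    def test_self_consistent_label_near_one(self, small_structure, selfconsistent_map):
        b = DescriptorBuilder(small_structure, selfconsistent_map)
        rec = label_record(b.build(small_structure.residues[2]), selfconsistent_map)
        assert rec.label is not None and rec.label >= 0.99

    def test_label_delegates_to_bcc(self, small_structure, obs_map, builder):
        from boxcc import bcc
        res = small_structure.residues[3]
        rec = label_record(builder.build(res), obs_map)
        box = extract_box(obs_map, residue_centroid(res))
        assert rec.label == pytest.approx(bcc(box.values, rec.calc_sum().astype(float)),
                                          abs=1e-12)

    def test_degenerate_correct_box_flags_record(self, small_structure, obs_map,
                                                 builder):
        from boxcc import DensityMap
        flat = DensityMap(obs_map.cell, np.zeros_like(obs_map.values))
        rec = label_record(builder.build(small_structure.residues[0]), flat)
        assert rec.label is None
        assert rec.flag == "unlabeled-degenerate"


def _toy_records(labels, rng=None):
    out = []
    for i, lab in enumerate(labels):
        out.append(DescriptorRecord(
            channels=np.zeros((5, 2, 2, 2), dtype=np.float32) + i,
            amino_acid="ALA", structure_id=f"s{i}", resolution_tag="2A",
            chain="A", resnum=i, label=lab))
    return out


class TestBalance:
    def test_flat_histogram_identity_up_to_order(self):
        labels = [0.05, 0.15, 0.25, 0.35, 0.45, 0.55]
        recs = _toy_records(labels)
        out = balance_dataset(recs, n_bins=10, per_bin_cap=5, seed=1)
        assert sorted(r.label for r in out) == sorted(labels)

    def test_caps_flatten_skewed_labels(self, rng):
        labels = np.concatenate([rng.uniform(0.55, 0.65, 300),
                                 (np.arange(200) + 0.5) / 200.0])
        out = balance_dataset(_toy_records(labels), n_bins=10, per_bin_cap=12, seed=2)
        hist, _ = np.histogram([r.label for r in out], bins=10, range=(0, 1))
        occupied = hist[hist > 0]
        assert occupied.max() <= 12
        assert occupied.max() / occupied.min() <= 2

    def test_seeded_selection_reproducible_and_unlabeled_dropped(self, rng):
        labels = list(rng.uniform(0, 1, 50)) + [None] * 5
        a = balance_dataset(_toy_records(labels), 10, 3, seed=9)
        b = balance_dataset(_toy_records(labels), 10, 3, seed=9)
        assert [r.resnum for r in a] == [r.resnum for r in b]
        assert all(r.label is not None for r in a)
        with pytest.raises(ValueError):
            balance_dataset(_toy_records(labels), n_bins=1, per_bin_cap=3)


class TestAugment:
    def test_24_outputs_rotation0_identity_labels_carried(self, rng):
        rec = _toy_records([0.42])[0]
        rec.channels = rng.normal(size=(5, 8, 8, 8)).astype(np.float32)
        out = augment_rotations(rec)
        assert len(out) == 24
        assert np.array_equal(out[0].channels, rec.channels)
        assert all(r.label == 0.42 for r in out)
        for k, r in enumerate(out):
            for c in range(5):
                assert np.array_equal(np.sort(r.channels[c].ravel()),
                                      np.sort(rec.channels[c].ravel()))
            assert np.array_equal(r.channels, rotate_voxels(rec.channels, k))


class TestArchive:
    def test_roundtrip_bit_identical_and_manifest(self, tmp_path, rng):
        from boxcc import DatasetArchive
        recs = _toy_records(list(rng.uniform(0, 1, 7)))
        for r in recs:
            r.channels = rng.normal(size=(5, 6, 6, 6)).astype(np.float32)
        recs[3].amino_acid = "LEU"
        path = tmp_path / "arc.h5"
        arc = DatasetArchive.create(path, provenance={"seed": 1})
        arc.add_records(recs)
        arc.finalize()
        assert arc.manifest["counts"] == {"ALA": 6, "LEU": 1}
        assert sum(arc.manifest["label_histogram"]["counts"]) == 7
        back = arc.load_records("ALA")
        orig = [r for r in recs if r.amino_acid == "ALA"]
        for a, b in zip(orig, back):
            assert np.array_equal(a.channels, b.channels)
            assert b.label == pytest.approx(a.label)
            assert (b.chain, b.resnum, b.structure_id) == (a.chain, a.resnum, a.structure_id)
        h1 = arc.manifest_hash()
        arc.close()
        arc2 = DatasetArchive(path)
        assert arc2.manifest_hash() == h1
        arc2.close()
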