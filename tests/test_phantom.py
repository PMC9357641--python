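"""Phantom generator: determinism, truth consistency, channel signatures."""

import numpy as np
import pytest

from mpmbreast import phantom as ph
from mpmbreast.errors import InvalidConfigError

ZERO_COUNTS = {k: 0 for k in ("ducts", "adipose", "collagen", "dcis", "invasive", "immune")}


class TestGeneratePhantom:
    def test_deterministic_given_seed(self):
        spec = ph.PhantomSpec(
            geometry=ph.StackGeometry(width_px=256, height_px=256),
            structure_counts=dict(ZERO_COUNTS, adipose=2, collagen=2),
            seed=5,
        )
        s1, t1 = ph.generate_phantom(spec)
        s2, t2 = ph.generate_phantom(spec)
        assert np.array_equal(s1.voxels, s2.voxels)
        assert np.array_equal(t1.structure_mask, t2.structure_mask)

    def test_empty_phantom_is_constant_background(self):
        spec = ph.PhantomSpec(
            geometry=ph.StackGeometry(width_px=256, height_px=256),
            structure_counts=ZERO_COUNTS,
            noise_sd=0.0,
            tissue_coverage=0.0,
            background_level=40.0,
            seed=1,
        )
        stack, truth = ph.generate_phantom(spec)
        assert np.unique(stack.voxels).tolist() == [40]
        assert truth.tile_labels.sum() == 0
        assert not truth.cancer_mask.any()

    def test_normal_tissue_has_no_cancer(self, normal_phantom):
        stack, truth = normal_phantom
        assert not truth.cancer_mask.any()
        assert truth.tile_labels.sum() == 0
        assert stack.tissue_label == "normal"

    def test_normal_spec_rejects_cancer_structures(self):
        with pytest.raises(InvalidConfigError):
            ph.PhantomSpec(tissue_class="normal", structure_counts=dict(ZERO_COUNTS, dcis=1))

    def test_voxels_are_12_bit(self, reference_phantom):
        stack, _ = reference_phantom
        assert stack.voxels.dtype == np.uint16
        assert stack.voxels.max() <= 4095

    def test_cancer_mask_lies_inside_cancer_structures(self, reference_phantom):
        _, truth = reference_phantom
        cancer_structs = np.isin(truth.structure_mask, ph.CANCER_CODES)
        assert truth.cancer_mask.sum() > 0
        assert np.all(cancer_structs[truth.cancer_mask])

    def test_tile_labels_follow_coverage_rule(self, reference_phantom):
        _, truth = reference_phantom
        cov = truth.cancer_mask.reshape(8, 128, 8, 128).mean(axis=(1, 3))
        assert np.array_equal(truth.tile_labels, cov > 0.05)

    def test_collagen_dominates_first_channel(self):
        # SHG signature check needs a noise-free render
        spec = ph.PhantomSpec(
            structure_counts=dict(ZERO_COUNTS, ducts=2, collagen=4),
            noise_sd=0.0,
            seed=9,
        )
        stack, truth = ph.generate_phantom(spec)
        ch1 = stack.voxels[0, 0].astype(float)
        collagen = truth.structure_mask == ph.STRUCTURE_CODES["collagen"]
        epithelium = truth.structure_mask == ph.STRUCTURE_CODES["duct_epithelium"]
        assert collagen.sum() > 0 and epithelium.sum() > 0
        assert ch1[collagen].mean() > ch1[epithelium].mean()

    def test_normal_ducts_have_edge_puncta_dcis_do_not(self):
        spec_n = ph.PhantomSpec(
            structure_counts=dict(ZERO_COUNTS, ducts=3), noise_sd=0.0, seed=13
        )
        spec_c = ph.PhantomSpec(
            tissue_class="cancer",
            structure_counts=dict(ZERO_COUNTS, dcis=3),
            noise_sd=0.0,
            seed=13,
        )
        _, truth_n = ph.generate_phantom(spec_n)
        _, truth_c = ph.generate_phantom(spec_c)
        assert (truth_n.structure_mask == ph.STRUCTURE_CODES["duct_edge_puncta"]).sum() > 0
        assert (truth_c.structure_mask == ph.STRUCTURE_CODES["duct_edge_puncta"]).sum() == 0


class TestGenerateCohort:
    @pytest.fixture(scope="class")
    def small_cohort(self):
        geom = ph.StackGeometry(width_px=256, height_px=256)
        return ph.generate_cohort(
            n_patients=4, images_per_patient=3, cancer_fraction=0.5, seed=2, geometry=geom
        )

    def test_manifest_row_count(self, small_cohort):
        assert len(small_cohort) == 12
        manifest = ph.cohort_manifest(small_cohort)
        assert len(manifest) == 12

    def test_patient_disjoint_groups(self, small_cohort):
        groups = {}
        for stack, _ in small_cohort:
            groups.setdefault(stack.patient_id, set()).add(stack.group)
        assert all(len(g) == 1 for g in groups.values())
        assert {g for s in groups.values() for g in s} == {"A", "B"}

    def test_cancer_fraction_zero_gives_no_cancer_tiles(self):
        geom = ph.StackGeometry(width_px=256, height_px=256)
        cohort = ph.generate_cohort(3, 2, cancer_fraction=0.0, seed=4, geometry=geom)
        assert all(not truth.tile_labels.any() for _, truth in cohort)

    def test_single_patient_rejected(self):
        with pytest.raises(InvalidConfigError):
            ph.generate_cohort(1, 2, seed=0)

    def test_invalid_cancer_fraction_rejected(self):
        with pytest.raises(InvalidConfigError):
            ph.generate_cohort(4, 2, cancer_fraction=1.5, seed=0)

    def test_cohort_deterministic(self):
        geom = ph.StackGeometry(width_px=256, height_px=256)
        c1 = ph.generate_cohort(3, 2, seed=8, geometry=geom)
        c2 = ph.generate_cohort(3, 2, seed=8, geometry=geom)
        for (s1, _), (s2, _) in zip(c1, c2):
            assert s1.image_id == s2.image_id
            assert np.array_equal(s1.voxels, s2.voxels)


class TestStackIO:
    def test_tiff_roundtrip(self, tmp_path):
        spec = ph.PhantomSpec(
            geometry=ph.StackGeometry(width_px=256, height_px=256),
            structure_counts=dict(ZERO_COUNTS, adipose=1),
            seed=6,
        )
        stack, truth = ph.generate_phantom(spec)
        stack.image_id = "t_img"
        ph.save_stack(stack, truth, tmp_path)
        back, back_truth = ph.load_stack(tmp_path, "t_img")
        assert np.array_equal(back.voxels, stack.voxels)
        assert back.geometry == stack.geometry
        assert np.array_equal(back_truth.cancer_mask, truth.cancer_mask)
        assert np.array_equal(back_truth.tile_labels, truth.tile_labels)

    def test_cohort_manifest_on_disk(self, tmp_path):
        geom = ph.StackGeometry(width_px=256, height_px=256)
        cohort = ph.generate_cohort(2, 2, seed=1, geometry=geom)
        path = ph.save_cohort(cohort, tmp_path)
        assert path.exists()
        loaded = ph.load_cohort(tmp_path)
        assert len(loaded) == 4
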