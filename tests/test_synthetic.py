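import numpy as np
import pytest

import bbquant as bq
from bbquant.errors import ConfigurationError


class TestReproducibility:
    def test_oocyte_bit_reproducible_for_fixed_seed(self):
        spec = bq.SyntheticSpec(mode="oocyte_cleft", cell_diameter_um=14)
        s1, r1, t1 = bq.generate_oocyte(spec, seed=5)
        s2, r2, t2 = bq.generate_oocyte(spec, seed=5)
        assert np.array_equal(s1.data, s2.data)
        assert np.array_equal(t1.nucleus_labels, t2.nucleus_labels)
        s3, _, _ = bq.generate_oocyte(spec, seed=6)
        assert not np.array_equal(s1.data, s3.data)

    def test_nest_bit_reproducible_for_fixed_seed(self):
        spec = bq.SyntheticSpec(mode="nest", n_cells=4)
        s1, _, t1 = bq.generate_nest(spec, seed=2)
        s2, _, t2 = bq.generate_nest(spec, seed=2)
        assert np.array_equal(s1.data, s2.data)
        assert t1.cells[0].centrosome_center_um == t2.cells[0].centrosome_center_um


class TestOocyteGeometry:
    def test_prenoise_channel_reproduces_generative_fold(self):
        """The clean experimental channel, measured with the truth geometry,
        must return the generative enrichment factor almost exactly."""
        spec = bq.SyntheticSpec(mode="oocyte_cleft", enrichment_factor=3.0)
        stack, rois, truth = bq.generate_oocyte(spec, seed=11)
        roi = bq.rasterize_unit(rois.units[0], stack.shape)
        nuclear = (truth.nucleus_labels > 0) & roi
        cyto = roi & ~nuclear
        part = bq.partition_cytoplasm(
            cyto, [truth.cells[0].centrosome_center_um], 4.8, 6.0, spec.voxel_size
        )
        clean = truth.clean_experimental
        fold = bq.fold_enrichment(
            clean[part.adjacent].mean(), clean[part.nonadjacent].mean(), clean[nuclear].mean()
        )
        assert fold == pytest.approx(3.0, rel=0.02)

    def test_rendered_punctum_is_at_least_eight_voxels_and_detected(self):
        cfg = bq.default_config("cleft")
        for seed in range(30):
            spec = bq.SyntheticSpec(mode="oocyte_cleft", cell_diameter_um=17)
            stack, rois, truth = bq.generate_oocyte(spec, seed=seed)
            roi = bq.rasterize_unit(rois.units[0], stack.shape)
            found = bq.detect_centrosomes(
                stack.channel("gamma_tubulin"),
                roi,
                cfg.t_tub_min,
                min_voxels=cfg.min_centrosome_voxels,
                voxel_size=stack.voxel_size,
            )
            assert len(found) >= 1, f"no centrosome detected for seed {seed}"
            # the largest detected component sits at the true centrosome
            err = np.linalg.norm(
                np.array(found[0].center_um) - np.array(truth.cells[0].centrosome_center_um)
            )
            assert err < 0.75, f"center off by {err:.2f} um for seed {seed}"

    def test_uniform_control_has_no_enrichment_gradient(self):
        spec = bq.SyntheticSpec(mode="uniform_control")
        _, _, truth = bq.generate_oocyte(spec, seed=0)
        cyto_vals = truth.clean_experimental[truth.clean_experimental > spec.offset_intensity]
        assert np.allclose(cyto_vals, spec.offset_intensity + spec.base_intensity)

    def test_spherical_nucleus_when_cleft_depth_zero(self):
        spec = bq.SyntheticSpec(mode="oocyte_cleft", cleft_depth_um=0.0, cell_diameter_um=14)
        stack, _, truth = bq.generate_oocyte(spec, seed=1)
        nucleus = truth.nucleus_labels > 0
        # a sphere's voxelization is symmetric under xy flips through its center
        assert np.array_equal(nucleus, nucleus[:, ::-1, :])
        assert np.array_equal(nucleus, nucleus[:, :, ::-1])


class TestNestGeometry:
    def test_cells_are_packed_without_overlap(self):
        spec = bq.SyntheticSpec(mode="nest", n_cells=8)
        _, _, truth = bq.generate_nest(spec, seed=4)
        centers = np.array([c.center_um for c in truth.cells])
        d = np.sqrt(((centers[:, None] - centers[None, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 0.9 * spec.cell_diameter_um

    def test_roi_encloses_all_nuclei(self):
        spec = bq.SyntheticSpec(mode="nest", n_cells=6)
        stack, rois, truth = bq.generate_nest(spec, seed=9)
        roi = bq.rasterize_unit(rois.units[0], stack.shape)
        assert roi[truth.nucleus_labels > 0].all()

    def test_all_truth_centers_recovered_within_one_voxel(self):
        spec = bq.SyntheticSpec(mode="nest", n_cells=8)
        cfg = bq.default_config("nest")
        for seed in (0, 1, 2):
            stack, rois, truth = bq.generate_nest(spec, seed=seed)
            roi = bq.rasterize_unit(rois.units[0], stack.shape)
            found = bq.detect_centrosomes(
                stack.channel("gamma_tubulin"), roi, cfg.t_tub_min,
                min_voxels=cfg.min_centrosome_voxels, voxel_size=stack.voxel_size,
            )
            assert len(found) == 8
            tol = np.linalg.norm(stack.voxel_size)  # one voxel diagonal
            for cell in truth.cells:
                best = min(
                    np.linalg.norm(np.array(f.center_um) - np.array(cell.centrosome_center_um))
                    for f in found
                )
                assert best <= tol

    def test_dispersed_control_is_uniform(self):
        spec = bq.SyntheticSpec(mode="dispersed_control", n_cells=4)
        _, _, truth = bq.generate_nest(spec, seed=3)
        assert truth.enrichment_factor == 1.0
        cyto = truth.clean_experimental > spec.offset_intensity
        assert np.allclose(
            truth.clean_experimental[cyto], spec.offset_intensity + spec.base_intensity
        )


class TestColocPair:
    def test_pearson_monotone_in_overlap_fraction(self):
        medians = []
        for overlap in (0.0, 0.25, 0.5, 0.75, 1.0):
            rs = []
            for seed in range(5):
                ch1, ch2, mask, _ = bq.generate_coloc_pair(overlap, size=96, seed=100 + seed)
                rs.append(bq.pearson(ch1, ch2, mask))
            medians.append(float(np.median(rs)))
        assert medians == sorted(medians)
        assert medians[-1] > 0.9

    def test_zero_overlap_manders_near_zero(self):
        ch1, ch2, mask, _ = bq.generate_coloc_pair(0.0, size=96, seed=7)
        m1, m2 = bq.manders(ch1, ch2, mask, 100, 100)
        assert m1 < 0.05 and m2 < 0.05

    def test_truth_reports_shared_positions(self):
        _, _, _, truth = bq.generate_coloc_pair(0.5, n_puncta=20, seed=0)
        assert truth["n_shared"] == 10
        assert np.array_equal(truth["positions_1"][:10], truth["positions_2"][:10])


class TestSpecValidation:
    def test_mode_dependent_defaults(self):
        assert bq.SyntheticSpec(mode="oocyte_cleft").cell_diameter_um == 20.0
        nest = bq.SyntheticSpec(mode="nest", n_cells=4)
        assert nest.cell_diameter_um == 12.0
        assert nest.enrichment_radius_um == 1.2

    def test_invalid_specs_rejected(self):
        with pytest.raises(ConfigurationError):
            bq.SyntheticSpec(mode="banana")
        with pytest.raises(ConfigurationError):
            bq.SyntheticSpec(mode="nest", n_cells=1)
        with pytest.raises(ConfigurationError):
            bq.SyntheticSpec(mode="oocyte_cleft", enrichment_factor=-1)
        with pytest.raises(ConfigurationError):
            bq.generate_nest(bq.SyntheticSpec(mode="oocyte_cleft"), seed=0)
        with pytest.raises(ConfigurationError):
            bq.generate_oocyte(bq.SyntheticSpec(mode="nest", n_cells=4), seed=0)
        with pytest.raises(ValueError):
            bq.generate_coloc_pair(1.5)
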