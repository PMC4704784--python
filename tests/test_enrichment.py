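import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bbquant as bq
from bbquant.errors import EmptyInputError
from oracles import mean_oracle, partition_oracle


class TestPartition:
    def test_cleft_radii_classify_by_distance(self):
        # a 1-voxel-thick line with dx = 0.1 um puts voxel x at d = x/10 um
        cyto = np.ones((1, 1, 80), dtype=bool)
        part = bq.partition_cytoplasm(cyto, [(0.0, 0.0, 0.0)], 4.8, 6.0, (1.0, 1.0, 0.1))
        assert part.adjacent[0, 0, 47]  # d = 4.7 um
        assert part.shell[0, 0, 55]  # d = 5.5 um
        assert part.nonadjacent[0, 0, 61]  # d = 6.1 um
        assert not part.adjacent[0, 0, 49]  # d = 4.9 um is past the inner radius

    def test_two_centers_nest_radii(self):
        cyto = np.ones((1, 1, 120), dtype=bool)
        centers = [(0.0, 0.0, 1.0), (0.0, 0.0, 11.0)]  # 10 um apart
        part = bq.partition_cytoplasm(cyto, centers, 1.2, 2.4, (1.0, 1.0, 0.1))
        assert part.adjacent[0, 0, 20]  # 1.0 um from first center
        assert part.adjacent[0, 0, 100]  # 1.0 um from second center
        assert part.nonadjacent[0, 0, 60]  # 5 um from both

    @pytest.mark.parametrize("seed", range(5))
    def test_partition_matches_distance_oracle(self, seed):
        rng = np.random.default_rng(seed)
        shape = (6, 10, 10)
        cyto = rng.random(shape) < 0.7
        voxel = (0.53, 0.25, 0.25)
        centers = [tuple(rng.uniform(0, 2.5, size=3)) for _ in range(rng.integers(1, 4))]
        part = bq.partition_cytoplasm(cyto, centers, 0.8, 1.4, voxel)
        adj, shell, non = partition_oracle(cyto, centers, 0.8, 1.4, voxel)
        assert np.array_equal(part.adjacent, adj)
        assert np.array_equal(part.shell, shell)
        assert np.array_equal(part.nonadjacent, non)
        # disjoint and exhaustive
        assert np.array_equal(part.adjacent | part.shell | part.nonadjacent, cyto)
        assert not np.any(part.adjacent & part.nonadjacent)

    def test_empty_centers_rejected(self):
        with pytest.raises(EmptyInputError):
            bq.partition_cytoplasm(np.ones((2, 2, 2), bool), [], 1.0, 2.0, (1, 1, 1))


class TestRegionalMeans:
    @staticmethod
    def build(values_nuc, values_adj, values_non):
        shape = (1, 3, 4)
        exp = np.zeros(shape)
        nuclear = np.zeros(shape, bool)
        adjacent = np.zeros(shape, bool)
        nonadjacent = np.zeros(shape, bool)
        nuclear[0, 0, :] = True
        adjacent[0, 1, :] = True
        nonadjacent[0, 2, :] = True
        exp[0, 0, :] = values_nuc
        exp[0, 1, :] = values_adj
        exp[0, 2, :] = values_non
        roi = nuclear | adjacent | nonadjacent
        masks = bq.RegionMasks(nuclear=nuclear, cytoplasm=adjacent | nonadjacent, roi=roi)
        part = bq.RegionPartition(
            adjacent=adjacent,
            shell=np.zeros(shape, bool),
            nonadjacent=nonadjacent,
            centers_used=[(0, 0, 0)],
            r_adjacent=1.0,
            r_nonadjacent=2.0,
        )
        return exp, masks, part

    def test_uniform_field_gives_equal_means(self):
        exp, masks, part = self.build(100, 100, 100)
        assert bq.regional_means(exp, masks, part) == (100.0, 100.0, 100.0)

    def test_three_region_toy(self):
        exp, masks, part = self.build(10, 40, 20)
        assert bq.regional_means(exp, masks, part) == (10.0, 40.0, 20.0)

    def test_random_volume_matches_summation_oracle(self):
        rng = np.random.default_rng(0)
        exp, masks, part = self.build(
            rng.uniform(0, 4095, 4), rng.uniform(0, 4095, 4), rng.uniform(0, 4095, 4)
        )
        mn, ma, mna = bq.regional_means(exp, masks, part)
        assert mn == pytest.approx(mean_oracle(exp[masks.nuclear]), rel=1e-14)
        assert ma == pytest.approx(mean_oracle(exp[part.adjacent]), rel=1e-14)
        assert mna == pytest.approx(mean_oracle(exp[part.nonadjacent]), rel=1e-14)

    def test_empty_region_rejected(self):
        exp, masks, part = self.build(10, 40, 20)
        part.nonadjacent[:] = False
        with pytest.raises(EmptyInputError):
            bq.regional_means(exp, masks, part)


class TestFold:
    def test_forced_arithmetic(self):
        assert bq.fold_enrichment(30, 15, 5) == pytest.approx(2.5)
        assert bq.fold_enrichment(20, 20, 5) == pytest.approx(1.0)

    def test_nonpositive_denominator_is_undefined_not_an_exception(self):
        assert bq.fold_enrichment(30, 5, 5) is None
        assert bq.fold_enrichment(30, 3, 5) is None

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        adj=st.floats(10, 4000),
        non=st.floats(10, 4000),
        nuc=st.floats(0, 4000),
        gain=st.floats(0.01, 50),
        offset=st.floats(-100, 100),
    )
    def test_affine_intensity_invariance(self, adj, non, nuc, gain, offset):
        base = bq.fold_enrichment(adj, non, nuc)
        scaled = bq.fold_enrichment(gain * adj + offset, gain * non + offset, gain * nuc + offset)
        if base is None:
            assert scaled is None
        else:
            assert scaled == pytest.approx(base, rel=1e-9)


class TestAnalyze:
    def test_uniform_experimental_channel_gives_unity_fold(self):
        spec = bq.SyntheticSpec(mode="uniform_control")
        stack, rois, _ = bq.generate_oocyte(spec, seed=42)
        res = bq.analyze_cleft(stack, rois.units[0], bq.default_config("cleft"))
        assert res.fold is not None
        assert abs(res.fold - 1.0) < 0.1

    def test_roi_excluding_punctum_is_skipped_with_flag(self):
        spec = bq.SyntheticSpec(mode="oocyte_cleft")
        stack, rois, _ = bq.generate_oocyte(spec, seed=3)
        # a small corner ROI that cannot contain the punctum
        corner = bq.RoiUnit(
            name="corner",
            polygons=[(z, [(0.5, 0.5), (4.5, 0.5), (4.5, 4.5), (0.5, 4.5)]) for z in range(3)],
        )
        res = bq.analyze_cleft(stack, corner, bq.default_config("cleft"))
        assert res.fold is None
        assert "no_centrosome" in res.qc_flags
        assert res.n_centrosomes == 0

    def test_nest_with_missing_punctum_still_produces_result(self):
        spec = bq.SyntheticSpec(mode="nest", n_cells=8, enrichment_factor=1.6, n_missing_centrosomes=1)
        stack, rois, _ = bq.generate_nest(spec, seed=8)
        res = bq.analyze_nest(stack, rois.units[0], bq.default_config("nest"))
        assert res.n_centrosomes == 7
        assert res.fold is not None

    def test_mode_mismatch_raises(self):
        spec = bq.SyntheticSpec(mode="oocyte_cleft", cell_diameter_um=14)
        stack, rois, _ = bq.generate_oocyte(spec, seed=1)
        with pytest.raises(ValueError):
            bq.analyze_cleft(stack, rois.units[0], bq.default_config("nest"))

    def test_group_fold_averages_defined_folds(self):
        r1 = bq.EnrichmentResult(unit_id="a", mode="cleft", fold=2.0)
        r2 = bq.EnrichmentResult(unit_id="b", mode="cleft", fold=3.0)
        r3 = bq.EnrichmentResult(unit_id="c", mode="cleft", fold=None)
        assert bq.group_fold([r1, r2, r3]) == pytest.approx(2.5)
        with pytest.raises(EmptyInputError):
            bq.group_fold([r3])
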