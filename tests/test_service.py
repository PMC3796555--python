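import numpy as np
import pytest

from pollmap import GridSpec
from pollmap.synthetic import CropMap
from pollmap.service import (
    ForagingSpec,
    honeybee_layer,
    low_service_mask,
    resample_crop,
    service_single_species,
    total_service,
)


def naive_service(p_sm, crop_mask, a_s, factor, cell_size=1.0):
    """Literal double loop over (crop cell, map cell) — the kernel oracle."""
    nr, nc = p_sm.shape
    radius = factor * a_s
    out = np.zeros_like(p_sm)
    for oi in range(nr):
        for oj in range(nc):
            if not crop_mask[oi, oj]:
                continue
            num = den = 0.0
            for mi in range(nr):
                for mj in range(nc):
                    d = cell_size * np.hypot(oi - mi, oj - mj)
                    if d <= radius:
                        w = np.exp(-d / a_s)
                        num += p_sm[mi, mj] * w
                        den += w
            out[oi, oj] = num / den if den else 0.0
    return out


def _crop(spec, mask=None):
    raster = np.ones(spec.shape, np.uint8) if mask is None else mask.astype(np.uint8)
    return CropMap(raster, spec)


class TestServiceSingleSpecies:
    def test_single_cell_universe_is_identity(self):
        spec = GridSpec(1, 1)
        sm = service_single_species(np.array([[0.7]]), _crop(spec), a_s=1.0)
        assert sm.values[0, 0] == pytest.approx(0.7)

    def test_constant_field_weights_cancel(self):
        spec = GridSpec(6, 6)
        sm = service_single_species(np.full(spec.shape, 0.42), _crop(spec), a_s=2.0)
        np.testing.assert_allclose(sm.values, 0.42, atol=1e-12)

    def test_two_cell_hand_evaluation(self):
        # source at distance 0 with P=1, neighbour at distance a_s with P=0
        spec = GridSpec(1, 2)
        p_sm = np.array([[1.0, 0.0]])
        crop = _crop(spec, np.array([[1, 0]]))
        sm = service_single_species(p_sm, crop, a_s=1.0)
        assert sm.values[0, 0] == pytest.approx(1 / (1 + np.exp(-1)), abs=1e-12)
        assert sm.values[0, 0] == pytest.approx(0.7311, abs=1e-4)

    @pytest.mark.parametrize("seed,a_s", [(0, 1.0), (1, 2.0)])
    def test_matches_naive_double_loop(self, seed, a_s):
        rng = np.random.default_rng(seed)
        spec = GridSpec(12, 12)
        p_sm = rng.uniform(size=spec.shape)
        crop_mask = rng.uniform(size=spec.shape) > 0.5
        sm = service_single_species(p_sm, _crop(spec, crop_mask), a_s=a_s)
        oracle = naive_service(p_sm, crop_mask, a_s, 3.0)
        np.testing.assert_allclose(sm.values, oracle, atol=1e-10)

    def test_out_of_reach_crop_cell_scores_exactly_zero(self):
        spec = GridSpec(1, 10)
        p_sm = np.zeros(spec.shape)
        p_sm[0, 0] = 1.0
        sm = service_single_species(p_sm, _crop(spec), a_s=1.0, kernel_radius_factor=3.0)
        assert sm.values[0, 9] == 0.0  # distance 9 > 3 x a_s
        assert sm.values[0, 1] > 0.0

    def test_distance_decay_from_point_source(self):
        spec = GridSpec(1, 7)
        p_sm = np.zeros(spec.shape)
        p_sm[0, 0] = 1.0
        sm = service_single_species(p_sm, _crop(spec), a_s=2.0)
        within = sm.values[0, :6]  # inside the kernel radius
        assert np.all(np.diff(within) < 0)

    def test_doubling_foraging_distance_reaches_new_cells(self):
        spec = GridSpec(1, 12)
        p_sm = np.zeros(spec.shape)
        p_sm[0, 0] = 1.0
        short = service_single_species(p_sm, _crop(spec), a_s=1.0)
        doubled = service_single_species(p_sm, _crop(spec), a_s=2.0)
        beyond = np.arange(12) > 3  # cells past the original radius
        assert np.all(doubled.values[0, beyond] >= short.values[0, beyond])
        assert doubled.values[0, 5] > 0 == short.values[0, 5]

    def test_bounds_and_validation(self):
        spec = GridSpec(5, 5)
        rng = np.random.default_rng(2)
        p_sm = rng.uniform(size=spec.shape)
        sm = service_single_species(p_sm, _crop(spec), a_s=1.5)
        assert np.all(sm.values >= 0) and np.all(sm.values <= p_sm.max() + 1e-12)
        with pytest.raises(ValueError):
            service_single_species(p_sm, _crop(spec), a_s=0.0)
        with pytest.raises(ValueError):
            service_single_species(p_sm * 2, _crop(spec), a_s=1.0)


class TestTotalService:
    def _maps(self, spec, vals):
        from pollmap.service import ServiceMap

        mask = np.ones(spec.shape, bool)
        return [
            ServiceMap(np.full(spec.shape, v), mask, spec, species_id=f"sp{i}")
            for i, v in enumerate(vals)
        ]

    def test_compatible_species_sum(self):
        spec = GridSpec(3, 3)
        maps = self._maps(spec, [0.3, 0.2])
        total = total_service(maps, {"sp0": 1, "sp1": 1})
        assert np.allclose(total.values, 0.5)

    def test_incompatible_species_masked_out(self):
        spec = GridSpec(3, 3)
        maps = self._maps(spec, [0.3, 0.2])
        total = total_service(maps, {"sp0": 1, "sp1": 0})
        assert np.allclose(total.values, 0.3)

    def test_missing_species_rejected(self):
        spec = GridSpec(3, 3)
        with pytest.raises(KeyError, match="sp1"):
            total_service(self._maps(spec, [0.3, 0.2]), {"sp0": 1})


class TestHoneybeeLayer:
    def test_forager_counts_divided_by_four(self):
        coarse = GridSpec(1, 1, cell_size=2.0)
        layer = honeybee_layer(np.array([[100.0]]), coarse, absence_percentile=0)
        # one coarse cell -> four fine cells; single positive score rescales to 1
        assert layer.score.shape == (2, 2)
        assert np.all(layer.score == 1.0)

    def test_min_max_rescale(self):
        coarse = GridSpec(1, 3, cell_size=2.0)
        layer = honeybee_layer(np.array([[0.0, 50.0, 100.0]]), coarse, absence_percentile=0)
        assert np.unique(layer.score).tolist() == [0.0, 0.5, 1.0]

    def test_fifth_percentile_cutoff_zeroes_low_cells(self):
        coarse = GridSpec(10, 10, cell_size=2.0)
        rng = np.random.default_rng(0)
        counts = rng.uniform(1, 100, coarse.shape)
        layer = honeybee_layer(counts, coarse, absence_percentile=5)
        nonzero_before = np.kron(counts / 4, np.ones((2, 2)))
        rescaled = (nonzero_before - nonzero_before.min()) / np.ptp(nonzero_before)
        expected_cut = np.percentile(rescaled[rescaled > 0], 5)
        assert layer.cutoff == pytest.approx(expected_cut)
        assert np.all(layer.score[layer.absence_mask] == 0.0)
        # roughly 5% of the positive-score cells fall below the cut
        assert 0.0 < layer.absence_mask.mean() <= 0.10

    def test_all_zero_input_warns(self):
        with pytest.warns(UserWarning, match="all-zero"):
            layer = honeybee_layer(np.zeros((2, 2)), GridSpec(2, 2, cell_size=2.0))
        assert layer.absence_mask.all()


class TestResampleCrop:
    def test_one_coarse_cell_becomes_four_fine_cells(self):
        coarse = GridSpec(2, 2, cell_size=2.0)
        crop = CropMap(np.array([[1, 0], [0, 0]], np.uint8), coarse)
        fine = resample_crop(crop)
        assert fine.raster.sum() == 4
        assert fine.spec.cell_size == 1.0

    def test_area_conserved(self):
        coarse = GridSpec(4, 4, cell_size=2.0)
        rng = np.random.default_rng(1)
        crop = CropMap((rng.uniform(size=coarse.shape) > 0.5).astype(np.uint8), coarse)
        fine = resample_crop(crop)
        assert fine.raster.sum() * fine.spec.cell_size**2 == pytest.approx(
            crop.raster.sum() * coarse.cell_size**2
        )

    def test_empty_stays_empty(self):
        coarse = GridSpec(2, 2, cell_size=2.0)
        assert resample_crop(CropMap(np.zeros((2, 2), np.uint8), coarse)).raster.sum() == 0


class TestLowServiceMask:
    def _total(self, spec, values, crop_mask=None):
        from pollmap.service import ServiceMap

        mask = np.ones(spec.shape, bool) if crop_mask is None else crop_mask
        return ServiceMap(values, mask, spec)

    def test_equal_service_flags_only_zero_cells(self):
        spec = GridSpec(3, 3)
        vals = np.full(spec.shape, 0.4)
        vals[0, 0] = 0.0
        mask, summary = low_service_mask(self._total(spec, vals))
        assert mask.sum() == 1 and mask[0, 0]
        assert summary["min_service"] == 0.0

    def test_flagged_area_monotone_in_quantile(self):
        spec = GridSpec(10, 10)
        vals = np.random.default_rng(2).uniform(0.01, 1, spec.shape)
        areas = [
            low_service_mask(self._total(spec, vals), q)[1]["flagged_area_km2"]
            for q in (5, 10, 25, 50)
        ]
        assert areas == sorted(areas)

    def test_no_crop_cells_rejected(self):
        spec = GridSpec(2, 2)
        with pytest.raises(ValueError):
            low_service_mask(self._total(spec, np.ones(spec.shape), np.zeros(spec.shape, bool)))


def test_foraging_spec_validation():
    assert ForagingSpec("Bombus terrestris", 2.0).foraging_distance == 2.0
    with pytest.raises(ValueError):
        ForagingSpec("x", 0.0)
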