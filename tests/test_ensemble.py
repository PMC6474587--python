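import numpy as np
import pytest
from shapely.geometry import box

from probhab import (
    ACRES_PER_M2,
    AlignmentError,
    DeliveryKind,
    HabitatProduct,
    OverlayLayer,
    ParameterError,
    ProductNotPossibleError,
    SuitabilityModel,
    area_summary,
    build_potential,
    build_probable,
    capture_rate,
    multispecies_count,
)
from probhab.ensemble import boundary_polygons
from probhab.rubric import RubricEvaluation
from conftest import eval_points, flat_grid, pipeline_pieces


def verdict(model_id: str, acceptable: bool = True) -> RubricEvaluation:
    g = acceptable
    return RubricEvaluation(model_id, (), gate_count_pass=g, gate_age_pass=g, gate_accuracy_pass=g)


def ladder(model_id: str, vals, **kw) -> SuitabilityModel:
    return SuitabilityModel(model_id, "T", flat_grid([vals], res=100.0), **kw)


def ten_points():
    return eval_points([[50.0 + 100.0 * i, 50.0] for i in range(10)], species="sp")


class TestBuildProbable:
    def test_no_acceptable_model_raises(self):
        m = ladder("m", [0.9] * 10)
        with pytest.raises(ProductNotPossibleError):
            build_probable([(m, verdict("m", acceptable=False))], ten_points())

    def test_single_model_calibrates_closest_to_90pct(self):
        m = ladder("m", [round(0.9 - 0.1 * i, 10) for i in range(10)])
        prod = build_probable([(m, verdict("m"))], ten_points())
        assert prod.capture_eval == pytest.approx(0.9)
        assert prod.thresholds_used["m"] == pytest.approx(0.1)
        assert prod.boundary_model_ids == ("m",)

    def test_disjoint_half_models_union_to_full_capture_without_lowering(self):
        left = ladder("L", [0.9, 0.8, 0.7, 0.6, 0.5, 0.0, 0.0, 0.0, 0.0, 0.0])
        right = ladder("R", [0.0, 0.0, 0.0, 0.0, 0.0, 0.5, 0.6, 0.7, 0.8, 0.9])
        pairs = [(left, verdict("L")), (right, verdict("R"))]
        prod = build_probable(pairs, ten_points(), per_model_target=0.5)
        assert prod.capture_eval == 1.0
        # no lowering happened: each threshold still captures exactly 50%
        assert prod.thresholds_used["L"] == pytest.approx(0.5)
        assert prod.thresholds_used["R"] == pytest.approx(0.5)

    def test_identical_models_are_lowered_until_the_union_meets_90pct(self):
        vals = [round(0.9 - 0.1 * i, 10) for i in range(10)]
        pairs = [(ladder("a", vals), verdict("a")), (ladder("b", vals), verdict("b"))]
        prod = build_probable(pairs, ten_points())
        assert prod.capture_eval >= 0.9
        assert min(prod.thresholds_used.values()) == pytest.approx(0.1)

    def test_uncalibratable_model_maps_inside_the_boundary_only(self):
        full = ladder("A", [round(0.9 - 0.1 * i, 10) for i in range(10)])
        vals = [0.9, 0.8, 0.7, 0.6] + [np.nan] * 6  # fixed footprint, 40% capture
        fixed = ladder(
            "C", vals, delivered_threshold=0.6,
            delivery_kind=DeliveryKind.ABOVE_THRESHOLD_ONLY,
        )
        prod = build_probable([(full, verdict("A")), (fixed, verdict("C"))], ten_points())
        assert prod.boundary_model_ids == ("A",)
        counts = prod.model_count.data[0]
        assert list(counts[:4]) == [2.0] * 4  # both models inside the boundary
        assert list(counts[4:9]) == [1.0] * 5
        assert counts[9] == 0.0  # outside the boundary entirely
        assert any("C" in note for note in prod.notes)

    def test_union_capture_at_least_max_individual(self, small_species):
        pairs, points = pipeline_pieces(small_species, seed=11)
        prod = build_probable(pairs, points)
        for m, _ in pairs:
            individual = capture_rate(
                m.binary_map(prod.thresholds_used[m.model_id]), points
            )
            assert prod.capture_eval >= individual - 1e-12

    def test_count_and_score_invariants_inside_the_boundary(self, small_species):
        pairs, points = pipeline_pieces(small_species, seed=11)
        prod = build_probable(pairs, points)
        inside = prod.footprint_mask()
        count = prod.model_count.data
        assert ((count > 0) == inside).all()
        assert count.max() <= len(pairs)
        scores = prod.mean_score.data[inside]
        assert np.isfinite(scores).all()
        assert scores.min() >= 1.0 and scores.max() <= 100.0
        assert np.isnan(prod.mean_score.data[~inside]).all()

    def test_water_mask_removes_pixels_before_statistics(self):
        m = ladder("m", [0.9] * 10)
        water = OverlayLayer("water", geometry=box(0, 0, 250, 100))
        prod = build_probable([(m, verdict("m"))], ten_points(), water=water)
        assert not prod.footprint_mask()[0, :2].any()
        assert prod.footprint_mask()[0, 3:].all()
        assert prod.capture_eval == pytest.approx(0.8)
        assert prod.model_count.data[0, 0] == 0.0

    def test_suitable_only_score_mode_uses_only_predicting_models(self):
        hi = ladder("hi", [1.0] * 5 + [0.0] * 5)
        lo = ladder("lo", [0.5] * 10)
        pairs = [(hi, verdict("hi")), (lo, verdict("lo"))]
        prod_all = build_probable(pairs, ten_points(), per_model_target=0.5,
                                  score_mode="all_valid")
        prod_suit = build_probable(pairs, ten_points(), per_model_target=0.5,
                                   score_mode="suitable_only")
        inside = prod_all.footprint_mask()
        assert not np.allclose(
            prod_all.mean_score.data[inside], prod_suit.mean_score.data[inside]
        )


class TestBuildPotential:
    def test_no_leftovers_and_no_variants_is_an_empty_product(self, small_species):
        pairs, points = pipeline_pieces(small_species, seed=11)
        prod = build_probable(pairs, points)
        if set(prod.boundary_model_ids) == {m.model_id for m, _ in pairs}:
            pot = build_potential(pairs, prod, points)
            assert pot.footprint_mask().sum() == 0
            assert pot.thresholds_used == {}

    def test_probable_and_potential_are_disjoint(self, small_mixed_species):
        pairs, points = pipeline_pieces(small_mixed_species, seed=12)
        prod = build_probable(pairs, points)
        pot = build_potential(pairs, prod, points)
        assert not (prod.footprint_mask() & pot.footprint_mask()).any()
        assert pot.kind == "potential"

    def test_unmasked_variant_and_leftovers_feed_the_potential_map(
        self, small_mixed_species
    ):
        pairs, points = pipeline_pieces(small_mixed_species, seed=12)
        prod = build_probable(pairs, points)
        pot = build_potential(pairs, prod, points)
        used = set(prod.boundary_model_ids)
        masked_used = [
            m for m, _ in pairs if m.model_id in used and m.unmasked_variant is not None
        ]
        for m in masked_used:
            assert m.unmasked_variant.model_id in pot.thresholds_used
        for m, _ev in pairs:
            if m.model_id not in used and m.unmasked_variant is None:
                assert m.model_id in pot.thresholds_used

    def test_leftover_fixed_footprint_model_keeps_its_delivered_threshold(self):
        full = ladder("A", [round(0.9 - 0.1 * i, 10) for i in range(10)])
        vals = [0.9, 0.8, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan]
        fixed = ladder(
            "C", vals, delivered_threshold=0.8,
            delivery_kind=DeliveryKind.ABOVE_THRESHOLD_ONLY,
        )
        pairs = [(full, verdict("A")), (fixed, verdict("C"))]
        prod = build_probable(pairs, ten_points())
        pot = build_potential(pairs, prod, points=ten_points())
        assert pot.thresholds_used["C"] == pytest.approx(0.8)


class TestMultispecies:
    def make_product(self, mask) -> HabitatProduct:
        g = flat_grid(np.asarray(mask, dtype=float), res=100.0)
        return HabitatProduct(
            species=f"sp{id(mask) % 97}",
            kind="probable",
            boundary=g,
            model_count=g,
            mean_score=g,
            thresholds_used={},
            capture_eval=1.0,
        )

    def test_identical_and_disjoint_boundaries(self):
        a = self.make_product([[1, 1, 0]])
        b = self.make_product([[1, 1, 0]])
        out = multispecies_count([a, b])
        assert list(out.data[0]) == [2.0, 2.0, 0.0]
        c = self.make_product([[0, 0, 1]])
        assert multispecies_count([a, c]).data.max() == 1.0

    def test_counts_equal_elementwise_boolean_sum(self):
        rng = np.random.default_rng(8)
        masks = [rng.integers(0, 2, (4, 5)) for _ in range(3)]
        out = multispecies_count([self.make_product(m) for m in masks])
        np.testing.assert_array_equal(out.data, np.sum(masks, axis=0).astype(float))

    def test_mixed_grids_rejected(self):
        a = self.make_product([[1, 0]])
        b = self.make_product([[1, 0, 1]])
        with pytest.raises(AlignmentError):
            multispecies_count([a, b])


class TestAreas:
    def product_with_pixels(self, n, res=10.0) -> HabitatProduct:
        side = 50
        mask = np.zeros((side, side))
        mask.ravel()[:n] = 1.0
        g = flat_grid(mask, res=res)
        return HabitatProduct(
            species="sp", kind="probable", boundary=g, model_count=g,
            mean_score=g, thresholds_used={}, capture_eval=1.0,
        )

    def test_unit_arithmetic_for_1000_ten_metre_pixels(self):
        table = area_summary(self.product_with_pixels(1000))
        row = table.iloc[0]
        assert row["pixels"] == 1000
        assert row["km2"] == pytest.approx(0.1)
        assert row["acres"] == pytest.approx(100_000 * ACRES_PER_M2)
        assert row["acres"] == pytest.approx(24.7105381)

    def test_overlay_covering_half_the_footprint(self):
        prod = self.product_with_pixels(1000)
        # first 500 suitable pixels: rows 0-9 and half of row 10 (50-px rows)
        half = OverlayLayer("managed", geometry=box(0, 400, 500, 500))
        table = area_summary(prod, [half])
        assert table.set_index("region").loc["managed", "pixels"] == 500

    def test_overlapping_overlays_may_sum_past_the_total(self):
        prod = self.product_with_pixels(1000)
        o1 = OverlayLayer("a", geometry=box(0, 300, 500, 500))
        o2 = OverlayLayer("b", geometry=box(0, 350, 500, 500))
        table = area_summary(prod, [o1, o2]).set_index("region")
        assert (
            table.loc["a", "pixels"] + table.loc["b", "pixels"]
            > table.loc["total", "pixels"]
        )

    def test_overlay_layer_requires_exactly_one_source(self):
        with pytest.raises(ParameterError):
            OverlayLayer("bad", geometry=box(0, 0, 1, 1), grid=flat_grid([[1.0]]))

    def test_boundary_polygons_area_matches_pixel_count(self):
        prod = self.product_with_pixels(120)
        poly = boundary_polygons(prod)
        assert poly.area == pytest.approx(120 * 100.0)
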