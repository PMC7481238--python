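"""Milkweed losses, duck accessibility, long-term habitat, characteristics."""

import math

import numpy as np
import pandas as pd
import pytest

from landtrax.habitat import (
    MissingStratumError,
    PairCategory,
    attach_current_cover,
    category_midpoints,
    duck_accessibility,
    longterm_conversion_tally,
    longterm_mask,
    milkweed_loss,
    zonal_characteristics,
)
from landtrax.legend import default_legend
from landtrax.mmu import ACRE_M2
from landtrax.transitions import TransitionClass, TransitionMap

ACRE_SIDE_M = math.sqrt(ACRE_M2)  # pixel size that makes one pixel one acre


def make_tmap(transition, pre_cover=None, pixel_size_m=ACRE_SIDE_M):
    transition = np.asarray(transition, dtype=np.uint8)
    shape = transition.shape
    pre = np.zeros(shape, np.int32) if pre_cover is None else np.asarray(pre_cover, np.int32)
    return TransitionMap(
        transition=transition,
        conv_year=np.where(np.isin(transition, (3, 4)), 2012, 0).astype(np.int32),
        pre_cover=pre,
        post_cover=np.zeros(shape, np.int32),
        pixel_size_m=pixel_size_m,
    )


def density_rows(*rows):
    return pd.DataFrame(rows, columns=["cover", "crp", "stems_per_acre", "se_per_acre"])


class TestMilkweedLoss:
    def test_ten_acres_at_ten_stems(self, legend):
        grass = legend.code("grassland_pasture")
        t = np.full((1, 10), TransitionClass.TO_CROP)
        tmap = make_tmap(t, pre_cover=np.full((1, 10), grass))
        table = density_rows(("grassland_pasture", False, 10.0, 0.0))
        rep = milkweed_loss(tmap, np.zeros((1, 10), bool), table, legend)
        assert rep.stems_lost == pytest.approx(100.0)
        assert rep.converted_acres == pytest.approx(10.0)

    def test_zero_conversion_reports_undefined_ratio(self, legend):
        tmap = make_tmap(np.full((3, 3), TransitionClass.STABLE_CROP))
        rep = milkweed_loss(tmap, np.zeros((3, 3), bool), density_rows(), legend)
        assert rep.stems_lost == 0.0
        assert math.isnan(rep.density_ratio)

    def test_two_stratum_quadrature(self, legend):
        """Loss 400 from (40 ac @ 5 +/- 1) + (10 ac @ 20 +/- 4); SE = sqrt(3200)."""
        grass = legend.code("grassland_pasture")
        wet = legend.code("wetlands")
        t = np.full((1, 50), TransitionClass.TO_CROP)
        pre = np.full((1, 50), grass)
        pre[0, 40:] = wet
        tmap = make_tmap(t, pre_cover=pre)
        table = density_rows(("grassland_pasture", False, 5.0, 1.0),
                             ("wetlands", False, 20.0, 4.0))
        rep = milkweed_loss(tmap, np.zeros((1, 50), bool), table, legend)
        assert rep.stems_lost == pytest.approx(400.0)
        assert rep.stems_lost_se == pytest.approx(math.sqrt(3200.0))

    def test_crp_split_uses_distinct_densities(self, legend):
        grass = legend.code("grassland_pasture")
        t = np.full((1, 4), TransitionClass.TO_CROP)
        crp = np.array([[True, True, False, False]])
        tmap = make_tmap(t, pre_cover=np.full((1, 4), grass))
        table = density_rows(("grassland_pasture", True, 60.0, 0.0),
                             ("grassland_pasture", False, 15.0, 0.0))
        rep = milkweed_loss(tmap, crp, table, legend)
        assert rep.stems_lost == pytest.approx(2 * 60.0 + 2 * 15.0)

    def test_missing_stratum_raises(self, legend):
        grass = legend.code("grassland_pasture")
        t = np.full((1, 2), TransitionClass.TO_CROP)
        tmap = make_tmap(t, pre_cover=np.full((1, 2), grass))
        with pytest.raises(MissingStratumError, match="grassland_pasture"):
            milkweed_loss(tmap, np.zeros((1, 2), bool), density_rows(), legend)

    def test_additive_over_disjoint_regions_and_homogeneous(self, legend):
        grass = legend.code("grassland_pasture")
        t = np.full((2, 6), TransitionClass.STABLE_NONCROP)
        t[0, :3] = TransitionClass.TO_CROP
        t[1, 3:] = TransitionClass.TO_CROP
        tmap = make_tmap(t, pre_cover=np.full((2, 6), grass))
        crp = np.zeros((2, 6), bool)
        attach_current_cover(tmap, np.full((2, 6), grass))
        t1 = density_rows(("grassland_pasture", False, 7.0, 0.0))
        t2 = density_rows(("grassland_pasture", False, 14.0, 0.0))
        r1 = milkweed_loss(tmap, crp, t1, legend)
        r2 = milkweed_loss(tmap, crp, t2, legend)
        assert r2.stems_lost == pytest.approx(2 * r1.stems_lost)

    def test_converted_vs_existing_ratio(self, legend):
        """Converted land at 3x the density of remaining habitat yields a
        density ratio of 3."""
        grass = legend.code("grassland_pasture")
        hay = legend.code("other_hay")
        t = np.full((10, 10), TransitionClass.STABLE_NONCROP)
        t[:5] = TransitionClass.TO_CROP
        pre = np.where(t == TransitionClass.TO_CROP, grass, 0)
        tmap = make_tmap(t, pre_cover=pre)
        attach_current_cover(tmap, np.full((10, 10), hay))
        table = density_rows(("grassland_pasture", False, 30.0, 0.0),
                             ("other_hay", False, 10.0, 0.0))
        rep = milkweed_loss(tmap, np.zeros((10, 10), bool), table, legend)
        assert rep.density_ratio == pytest.approx(3.0)


class TestDuckAccessibility:
    CATS = {1: PairCategory(0, 20), 2: PairCategory(60, 80), 3: PairCategory(100, None)}

    def test_closed_range_midpoint(self):
        assert category_midpoints(self.CATS)[2] == 70.0

    def test_open_top_constant(self):
        assert category_midpoints(self.CATS)[3] == 110.0
        assert category_midpoints(self.CATS, open_top_value=150.0)[3] == 150.0

    def test_midpoint_operator_idempotent_and_order_preserving(self):
        mids = category_midpoints(self.CATS)
        ordered = [mids[k] for k in sorted(self.CATS, key=lambda k: self.CATS[k].low)]
        assert ordered == sorted(ordered)

    def test_two_open_top_categories_rejected(self):
        with pytest.raises(ValueError):
            category_midpoints({1: PairCategory(0, None), 2: PairCategory(5, None)})

    def test_stratum_means_and_sign_recovery(self):
        """Converted pixels drawn from uniformly higher categories score a
        higher mean accessibility than unconverted habitat."""
        t = np.full((4, 6), TransitionClass.STABLE_NONCROP)
        t[:2] = TransitionClass.TO_CROP
        cat = np.full((4, 6), 1)
        cat[:2] = 2  # converted land sits in the 60-80 category
        tmap = make_tmap(t)
        rep = duck_accessibility(tmap, cat, self.CATS)
        assert rep.mean_converted == 70.0
        assert rep.mean_unconverted == 10.0
        assert rep.mean_converted > rep.mean_unconverted
        # 12 px of one acre each = 12/640 sq mi at 70 pairs/sq mi
        assert rep.total_opportunities["converted"] == pytest.approx(70.0 * 12 / 640.0)

    def test_uncategorized_pixels_excluded_and_counted(self):
        t = np.full((2, 2), TransitionClass.TO_CROP)
        cat = np.array([[1, 99], [1, 1]])
        rep = duck_accessibility(make_tmap(t), cat, self.CATS)
        assert rep.excluded_pixels == 1
        assert rep.mean_converted == 10.0


class TestLongterm:
    def test_epoch_with_cultivation_excludes_pixel(self):
        epochs = np.zeros((2, 2, 2), dtype=int)
        epochs[0, 0, 0] = 81
        mask = longterm_mask(epochs)
        assert not mask[0, 0]
        assert mask[1, 1]

    def test_never_cultivated_across_four_epochs(self):
        epochs = np.full((4, 3, 3), 41)  # forest-like code throughout
        assert longterm_mask(epochs).all()

    def test_adding_epoch_only_shrinks_mask(self):
        rng = np.random.default_rng(0)
        epochs = rng.choice([41, 81, 82], size=(3, 8, 8))
        m3 = longterm_mask(epochs)
        extra = rng.choice([41, 81, 82], size=(1, 8, 8))
        m4 = longterm_mask(np.concatenate([epochs, extra]))
        assert (m4 <= m3).all()

    def test_tally_groups_by_pre_cover(self, legend):
        grass = legend.code("grassland_pasture")
        shrub = legend.code("shrubland")
        t = np.full((2, 4), TransitionClass.TO_CROP)
        pre = np.array([[grass, grass, shrub, shrub]] * 2)
        tmap = make_tmap(t, pre_cover=pre)
        tally = longterm_conversion_tally(tmap, np.ones((2, 4), bool), legend)
        by_cover = dict(zip(tally.pre_cover, tally.pixels))
        assert by_cover == {"grassland_pasture": 4, "shrubland": 4}


class TestZonalCharacteristics:
    def test_identical_grids_give_equal_means(self):
        t = np.full((4, 4), TransitionClass.STABLE_CROP)
        t[:2] = TransitionClass.TO_CROP
        grid = np.full((4, 4), 3.3)
        table = zonal_characteristics(make_tmap(t), {"slope": grid})
        means = table.set_index("stratum")["mean"]
        assert means["new_cropland"] == means["stable_cropland"] == pytest.approx(3.3)

    def test_planted_slope_ratio_recovered(self):
        t = np.full((10, 10), TransitionClass.STABLE_CROP)
        t[:5] = TransitionClass.TO_CROP
        slope = np.where(t == TransitionClass.TO_CROP, 4.0, 2.0)
        table = zonal_characteristics(make_tmap(t), {"slope": slope})
        m = table.set_index("stratum")["mean"]
        assert m["new_cropland"] / m["stable_cropland"] == pytest.approx(2.0)

    def test_hydric_reported_as_percentage(self):
        t = np.full((1, 10), TransitionClass.TO_CROP)
        hydric = np.zeros((1, 10))
        hydric[0, 0] = 1
        table = zonal_characteristics(make_tmap(t), {"hydric": hydric})
        row = table[(table.characteristic == "hydric") & (table.stratum == "new_cropland")]
        assert row["percent_flagged"].iloc[0] == pytest.approx(10.0)
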