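"""Transition classification, attribution, and refinement exclusions."""

import numpy as np
import pytest

from landtrax.legend import CROP, NONCROP, default_legend
from landtrax.transitions import (
    COVER_SENTINEL,
    RefinementRules,
    TransitionClass,
    TransitionMap,
    YEAR_SENTINEL,
    apply_refinements,
    attribute_conversion,
    classify_transitions,
    count_conversion_intervals,
    minimum_prior_duration,
)

from conftest import series_from_codes, uniform_sequence_traj

YEARS = list(range(2008, 2018))
EPOCH_YEARS = [2008, 2009]


def classify_seq(seq, epoch_groups=(NONCROP, NONCROP), shape=(1, 1)):
    traj = uniform_sequence_traj(seq, shape=shape)
    epochs = np.stack([np.full(shape, g, dtype=np.uint8) for g in epoch_groups])
    return classify_transitions(traj, epochs, EPOCH_YEARS, YEARS)


class TestClassify:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ((0, 0, 0, 0, 1, 1, 1, 1, 1, 1), TransitionClass.TO_CROP),
            ((1, 1, 1, 1, 0, 0, 0, 0, 0, 0), TransitionClass.TO_NONCROP),
            ((1, 0, 1, 0, 1, 0, 1, 0, 1, 0), TransitionClass.INTERMITTENT),
            ((0,) * 10, TransitionClass.STABLE_NONCROP),
            ((1,) * 10, TransitionClass.STABLE_CROP),
        ],
    )
    def test_rule_examples(self, seq, expected):
        epochs = (seq[0], seq[0])
        tmap = classify_seq(seq, epoch_groups=epochs)
        assert tmap.transition[0, 0] == expected

    def test_epoch_disagreement_blocks_conversion(self):
        """A single-switch trajectory whose prior epoch shows the new group is
        not a conversion; with >=2 crop years it falls back to intermittent."""
        seq = (0, 0, 0, 0, 1, 1, 1, 1, 1, 1)
        tmap = classify_seq(seq, epoch_groups=(NONCROP, CROP))
        assert tmap.transition[0, 0] == TransitionClass.INTERMITTENT
        assert tmap.conv_year[0, 0] == YEAR_SENTINEL

    def test_switch_too_close_to_start_is_not_conversion(self):
        seq = (0, 1, 1, 1, 1, 1, 1, 1, 1, 1)  # only one preceding year
        tmap = classify_seq(seq)
        assert tmap.transition[0, 0] != TransitionClass.TO_CROP

    def test_switch_too_close_to_end_is_not_conversion(self):
        seq = (0, 0, 0, 0, 0, 0, 0, 0, 0, 1)  # one succeeding year, one crop year
        tmap = classify_seq(seq)
        assert tmap.transition[0, 0] == TransitionClass.STABLE_NONCROP

    def test_multi_switch_single_crop_year_is_stable(self):
        seq = (0, 0, 0, 1, 0, 0, 0, 0, 0, 0)  # 2 switches but only 1 crop year
        tmap = classify_seq(seq)
        assert tmap.transition[0, 0] == TransitionClass.STABLE_NONCROP

    def test_conv_year_is_first_year_of_new_group(self):
        seq = (0, 0, 0, 0, 1, 1, 1, 1, 1, 1)  # switch at index 4
        tmap = classify_seq(seq)
        assert tmap.conv_year[0, 0] == YEARS[4] == 2012

    def test_excluded_sequence_is_masked(self):
        seq = (2,) * 10
        tmap = classify_seq(seq)
        assert tmap.transition[0, 0] == TransitionClass.MASKED

    def test_partition_is_exhaustive(self):
        rng = np.random.default_rng(3)
        from landtrax.trajectory import encode_trajectories

        stack = rng.integers(0, 2, size=(10, 15, 15)).astype(np.uint8)
        traj = encode_trajectories(stack)
        epochs = np.stack([stack[0], stack[1]])
        tmap = classify_transitions(traj, epochs, EPOCH_YEARS, YEARS)
        assert set(np.unique(tmap.transition)) <= {int(c) for c in TransitionClass}
        assert (tmap.transition != TransitionClass.MASKED).all()

    def test_single_switch_conversion_is_monotone_after_conv_year(self):
        """Every conversion pixel keeps its new group for all later years."""
        seq = (0, 0, 0, 1, 1, 1, 1, 1, 1, 1)
        tmap = classify_seq(seq)
        assert tmap.transition[0, 0] == TransitionClass.TO_CROP
        k = YEARS.index(int(tmap.conv_year[0, 0]))
        assert all(v == CROP for v in seq[k:])


class TestAttribution:
    def _tmap_and_series(self, pre_codes, post_code):
        legend = default_legend()
        rasters = np.zeros((10, 1, 1), dtype=np.int32)
        for t in range(10):
            if t < 4:
                rasters[t] = pre_codes[min(t, len(pre_codes) - 1)]
            else:
                rasters[t] = post_code
        series = series_from_codes(rasters, years=YEARS, legend=legend)
        seq = tuple(NONCROP if t < 4 else CROP for t in range(10))
        tmap = classify_seq(seq)
        return attribute_conversion(tmap, series), legend

    def test_pre_cover_mode_of_two_equal_years(self):
        legend = default_legend()
        grass = legend.code("grassland_pasture")
        corn = legend.code("corn")
        tmap, _ = self._tmap_and_series([grass, grass, grass, grass], corn)
        assert tmap.pre_cover[0, 0] == grass
        assert tmap.post_cover[0, 0] == corn

    def test_pre_cover_tie_breaks_to_latest_year(self):
        legend = default_legend()
        grass = legend.code("grassland_pasture")
        shrub = legend.code("shrubland")
        corn = legend.code("corn")
        rasters = np.zeros((10, 1, 1), dtype=np.int32)
        rasters[:4] = grass
        rasters[3] = shrub  # years k-2, k-1 = grass, shrub: no mode
        rasters[4:] = corn
        series = series_from_codes(rasters, years=YEARS, legend=legend)
        seq = tuple(NONCROP if t < 4 else CROP for t in range(10))
        tmap = attribute_conversion(classify_seq(seq), series)
        assert tmap.pre_cover[0, 0] == shrub

    def test_non_conversion_pixels_keep_sentinels(self):
        tmap = classify_seq((0,) * 10)
        series = series_from_codes(
            np.full((10, 1, 1), default_legend().code("grassland_pasture")), years=YEARS
        )
        out = attribute_conversion(tmap, series)
        assert out.pre_cover[0, 0] == COVER_SENTINEL
        assert out.conv_year[0, 0] == YEAR_SENTINEL


class TestRefinements:
    def _conversion_map(self, pre_name, post_name, cls=TransitionClass.TO_CROP):
        legend = default_legend()
        shape = (2, 2)
        return (
            TransitionMap(
                transition=np.full(shape, cls, dtype=np.uint8),
                conv_year=np.full(shape, 2012, dtype=np.int32),
                pre_cover=np.full(shape, legend.code(pre_name), dtype=np.int32),
                post_cover=np.full(shape, legend.code(post_name), dtype=np.int32),
            ),
            legend,
        )

    def test_grass_to_alfalfa_is_excluded(self):
        tmap, legend = self._conversion_map("grassland_pasture", "alfalfa")
        out, tallies = apply_refinements(tmap, RefinementRules(), legend)
        assert (out.transition == TransitionClass.STABLE_CROP).all()
        assert (out.conv_year == YEAR_SENTINEL).all()
        assert tallies["confusion_pair"] == 4

    def test_fallow_to_grass_abandonment_is_excluded(self):
        tmap, legend = self._conversion_map(
            "fallow_idle", "grassland_pasture", cls=TransitionClass.TO_NONCROP
        )
        out, _ = apply_refinements(tmap, RefinementRules(), legend)
        assert (out.transition == TransitionClass.STABLE_NONCROP).all()

    def test_developed_to_corn_is_excluded(self):
        tmap, legend = self._conversion_map("developed", "corn")
        out, tallies = apply_refinements(tmap, RefinementRules(), legend)
        assert (out.transition == TransitionClass.STABLE_CROP).all()
        assert tallies["developed_to_crop"] == 4

    def test_grass_to_corn_is_kept(self):
        tmap, legend = self._conversion_map("grassland_pasture", "corn")
        out, tallies = apply_refinements(tmap, RefinementRules(), legend)
        assert (out.transition == TransitionClass.TO_CROP).all()
        assert sum(tallies.values()) == 0

    def test_special_class_codes_are_configurable(self):
        tmap, legend = self._conversion_map("grassland_pasture", "wheat")
        rules = RefinementRules(special_class_codes={"rice_like": [legend.code("wheat")]})
        out, tallies = apply_refinements(tmap, rules, legend)
        assert (out.transition == TransitionClass.STABLE_CROP).all()
        assert tallies["special_class"] == 4


class TestRuleParameters:
    def test_annual_series_2008_2016_has_eight_conversion_intervals(self):
        assert count_conversion_intervals(list(range(2008, 2017))) == 8

    def test_minimum_prior_duration_with_sparse_epochs(self):
        """With annual years 2008-17 and epoch products 2001/2006/2011, an
        accepted conversion carries at least six years of prior evidence."""
        assert minimum_prior_duration(list(range(2008, 2018)), [2001, 2006, 2011]) == 6
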