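"""Five-class transition classification, attribution, and refinement rules.

A conversion between cropland and noncropland is a pixel observed in one
binary group for both of the two preceding annual years *and* the most recent
sparse-epoch products, then in the opposite group for the two succeeding
annual years, with exactly one switch over the whole annual record. Pixels
cropped in at least two annual years that switch more than once are
intermittent (rotational) cropland; everything else is stable. Conversions
between a year pair (y-1, y) are dated y — the first growing season showing
the new group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .legend import CROP, EXCLUDED, NONCROP, Legend
from .trajectory import LandcoverSeries, TrajectoryRaster

YEAR_SENTINEL = 0
COVER_SENTINEL = 0


class TransitionClass(IntEnum):
    MASKED = 0
    STABLE_NONCROP = 1
    STABLE_CROP = 2
    TO_CROP = 3
    TO_NONCROP = 4
    INTERMITTENT = 5


CONVERSION_CLASSES = (TransitionClass.TO_CROP, TransitionClass.TO_NONCROP)


@dataclass
class TransitionMap:
    """Per-pixel transition class with conversion attribution.

    ``conv_year``, ``pre_cover`` and ``post_cover`` hold the sentinel 0
    everywhere except on conversion pixels.
    """

    transition: np.ndarray  # uint8 of TransitionClass
    conv_year: np.ndarray  # int32 calendar year, 0 where none
    pre_cover: np.ndarray  # int32 legend code, 0 where none
    post_cover: np.ndarray  # int32 legend code, 0 where none
    pixel_size_m: float = 30.0
    qa_single_epoch: np.ndarray | None = None  # pixels accepted on one epoch only

    def __post_init__(self):
        shapes = {a.shape for a in (self.transition, self.conv_year, self.pre_cover, self.post_cover)}
        if len(shapes) != 1:
            raise ValueError("transition map bands are misaligned")

    @property
    def shape(self) -> tuple[int, int]:
        return self.transition.shape

    def conversion_mask(self) -> np.ndarray:
        return np.isin(self.transition, CONVERSION_CLASSES)

    def copy(self) -> "TransitionMap":
        return TransitionMap(
            transition=self.transition.copy(),
            conv_year=self.conv_year.copy(),
            pre_cover=self.pre_cover.copy(),
            post_cover=self.post_cover.copy(),
            pixel_size_m=self.pixel_size_m,
            qa_single_epoch=None if self.qa_single_epoch is None else self.qa_single_epoch.copy(),
        )


def _sequence_facts(seq: tuple[int, ...]) -> tuple[int, int, int]:
    """(n_switches, n_crop_years, first index of final group) for a 0/1 sequence."""
    switches = sum(1 for a, b in zip(seq, seq[1:]) if a != b)
    crop_years = sum(1 for v in seq if v == CROP)
    k = len(seq)
    for i in range(len(seq) - 1, -1, -1):
        if seq[i] != seq[-1]:
            break
        k = i
    return switches, crop_years, k


def _stable_of(group: int) -> TransitionClass:
    return TransitionClass.STABLE_CROP if group == CROP else TransitionClass.STABLE_NONCROP


def _majority_stable(seq: tuple[int, ...]) -> TransitionClass:
    crop_years = sum(1 for v in seq if v == CROP)
    return _stable_of(CROP if 2 * crop_years > len(seq) else NONCROP)


def _fallback_class(seq: tuple[int, ...]) -> TransitionClass:
    """Class for single-switch candidates that fail epoch or window checks.

    Conservative toward non-conversion: intermittent when the at-least-two
    crop-years rule is met, else the stable class of the majority group.
    """
    crop_years = sum(1 for v in seq if v == CROP)
    if crop_years >= 2:
        return TransitionClass.INTERMITTENT
    return _majority_stable(seq)


def classify_transitions(
    traj: TrajectoryRaster,
    epoch_stack: np.ndarray,
    epoch_years: list[int],
    years: list[int],
    pixel_size_m: float = 30.0,
) -> TransitionMap:
    """Reduce filtered trajectories to the five transition classes.

    ``epoch_stack`` is a (n_epochs, rows, cols) binary stack of the
    sparse-epoch products in ``epoch_years`` order. Single-switch candidates
    must agree with the two most recent epochs strictly before the switch
    year; where only one such epoch exists, it alone must agree and the pixel
    is flagged in ``qa_single_epoch``. Candidates failing the check fall back
    conservatively (see :func:`_fallback_class`).
    """
    if traj.n_years < 4:
        raise ValueError("classification needs at least 4 annual years")
    if len(epoch_years) != epoch_stack.shape[0]:
        raise ValueError("epoch_years must match epoch_stack layers")
    if epoch_stack.shape[1:] != traj.codes.shape:
        raise ValueError("epoch stack misaligned with trajectory grid")
    years = [int(y) for y in years]
    if len(years) != traj.n_years:
        raise ValueError("years must match trajectory length")

    n = traj.n_years
    rows, cols = traj.codes.shape
    transition = np.zeros((rows, cols), dtype=np.uint8)
    conv_year = np.zeros((rows, cols), dtype=np.int32)
    qa = np.zeros((rows, cols), dtype=bool)

    # classify each unique trajectory once; candidates get per-pixel epoch checks
    candidates: list[tuple[int, int, int, tuple[int, ...]]] = []  # (code, k, post_group, seq)
    code_class: dict[int, TransitionClass] = {}
    for code, seq in traj.code_book.items():
        if EXCLUDED in seq:
            code_class[code] = TransitionClass.MASKED
            continue
        switches, crop_years, k = _sequence_facts(seq)
        if switches == 0:
            code_class[code] = _stable_of(seq[0])
        elif switches == 1:
            if k >= 2 and n - k >= 2:
                candidates.append((code, k, seq[-1], seq))
                code_class[code] = TransitionClass.MASKED  # resolved below
            else:
                code_class[code] = _fallback_class(seq)
        else:
            if crop_years >= 2:
                code_class[code] = TransitionClass.INTERMITTENT
            else:
                code_class[code] = _majority_stable(seq)

    max_code = max(traj.code_book) if traj.code_book else 0
    lut = np.zeros(max_code + 1, dtype=np.uint8)
    for code, cls in code_class.items():
        lut[code] = cls
    transition = lut[traj.codes]

    for code, k, post_group, seq in candidates:
        pix = traj.codes == code
        if not pix.any():
            continue
        pre_group = seq[0]
        switch_year = years[k]
        prior = [i for i, ey in enumerate(epoch_years) if ey < switch_year]
        use = prior[-2:]
        if use:
            agree = np.ones((rows, cols), dtype=bool)
            for i in use:
                agree &= epoch_stack[i] == pre_group
        else:
            agree = np.zeros((rows, cols), dtype=bool)
        conv_cls = TransitionClass.TO_CROP if post_group == CROP else TransitionClass.TO_NONCROP
        ok = pix & agree
        transition[ok] = conv_cls
        conv_year[ok] = switch_year
        if len(use) == 1:
            qa[ok] = True
        fb = pix & ~agree
        transition[fb] = _fallback_class(seq)

    return TransitionMap(
        transition=transition,
        conv_year=conv_year,
        pre_cover=np.zeros((rows, cols), dtype=np.int32),
        post_cover=np.zeros((rows, cols), dtype=np.int32),
        pixel_size_m=pixel_size_m,
        qa_single_epoch=qa,
    )


def attribute_conversion(tmap: TransitionMap, series: LandcoverSeries) -> TransitionMap:
    """Fill pre/post cover for conversion pixels from the original series.

    pre_cover is the modal legend code over the two years preceding the
    switch, ties broken by the most recent year; post_cover is the code of the
    first post-switch year (the first planting).
    """
    out = tmap.copy()
    conv = out.conversion_mask()
    for year in np.unique(out.conv_year[conv]):
        k = series.year_index(int(year))
        sel = conv & (out.conv_year == year)
        a, b = series.rasters[k - 2], series.rasters[k - 1]
        # mode of a 2-year window with latest-year tie-break resolves to year k-1
        pre = np.where(a == b, a, b)
        out.pre_cover[sel] = pre[sel]
        out.post_cover[sel] = series.rasters[k][sel]
    return out


@dataclass
class RefinementRules:
    """Class-specific exclusions applied after attribution.

    ``confusion_crop`` x ``confusion_noncrop`` transitions are discarded in
    both directions: cultivated fallow and alfalfa (crop group) are frequently
    confused with non-alfalfa hay and grassland/pasture (noncrop group), so
    apparent conversions among the four are treated as classification noise.
    Developed land is never allowed to convert to cropland. ``special_class_codes``
    holds configurable extra code lists (e.g. perennial tree crops, rice) whose
    conversions are likewise discarded.
    """

    confusion_crop: frozenset[str] = frozenset({"fallow_idle", "alfalfa"})
    confusion_noncrop: frozenset[str] = frozenset({"other_hay", "grassland_pasture"})
    exclude_developed_to_crop: bool = True
    developed_names: frozenset[str] = frozenset({"developed"})
    special_class_codes: dict[str, list[int]] = field(default_factory=dict)

    def excluded_pairs(self) -> set[tuple[str, str]]:
        pairs = set()
        for a in self.confusion_crop:
            for b in self.confusion_noncrop:
                pairs.add((a, b))
                pairs.add((b, a))
        return pairs

    def is_excluded(self, pre_name: str, post_name: str, transition: TransitionClass) -> bool:
        if (pre_name, post_name) in self.excluded_pairs():
            return True
        return (
            self.exclude_developed_to_crop
            and transition == TransitionClass.TO_CROP
            and pre_name in self.developed_names
        )


def apply_refinements(
    tmap: TransitionMap, rules: RefinementRules, legend: Legend
) -> tuple[TransitionMap, dict[str, int]]:
    """Reassign excluded conversions to the stable class of their final group.

    Returns the refined map and a tally of reassigned pixels per rule.
    """
    out = tmap.copy()
    conv = out.conversion_mask()
    tallies = {"confusion_pair": 0, "developed_to_crop": 0, "special_class": 0}
    special = {c for codes in rules.special_class_codes.values() for c in codes}

    rr, cc = np.nonzero(conv)
    drop = np.zeros(len(rr), dtype=bool)
    for i, (r, c) in enumerate(zip(rr, cc)):
        pre = int(out.pre_cover[r, c])
        post = int(out.post_cover[r, c])
        cls = TransitionClass(out.transition[r, c])
        pre_name = legend.names.get(pre, f"code_{pre}")
        post_name = legend.names.get(post, f"code_{post}")
        if (pre_name, post_name) in rules.excluded_pairs():
            tallies["confusion_pair"] += 1
            drop[i] = True
        elif (
            rules.exclude_developed_to_crop
            and cls == TransitionClass.TO_CROP
            and pre_name in rules.developed_names
        ):
            tallies["developed_to_crop"] += 1
            drop[i] = True
        elif pre in special or post in special:
            tallies["special_class"] += 1
            drop[i] = True

    for r, c in zip(rr[drop], cc[drop]):
        cls = TransitionClass(out.transition[r, c])
        stable = TransitionClass.STABLE_CROP if cls == TransitionClass.TO_CROP else TransitionClass.STABLE_NONCROP
        out.transition[r, c] = stable
        out.conv_year[r, c] = YEAR_SENTINEL
        out.pre_cover[r, c] = COVER_SENTINEL
        out.post_cover[r, c] = COVER_SENTINEL
    return out, tallies


def count_conversion_intervals(years: list[int]) -> int:
    """Number of year-to-year conversion intervals in an annual series.

    A conversion between the growing seasons of y-1 and y is one interval
    labeled y, so an annual record spanning 2008-2016 yields eight.
    """
    years = sorted(int(y) for y in years)
    if len(years) < 2:
        return 0
    return len(years) - 1


def minimum_prior_duration(annual_years: list[int], epoch_years: list[int]) -> int:
    """Minimum years of prior opposite-group evidence the detection rule enforces.

    For each admissible conversion year (two preceding and two succeeding
    annual years, at least two prior epoch products), the evidence reaches
    back to the older of the two most recent prior epochs, or the first of the
    two preceding annual years if older. The minimum over admissible years is
    the shortest prior record any accepted conversion can have.
    """
    annual_years = sorted(int(y) for y in annual_years)
    epoch_years = sorted(int(y) for y in epoch_years)
    best = None
    for idx in range(2, len(annual_years) - 1):
        y = annual_years[idx]
        prior = [e for e in epoch_years if e < y]
        if len(prior) < 2:
            continue
        earliest = min(prior[-2], annual_years[idx - 2])
        duration = y - earliest
        best = duration if best is None else min(best, duration)
    if best is None:
        raise ValueError("no admissible conversion year with two prior epochs")
    return best
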