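"""Minimum-mapping-unit enforcement on the composite transition map.

Patches (connected components of equal transition class) smaller than the MMU
are removed simultaneously across all classes, and the resulting voids are
filled from the geometrically nearest surviving pixel, attributes included.
The MMU is applied to the multiyear composite of transition classes, not to
individual years: recently converted fields are often classified in mixed-year
salt-and-pepper patterns, and per-year filtering would fragment and lose them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import label as sk_label

from .transitions import TransitionMap

ACRE_M2 = 4046.8564224  # international acre


def pixel_threshold(mmu_acres: float, pixel_size_m: float) -> int:
    """Smallest pixel count n with n * pixel_area >= mmu_acres.

    Patches with fewer pixels are below the minimum mapping unit. Five acres
    at 30 m pixels gives 23.
    """
    if mmu_acres <= 0 or pixel_size_m <= 0:
        raise ValueError("mmu_acres and pixel_size_m must be positive")
    pixel_area = pixel_size_m**2
    return math.ceil(mmu_acres * ACRE_M2 / pixel_area)


@dataclass
class PatchLabeling:
    """Connected-component labeling of a transition map."""

    labels: np.ndarray  # int patch ids, 1-based
    patch_table: dict[int, tuple[int, int, float]]  # id -> (class, n_px, acres)
    connectivity: int  # 1 = 4-neighbor, 2 = 8-neighbor

    def sizes(self) -> dict[int, int]:
        return {pid: n for pid, (_, n, _) in self.patch_table.items()}


def label_patches(
    tmap: TransitionMap, connectivity: int = 2
) -> PatchLabeling:
    """Label connected components of equal transition class.

    ``connectivity=2`` (8-neighbor, the default) matches the 8-neighbor
    majority filter; ``connectivity=1`` gives 4-neighbor components.
    """
    labels = sk_label(tmap.transition, connectivity=connectivity, background=-1)
    pixel_acres = tmap.pixel_size_m**2 / ACRE_M2
    counts = np.bincount(labels.ravel())
    table = {}
    # one representative pixel per patch suffices for the class
    flat_cls = tmap.transition.ravel()
    flat_lbl = labels.ravel()
    first_idx = np.full(counts.shape[0], -1, dtype=np.int64)
    seen = np.zeros(counts.shape[0], dtype=bool)
    for i, lab in enumerate(flat_lbl):
        if not seen[lab]:
            seen[lab] = True
            first_idx[lab] = i
    for pid in range(1, counts.shape[0]):
        n = int(counts[pid])
        if n == 0:
            continue
        cls = int(flat_cls[first_idx[pid]])
        table[pid] = (cls, n, n * pixel_acres)
    return PatchLabeling(labels=labels, patch_table=table, connectivity=connectivity)


class AllPatchesRemovedError(ValueError):
    """Every patch fell below the MMU; there is nothing to fill from."""


def enforce_mmu(
    tmap: TransitionMap,
    min_px: int,
    connectivity: int = 2,
    max_iter: int = 100,
) -> TransitionMap:
    """Remove sub-MMU patches and fill voids from the nearest surviving pixel.

    Removal is simultaneous across all classes before any fill, so a void can
    never be filled from a patch that is itself below threshold. Conversion
    attributes (year, pre/post cover) are copied from the fill source, keeping
    attribution consistent. The remove-and-fill pass repeats until no patch is
    below threshold (almost always a single pass), which makes the operation
    idempotent by construction.
    """
    if min_px < 1:
        raise ValueError("min_px must be >= 1")
    out = tmap.copy()
    for _ in range(max_iter):
        labeling = label_patches(out, connectivity=connectivity)
        small = [pid for pid, (_, n, _) in labeling.patch_table.items() if n < min_px]
        if not small:
            return out
        if len(labeling.patch_table) == 1:
            return out  # a lone patch is trivially nearest to itself
        if len(small) == len(labeling.patch_table):
            raise AllPatchesRemovedError(
                f"all {len(small)} patches are below the {min_px}-pixel MMU"
            )
        void = np.isin(labeling.labels, small)
        # nearest surviving pixel for every void pixel (Euclidean distance,
        # deterministic tie resolution by the transform's fixed scan order)
        _, (src_r, src_c) = ndimage.distance_transform_edt(void, return_indices=True)
        for band in (out.transition, out.conv_year, out.pre_cover, out.post_cover):
            band[void] = band[src_r[void], src_c[void]]
    raise RuntimeError("MMU enforcement did not converge")
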