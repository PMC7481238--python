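"""Binary consolidation, trajectory encoding, and the majority spatial filter.

The detection approach collapses each annual legend raster to crop/noncrop,
stacks the years into a per-pixel *trajectory* (the full temporal pattern as a
single categorical value), and smooths that composite once with an 8-neighbor
majority filter. Filtering the multiyear composite — rather than each year —
removes isolated space-time anomalies coherently: a pixel flipped in a single
year differs from its neighbors over the whole trajectory, so one spatial pass
on the composite repairs it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .legend import CROP, EXCLUDED, NONCROP, Legend, UnmappedCodeError


@dataclass
class LandcoverSeries:
    """Aligned stack of annual categorical land-cover rasters.

    ``rasters`` has shape (n_years, rows, cols) of integer legend codes.
    """

    years: list[int]
    rasters: np.ndarray
    legend: Legend
    pixel_size_m: float = 30.0

    def __post_init__(self):
        self.years = [int(y) for y in self.years]
        if any(b <= a for a, b in zip(self.years, self.years[1:])):
            raise ValueError("years must be strictly increasing")
        if self.rasters.ndim != 3 or self.rasters.shape[0] != len(self.years):
            raise ValueError("rasters must be (n_years, rows, cols) matching years")

    @property
    def shape(self) -> tuple[int, int]:
        return self.rasters.shape[1:]

    @property
    def n_years(self) -> int:
        return len(self.years)

    def year_index(self, year: int) -> int:
        return self.years.index(year)


def reclassify_binary(series: LandcoverSeries) -> np.ndarray:
    """Collapse legend codes to {0=noncrop, 1=crop, 2=excluded} per year.

    Raises :class:`UnmappedCodeError` listing any code present in the rasters
    but absent from the legend's binary map.
    """
    groups = series.legend.groups
    observed = np.unique(series.rasters)
    unmapped = [int(c) for c in observed if int(c) not in groups]
    if unmapped:
        counts = {c: int((series.rasters == c).sum()) for c in unmapped}
        raise UnmappedCodeError(counts)
    lut_size = int(observed.max()) + 1
    lut = np.full(lut_size, EXCLUDED, dtype=np.uint8)
    for code, grp in groups.items():
        if code < lut_size:
            lut[code] = grp
    return lut[series.rasters]


@dataclass
class TrajectoryRaster:
    """Per-pixel trajectory codes plus the code -> binary-sequence book."""

    codes: np.ndarray  # (rows, cols) int
    code_book: dict[int, tuple[int, ...]]
    n_years: int

    def __post_init__(self):
        bad = [c for c, seq in self.code_book.items() if len(seq) != self.n_years]
        if bad:
            raise ValueError(f"code_book sequences with wrong length: {bad}")

    def sequence_stack(self) -> np.ndarray:
        """Expand codes back to a (n_years, rows, cols) binary stack."""
        max_code = max(self.code_book) if self.code_book else 0
        lut = np.zeros((max_code + 1, self.n_years), dtype=np.uint8)
        for c, seq in self.code_book.items():
            lut[c] = seq
        return np.moveaxis(lut[self.codes], -1, 0)

    def excluded_codes(self) -> set[int]:
        """Codes whose sequences touch the excluded group in any year."""
        return {c for c, seq in self.code_book.items() if EXCLUDED in seq}


def encode_trajectories(binary_stack: np.ndarray) -> TrajectoryRaster:
    """Assign one integer code to each distinct per-pixel year-sequence.

    Two pixels share a code iff their full crop/noncrop sequences are
    identical; the code book is invertible by construction.
    """
    if binary_stack.ndim != 3 or binary_stack.shape[0] < 2:
        raise ValueError("binary stack must be (>=2 years, rows, cols)")
    n_years, rows, cols = binary_stack.shape
    flat = binary_stack.reshape(n_years, -1).T  # (n_px, n_years)
    uniq, inverse = np.unique(flat, axis=0, return_inverse=True)
    codes = inverse.reshape(rows, cols).astype(np.int32)
    code_book = {i: tuple(int(v) for v in row) for i, row in enumerate(uniq)}
    return TrajectoryRaster(codes=codes, code_book=code_book, n_years=n_years)


_NEIGHBOR_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def majority_filter(traj: TrajectoryRaster, passes: int = 1) -> TrajectoryRaster:
    """8-neighbor majority filter with a one-half replacement threshold.

    A pixel's code is replaced by v iff v differs from the center and v
    occupies at least ceil(valid/2) of the valid 8-neighbors, where valid
    neighbors are those inside the grid and not in the excluded group. Ties
    between two qualifying values go to the smaller code. Excluded-group
    pixels pass through unchanged and never count toward a majority. Single
    pass by default; ``passes`` exposes optional iteration.
    """
    codes = traj.codes
    if codes.shape[0] < 3 or codes.shape[1] < 3:
        raise ValueError("majority filter needs a grid of at least 3x3")
    excl = traj.excluded_codes()
    out = codes
    for _ in range(passes):
        out = _majority_pass(out, excl)
    return TrajectoryRaster(codes=out, code_book=dict(traj.code_book), n_years=traj.n_years)


def _majority_pass(codes: np.ndarray, excluded: set[int]) -> np.ndarray:
    rows, cols = codes.shape
    out = codes.copy()
    excl_mask = np.isin(codes, sorted(excluded)) if excluded else np.zeros_like(codes, bool)
    for r in range(rows):
        for c in range(cols):
            center = codes[r, c]
            if excl_mask[r, c]:
                continue
            counts: dict[int, int] = {}
            valid = 0
            for dr, dc in _NEIGHBOR_OFFSETS:
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols and not excl_mask[rr, cc]:
                    valid += 1
                    v = codes[rr, cc]
                    counts[v] = counts.get(v, 0) + 1
            if valid == 0:
                continue
            threshold = math.ceil(valid / 2)
            best = None
            for v, n in counts.items():
                if v != center and n >= threshold:
                    if best is None or v < best:
                        best = v
            if best is not None:
                out[r, c] = best
    return out
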