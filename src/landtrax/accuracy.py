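"""Per-pixel expected accuracy of detected conversions.

Each converted pixel's expected accuracy multiplies two superclass accuracies
(the probability the pixel was correctly labeled at the broad crop/noncrop
level for its zone and specific land-cover class): that of the post-conversion
class in the year of conversion, and that of the pre-conversion class in the
year before:

    expected_accuracy = SA(zone, post_cover, yoc) * SA(zone, pre_cover, yoc - 1)
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .raster import check_aligned
from .transitions import TransitionMap


class MissingAccuracyError(KeyError):
    """Lookups required by the transition map are absent from the SA table."""

    def __init__(self, keys):
        self.keys = sorted(keys)
        preview = ", ".join(map(str, self.keys[:10]))
        more = "" if len(self.keys) <= 10 else f" (+{len(self.keys) - 10} more)"
        super().__init__(f"superclass accuracies missing for: {preview}{more}")


def load_accuracy_table(df: pd.DataFrame) -> dict[tuple[int, int, int | None], float]:
    """Index an SA table by (zone, class code, year); year may be null (pooled).

    Accuracies must lie in [0, 1].
    """
    table: dict[tuple[int, int, int | None], float] = {}
    for r in df.itertuples(index=False):
        sa = float(r.sa)
        if not 0.0 <= sa <= 1.0:
            raise ValueError(f"superclass accuracy out of [0,1]: {sa}")
        year = None if pd.isna(r.year) else int(r.year)
        table[(int(r.zone), int(getattr(r, "cover_class")), year)] = sa
    return table


def _lookup(table, zone: int, cls: int, year: int) -> float | None:
    v = table.get((zone, cls, year))
    if v is None:
        v = table.get((zone, cls, None))  # pooled across years
    return v


def expected_accuracy(
    tmap: TransitionMap, table_df: pd.DataFrame, zone_raster: np.ndarray
) -> np.ndarray:
    """Expected conversion accuracy per pixel; NaN on non-conversion pixels.

    Raises :class:`MissingAccuracyError` listing every (zone, class, year)
    lookup the table cannot serve.
    """
    check_aligned(tmap.transition, zone_raster)
    table = load_accuracy_table(table_df)
    out = np.full(tmap.shape, np.nan)
    conv = tmap.conversion_mask()
    missing = set()
    keys = np.stack(
        [zone_raster, tmap.post_cover, tmap.pre_cover, tmap.conv_year], axis=-1
    )[conv]
    combos, inverse = np.unique(keys, axis=0, return_inverse=True)
    values = np.full(len(combos), np.nan)
    for i, (zone, post, pre, yoc) in enumerate(combos):
        sa_post = _lookup(table, int(zone), int(post), int(yoc))
        sa_pre = _lookup(table, int(zone), int(pre), int(yoc) - 1)
        if sa_post is None:
            missing.add((int(zone), int(post), int(yoc)))
        if sa_pre is None:
            missing.add((int(zone), int(pre), int(yoc) - 1))
        if sa_post is not None and sa_pre is not None:
            values[i] = sa_post * sa_pre
    if missing:
        raise MissingAccuracyError(missing)
    out[conv] = values[inverse]
    return out


def accuracy_summary(acc: np.ndarray, tmap: TransitionMap, legend=None) -> pd.DataFrame:
    """Mean expected accuracy per post-conversion class."""
    conv = tmap.conversion_mask() & np.isfinite(acc)
    rows = []
    for code in np.unique(tmap.post_cover[conv]):
        sel = conv & (tmap.post_cover == code)
        name = legend.names.get(int(code), f"code_{int(code)}") if legend else f"code_{int(code)}"
        rows.append({"post_cover": name, "pixels": int(sel.sum()),
                     "mean_expected_accuracy": float(acc[sel].mean())})
    return pd.DataFrame(rows)
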