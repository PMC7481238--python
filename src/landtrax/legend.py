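"""Land-cover legends and the crop/noncrop/excluded consolidation map.

A legend maps integer raster codes to class names and to one of three binary
groups: ``crop`` (cultivated row, closely grown, or horticultural crops,
including cultivated fallow and alfalfa), ``noncrop`` (everything else on the
land surface), and ``excluded`` (codes such as open water that never take part
in the crop/noncrop trajectory analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

# binary group codes used throughout the pipeline
NONCROP = 0
CROP = 1
EXCLUDED = 2

GROUP_NAMES = {NONCROP: "noncrop", CROP: "crop", EXCLUDED: "excluded"}
GROUP_CODES = {v: k for k, v in GROUP_NAMES.items()}


class UnmappedCodeError(KeyError):
    """A raster contains codes absent from the legend's binary map."""

    def __init__(self, codes_and_counts: dict[int, int]):
        self.codes_and_counts = dict(codes_and_counts)
        msg = ", ".join(f"code {c} ({n} px)" for c, n in sorted(codes_and_counts.items()))
        super().__init__(f"raster codes missing from binary map: {msg}")


@dataclass(frozen=True)
class Legend:
    """Code -> name and code -> binary group mapping for a categorical raster."""

    names: dict[int, str]
    groups: dict[int, int]  # code -> NONCROP | CROP | EXCLUDED
    nodata: int = 0

    def __post_init__(self):
        missing = set(self.names) ^ set(self.groups)
        if missing:
            raise ValueError(f"legend names/groups disagree on codes {sorted(missing)}")
        bad = {c: g for c, g in self.groups.items() if g not in GROUP_NAMES}
        if bad:
            raise ValueError(f"invalid binary groups: {bad}")

    def name(self, code: int) -> str:
        return self.names[code]

    def code(self, name: str) -> int:
        for c, n in self.names.items():
            if n == name:
                return c
        raise KeyError(name)

    def group(self, code: int) -> int:
        return self.groups[code]

    def codes_in_group(self, group: int) -> list[int]:
        return sorted(c for c, g in self.groups.items() if g == group)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"code": c, "name": self.names[c], "group": GROUP_NAMES[self.groups[c]]}
            for c in sorted(self.names)
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, nodata: int = 0) -> "Legend":
        names = {int(r.code): str(r.name) for r in df.itertuples(index=False)}
        groups = {int(r.code): GROUP_CODES[str(r.group)] for r in df.itertuples(index=False)}
        return cls(names=names, groups=groups, nodata=nodata)

    @classmethod
    def from_csv(cls, path, nodata: int = 0) -> "Legend":
        return cls.from_frame(pd.read_csv(path), nodata=nodata)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def default_legend() -> Legend:
    """A compact CDL-like legend used by the synthetic scene generator.

    Codes follow the Cropland Data Layer numbering where a direct analogue
    exists. ``fallow_idle`` and ``alfalfa`` sit in the crop group; ``other_hay``
    and ``grassland_pasture`` in the noncrop group — the four classes whose
    mutual transitions are excluded by the refinement rules.
    """
    names = {
        1: "corn",
        5: "soybeans",
        24: "wheat",
        36: "alfalfa",
        61: "fallow_idle",
        37: "other_hay",
        111: "open_water",
        121: "developed",
        141: "forest",
        152: "shrubland",
        176: "grassland_pasture",
        195: "wetlands",
    }
    groups = {
        1: CROP,
        5: CROP,
        24: CROP,
        36: CROP,
        61: CROP,
        37: NONCROP,
        111: EXCLUDED,
        121: NONCROP,
        141: NONCROP,
        152: NONCROP,
        176: NONCROP,
        195: NONCROP,
    }
    return Legend(names=names, groups=groups)
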