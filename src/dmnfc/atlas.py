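"""The 22-region default-mode-network ROI atlas.

The packaged default atlas lists the 22 DMN nodes (dorsal DMN, ventral DMN
and precuneus subnetworks) with their MNI centre coordinates and Brodmann
areas.  In ROI-time-series mode the atlas fixes node order and naming; in
volume mode each ROI is a 6 mm-radius sphere around its MNI centre.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

N_DMN_ROIS = 22

_COLUMNS = ["number", "name", "region", "subnetwork", "ba", "x", "y", "z"]


@dataclass(frozen=True)
class RoiAtlas:
    """Ordered ROI table: index (1-based), name, subnetwork, BA, MNI mm."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in _COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"atlas table missing columns: {missing}")
        if len(t) != N_DMN_ROIS:
            raise ValueError(
                f"atlas must define exactly {N_DMN_ROIS} ROIs, got {len(t)}"
            )
        if t["number"].duplicated().any() or t["name"].duplicated().any():
            raise ValueError("atlas ROI numbers and names must be unique")
        if sorted(t["number"]) != list(range(1, N_DMN_ROIS + 1)):
            raise ValueError("atlas ROI numbers must be 1..22")
        if t[["x", "y", "z"]].isna().any().any():
            raise ValueError("atlas has missing MNI coordinates")

    @property
    def n_rois(self) -> int:
        return len(self.table)

    @property
    def names(self) -> list[str]:
        return list(self.table["name"])

    def roi(self, number: int) -> pd.Series:
        """Return the atlas row for 1-based ROI ``number``."""
        row = self.table[self.table["number"] == number]
        if row.empty:
            raise KeyError(f"no ROI numbered {number}")
        return row.iloc[0]


def load_atlas(path: str | Path | None = None) -> RoiAtlas:
    """Load an ROI atlas TSV; with no argument, the packaged 22-ROI DMN atlas.

    The TSV must carry columns number, name, region, subnetwork, ba, x, y, z
    (and optionally radius_mm, defaulting to 6 mm spheres for volume mode).
    """
    if path is None:
        src = resources.files("dmnfc").joinpath("data/dmn_atlas_22.tsv")
        with resources.as_file(src) as p:
            table = pd.read_csv(p, sep="\t", dtype={"ba": "string"})
    else:
        table = pd.read_csv(path, sep="\t", dtype={"ba": "string"})
    if "radius_mm" not in table.columns:
        table["radius_mm"] = 6.0
    table = table.sort_values("number", kind="stable").reset_index(drop=True)
    return RoiAtlas(table)
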