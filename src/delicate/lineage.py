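"""Per-time-point nucleus records with parent links (CD-file-like tables).

A :class:`LineageTable` is the shared currency between the embryo simulator,
the tracker and the error classifier: one row per nucleus per time point,
with the cell's name, its parent's name (set on the first frame of a
daughter), its physical position and radius in micrometres, and a relative
brightness factor in (0, 1] that models lineage-specific marker dimness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: CSV column order; shared with the simulator's fixture writer.
COLUMNS = [
    "time",
    "cell",
    "parent",
    "x_um",
    "y_um",
    "z_um",
    "radius_um",
    "intensity_factor",
]


@dataclass
class LineageTable:
    """A table of nucleus records over time.

    Parameters
    ----------
    df : pandas.DataFrame
        Must contain :data:`COLUMNS`.  ``parent`` is the empty string for
        founder cells; it is only meaningful on the first frame in which a
        cell appears.
    """

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=COLUMNS))

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"LineageTable missing columns: {missing}")
        self.df = self.df[COLUMNS].reset_index(drop=True)
        self.df["time"] = self.df["time"].astype(int)
        self.df["parent"] = self.df["parent"].fillna("").astype(str)

    # -- accessors ---------------------------------------------------------
    def at_time(self, t: int) -> pd.DataFrame:
        return self.df[self.df["time"] == t]

    def times(self) -> np.ndarray:
        return np.sort(self.df["time"].unique())

    def cell_count(self, t: int) -> int:
        return int((self.df["time"] == t).sum())

    def positions(self, t: int) -> np.ndarray:
        """(n, 3) array of positions at ``t`` in (z, y, x) µm order."""
        sub = self.at_time(t)
        return sub[["z_um", "y_um", "x_um"]].to_numpy(dtype=float)

    def radii(self, t: int) -> np.ndarray:
        return self.at_time(t)["radius_um"].to_numpy(dtype=float)

    def lifespan(self, cell: str) -> tuple[int, int]:
        sub = self.df[self.df["cell"] == cell]
        if sub.empty:
            raise KeyError(cell)
        return int(sub["time"].min()), int(sub["time"].max())

    def parent_of(self, cell: str) -> str:
        sub = self.df[(self.df["cell"] == cell) & (self.df["parent"] != "")]
        if sub.empty:
            return ""
        return str(sub["parent"].iloc[0])

    def divisions(self) -> list[tuple[str, int, tuple[str, str]]]:
        """All divisions as (parent, daughter birth time, (d1, d2))."""
        births = self.df[self.df["parent"] != ""]
        out = []
        for (parent, t), grp in births.groupby(["parent", "time"]):
            names = sorted(grp["cell"].tolist())
            if len(names) == 2:
                out.append((str(parent), int(t), (names[0], names[1])))
        return sorted(out, key=lambda r: (r[1], r[0]))

    def are_sisters(self, a: str, b: str) -> bool:
        pa, pb = self.parent_of(a), self.parent_of(b)
        return pa != "" and pa == pb

    # -- IO ----------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LineageTable":
        df = pd.read_csv(path, keep_default_na=False, dtype={"cell": str, "parent": str})
        return cls(df)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LineageTable):
            return NotImplemented
        return self.df.equals(other.df)
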