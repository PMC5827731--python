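"""Turbidity phase diagrams for liquid–liquid phase separation assays.

A two-component LLPS experiment titrates one macromolecule against a partner
(an R-motif protein, rRNA, or a crowding agent) on a concentration grid and
reads the absorbance at 340 nm (A340) of each sample: demixing into droplets
scatters light and raises the apparent absorbance.  This module turns those
replicate A340 readings into a mixed/demixed classification per grid point,
extracts the phase boundary as a polyline on the grid, and reports threshold
concentrations for phase separation.

Classification is intentionally simple and transparent: a grid point is
*demixed* iff its mean blank-subtracted A340 is at or above a turbidity
threshold (default 0.05 absorbance units above blank, configurable).  The
boundary is reported on the tested grid only — no interpolation between grid
points is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_A340_THRESHOLD",
    "TurbidityMeasurement",
    "PhaseDiagram",
    "classify",
    "extract_boundary",
    "threshold_concentration",
    "read_turbidity_csv",
]

#: Default demixing threshold: mean blank-subtracted A340 at or above this
#: value is scored as demixed.  Chosen to sit well above spectrophotometer
#: read noise (~0.01 AU) yet far below the turbidity of a demixed sample.
DEFAULT_A340_THRESHOLD = 0.05


@dataclass(frozen=True)
class TurbidityMeasurement:
    """One replicate A340 reading at a grid point (c_x, c_y).

    ``a340`` is the blank-subtracted absorbance; negative values arising from
    blank subtraction are clipped to zero on construction.
    """

    c_x: float
    c_y: float
    a340: float
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.c_x < 0 or self.c_y < 0:
            raise ValueError("concentrations must be >= 0")
        if self.a340 < 0:
            object.__setattr__(self, "a340", 0.0)


@dataclass
class PhaseDiagram:
    """Classified turbidity grid.

    ``table`` holds one row per tested grid point with columns
    ``c_x, c_y, mean_a340, n_replicates, demixed``.  Untested cells simply do
    not appear and are excluded from all boundary logic.
    """

    table: pd.DataFrame = field(repr=False)
    threshold: float

    @property
    def demixed(self) -> pd.DataFrame:
        return self.table[self.table["demixed"]]

    @property
    def mixed(self) -> pd.DataFrame:
        return self.table[~self.table["demixed"]]


def classify(
    points: Sequence[TurbidityMeasurement],
    threshold: float = DEFAULT_A340_THRESHOLD,
) -> PhaseDiagram:
    """Average replicates per grid point and classify each point.

    A point is demixed iff its replicate-mean blank-subtracted A340 is
    >= ``threshold`` (inclusive rule).  Raises on empty input.
    """
    if len(points) == 0:
        raise ValueError("no turbidity measurements supplied")
    df = pd.DataFrame(
        {"c_x": [p.c_x for p in points], "c_y": [p.c_y for p in points],
         "a340": [p.a340 for p in points]}
    )
    grouped = (
        df.groupby(["c_x", "c_y"], as_index=False)
        .agg(mean_a340=("a340", "mean"), n_replicates=("a340", "size"))
    )
    grouped["demixed"] = grouped["mean_a340"] >= threshold
    return PhaseDiagram(table=grouped, threshold=threshold)


def extract_boundary(diagram: PhaseDiagram, axis: Literal["x", "y"] = "y") -> pd.DataFrame:
    """Phase boundary as a polyline on the tested grid.

    For ``axis="y"``: for each tested c_x value, the lowest c_y classified as
    demixed (rows with no demixed point are omitted).  ``axis="x"`` is the
    symmetric per-column scan.  An all-mixed diagram yields an empty polyline.
    """
    dem = diagram.demixed
    if dem.empty:
        return pd.DataFrame(columns=["c_x", "c_y"])
    scan, other = ("c_x", "c_y") if axis == "y" else ("c_y", "c_x")
    idx = dem.groupby(scan)[other].idxmin()
    out = dem.loc[idx, ["c_x", "c_y"]].sort_values(scan).reset_index(drop=True)
    return out


class NoPhaseSeparationError(ValueError):
    """Raised when no grid point demixes in the tested concentration range."""


def threshold_concentration(diagram: PhaseDiagram, axis: Literal["x", "y"] = "x") -> float:
    """Minimum concentration along ``axis`` at which any tested point is demixed.

    This is the assay's "threshold concentration for phase separation" along
    one component's axis.  Raises :class:`NoPhaseSeparationError` when the
    whole tested grid is mixed.
    """
    dem = diagram.demixed
    if dem.empty:
        raise NoPhaseSeparationError("no phase separation in tested concentration range")
    col = "c_x" if axis == "x" else "c_y"
    return float(dem[col].min())


def read_turbidity_csv(path: str | Path, blank_column: str = "blank") -> list[TurbidityMeasurement]:
    """Read a turbidity CSV with columns ``c_x, c_y, replicate, A340[, blank]``.

    When a blank column is present, it is subtracted row-wise (negatives clip
    to zero).  A ``construct`` column, if present, is ignored here; filter the
    frame upstream to analyse one construct at a time.
    """
    df = pd.read_csv(path)
    a340 = df["A340"].to_numpy(dtype=float)
    if blank_column in df.columns:
        a340 = a340 - df[blank_column].to_numpy(dtype=float)
    rep = df["replicate"].to_numpy() if "replicate" in df.columns else np.zeros(len(df), int)
    return [
        TurbidityMeasurement(c_x=float(x), c_y=float(y), a340=float(max(a, 0.0)), replicate=int(r))
        for x, y, a, r in zip(df["c_x"], df["c_y"], a340, rep)
    ]
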