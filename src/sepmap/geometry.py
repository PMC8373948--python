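"""Electrode geometries: epidural μECoG grid and laminar silicon probe.

Coordinate conventions used throughout the package:

* Grid recordings live in a planar frame with ``x`` increasing caudally and
  ``y`` increasing medially, both in μm. Rows are lettered A.. starting at the
  caudal edge; columns are numbered 1.. starting at the medial edge. The hull
  of the default 6 × 10 grid at 400 μm pitch is 2.0 × 3.6 mm.
* Polar displacements derived from this frame use θ = atan2(Δy, Δx), so
  0° points caudal, +90° medial and −90° lateral.
* Laminar probes are indexed from the most superficial site; ``depths`` are
  μm below the cortical surface, increasing with depth.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridGeometry", "ProbeGeometry"]


@dataclass(frozen=True)
class GridGeometry:
    """Regular planar electrode grid (rows × columns at a fixed pitch)."""

    n_rows: int = 6
    n_cols: int = 10
    pitch: float = 400.0  # μm
    row_axis_label: str = "caudal->rostral"
    col_axis_label: str = "medial->lateral"

    def __post_init__(self) -> None:
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("grid needs at least 2 rows and 2 columns")
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")

    @property
    def n_channels(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def channel_ids(self) -> list[str]:
        """Row letter + column number, row-major: A1, A2, ... F10."""
        letters = string.ascii_uppercase
        return [
            f"{letters[r]}{c + 1}"
            for r in range(self.n_rows)
            for c in range(self.n_cols)
        ]

    def rowcol(self, index: int) -> tuple[int, int]:
        return divmod(index, self.n_cols)

    @property
    def positions(self) -> np.ndarray:
        """(n_channels, 2) array of (x_caudal, y_medial) in μm.

        Row A (index 0) is the caudal-most row, column 1 (index 0) the
        medial-most column, so both coordinates decrease with index and the
        hull spans [0, (n_rows−1)·pitch] × [0, (n_cols−1)·pitch].
        """
        rows, cols = np.divmod(np.arange(self.n_channels), self.n_cols)
        x = (self.n_rows - 1 - rows) * self.pitch
        y = (self.n_cols - 1 - cols) * self.pitch
        return np.column_stack([x, y]).astype(float)

    @property
    def hull_extent(self) -> tuple[float, float]:
        """(x span, y span) of the electrode hull in μm."""
        return ((self.n_rows - 1) * self.pitch, (self.n_cols - 1) * self.pitch)

    @property
    def hull_center(self) -> tuple[float, float]:
        ex, ey = self.hull_extent
        return (ex / 2.0, ey / 2.0)

    def neighbors4(self, index: int) -> list[int]:
        """Indices of the 4-neighborhood (N/S/E/W on the grid)."""
        r, c = self.rowcol(index)
        out = []
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < self.n_rows and 0 <= cc < self.n_cols:
                out.append(rr * self.n_cols + cc)
        return out

    def to_dict(self) -> dict:
        return {
            "kind": "grid",
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "pitch_um": self.pitch,
            "row_axis_label": self.row_axis_label,
            "col_axis_label": self.col_axis_label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridGeometry":
        return cls(
            n_rows=int(d["n_rows"]),
            n_cols=int(d["n_cols"]),
            pitch=float(d["pitch_um"]),
            row_axis_label=d.get("row_axis_label", "caudal->rostral"),
            col_axis_label=d.get("col_axis_label", "medial->lateral"),
        )


@dataclass(frozen=True)
class ProbeGeometry:
    """Linear laminar probe with uniformly spaced recording sites."""

    n_sites: int = 16
    site_spacing: float = 50.0  # μm
    insertion_depth: float = 800.0  # μm below surface, deepest site

    def __post_init__(self) -> None:
        if self.n_sites < 3:
            raise ValueError(
                "a laminar probe needs at least 3 sites (CSD requires "
                "interior sites)"
            )
        if self.site_spacing <= 0:
            raise ValueError("site_spacing must be positive")

    @property
    def n_channels(self) -> int:
        return self.n_sites

    @property
    def channel_ids(self) -> list[str]:
        return [f"D{i + 1}" for i in range(self.n_sites)]

    @property
    def depths(self) -> np.ndarray:
        """Site depths in μm, most superficial site first."""
        i = np.arange(self.n_sites)
        return self.insertion_depth - (self.n_sites - 1 - i) * self.site_spacing

    def to_dict(self) -> dict:
        return {
            "kind": "probe",
            "n_sites": self.n_sites,
            "site_spacing_um": self.site_spacing,
            "insertion_depth_um": self.insertion_depth,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProbeGeometry":
        return cls(
            n_sites=int(d["n_sites"]),
            site_spacing=float(d["site_spacing_um"]),
            insertion_depth=float(d["insertion_depth_um"]),
        )


def geometry_from_dict(d: dict):
    kind = d.get("kind")
    if kind == "grid":
        return GridGeometry.from_dict(d)
    if kind == "probe":
        return ProbeGeometry.from_dict(d)
    raise ValueError(f"unknown geometry kind: {kind!r}")
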