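"""Geometry of the CMOS microelectrode array.

The recording substrate is a planar array of microelectrodes on a regular
rectangular lattice.  The default dimensions follow the high-density CMOS
device used throughout this package: 26,400 electrodes in a 220 x 120 grid
at 17.5 um pitch, covering a 3.85 mm x 2.1 mm sensing area.  Every spatial
quantity downstream (proximity areas, distance rings, stimulation-site
separations) derives from :class:`ElectrodeGrid`.

Electrodes are addressed by 0-based ``(col, row)`` integer pairs with the
column index running along the long (220-electrode) axis.  All physical
distances are Euclidean and expressed in micrometres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import numpy as np

#: An electrode address: 0-based (col, row).
ElectrodeId = Tuple[int, int]


@dataclass(frozen=True)
class ElectrodeGrid:
    """Regular rectangular electrode lattice.

    Parameters
    ----------
    n_cols
        Electrode count along the long axis (default 220).
    n_rows
        Electrode count along the short axis (default 120).
    pitch_um
        Centre-to-centre inter-electrode spacing in micrometres
        (default 17.5).
    """

    n_cols: int = 220
    n_rows: int = 120
    pitch_um: float = 17.5

    def __post_init__(self) -> None:
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError(
                f"grid must have at least one electrode per axis, got "
                f"{self.n_cols} x {self.n_rows}"
            )
        if not self.pitch_um > 0:
            raise ValueError(f"pitch_um must be positive, got {self.pitch_um}")

    @property
    def electrode_count(self) -> int:
        """Total number of electrodes (n_cols * n_rows)."""
        return self.n_cols * self.n_rows

    @property
    def extent_um(self) -> Tuple[float, float]:
        """(long-axis, short-axis) physical extent in um.

        The extent convention is ``count * pitch`` (each electrode owns one
        pitch-sized cell), which reproduces the device's quoted
        3,850 x 2,100 um sensing area from 220/120 electrodes at 17.5 um.
        """
        return (self.n_cols * self.pitch_um, self.n_rows * self.pitch_um)

    def validate_electrode(self, electrode: ElectrodeId) -> None:
        """Raise ``ValueError`` if *electrode* is off the grid."""
        col, row = electrode
        if not (0 <= col < self.n_cols and 0 <= row < self.n_rows):
            raise ValueError(
                f"electrode (col={col}, row={row}) outside "
                f"{self.n_cols} x {self.n_rows} grid"
            )

    def distance_um(self, a: ElectrodeId, b: ElectrodeId) -> float:
        """Euclidean distance between two electrodes in um."""
        self.validate_electrode(a)
        self.validate_electrode(b)
        return self.pitch_um * math.hypot(a[0] - b[0], a[1] - b[1])

    def distances_um(
        self, center: ElectrodeId, electrodes: Sequence[ElectrodeId]
    ) -> np.ndarray:
        """Vectorised Euclidean distances from *center*, in um."""
        self.validate_electrode(center)
        arr = np.asarray(list(electrodes), dtype=float)
        if arr.size == 0:
            return np.empty(0)
        for e in electrodes:
            self.validate_electrode(e)
        d = arr - np.asarray(center, dtype=float)
        return self.pitch_um * np.hypot(d[:, 0], d[:, 1])

    def electrodes_within_radius(
        self, center: ElectrodeId, radius_electrodes: float
    ) -> list[ElectrodeId]:
        """All on-grid electrodes within a closed Euclidean ball.

        ``radius_electrodes`` is expressed in units of the electrode pitch,
        so radius 15 means "15 electrode lengths".  The ball is closed
        (boundary electrodes included) and always contains *center*.
        """
        self.validate_electrode(center)
        if radius_electrodes < 0:
            raise ValueError(f"radius must be >= 0, got {radius_electrodes}")
        c0, r0 = center
        rmax = int(math.floor(radius_electrodes))
        r2 = radius_electrodes**2
        out: list[ElectrodeId] = []
        for dc in range(-rmax, rmax + 1):
            col = c0 + dc
            if not 0 <= col < self.n_cols:
                continue
            for dr in range(-rmax, rmax + 1):
                row = r0 + dr
                if 0 <= row < self.n_rows and dc * dc + dr * dr <= r2:
                    out.append((col, row))
        return out


# Thin functional aliases -------------------------------------------------


def electrode_count(grid: ElectrodeGrid) -> int:
    return grid.electrode_count


def grid_extent(grid: ElectrodeGrid) -> Tuple[float, float]:
    return grid.extent_um


def electrode_distance(grid: ElectrodeGrid, a: ElectrodeId, b: ElectrodeId) -> float:
    return grid.distance_um(a, b)


def electrodes_within_radius(
    grid: ElectrodeGrid, center: ElectrodeId, radius_electrodes: float
) -> list[ElectrodeId]:
    return grid.electrodes_within_radius(center, radius_electrodes)
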