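"""Stimulus-grid geometry and reference-frame conversions.

The reaching task presents cubes on a 3-row x 13-column lattice defined in
Unity scene units. Analyses are carried out in midline-relative Unity units
and only converted to physical units for reporting. Three additional frames
are supported:

* ``visual2D`` -- centimetres on the laptop screen (2.4 cm per Unity unit);
* ``virtual3D`` -- screen centimetres including the simulated depth between
  the hand start plane and the stimulus plane;
* ``real3D`` -- centimetres in the physical workspace, obtained from screen
  centimetres through a rounded gain factor of 4 (the ratio of the real hand
  separation, 22.1 cm, to the mean on-screen hand separation, 5.53 cm).

Horizontal positions therefore scale by exactly 9.6 cm per Unity unit when
going from the scene to the real workspace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = [
    "FRAMES",
    "FramePoint",
    "FrameSpec",
    "StimulusGrid",
    "build_grid",
    "convert",
    "reach_distance",
    "real3d_from_virtual",
    "PRINTED_REACH_CM",
]

#: Supported reference-frame tags.
FRAMES = ("unity3D", "visual2D", "virtual3D", "real3D")

#: Gaps between adjacent column centres in Unity units, left to right.
COLUMN_GAPS = (1.0, 1.0, 0.25, 0.25, 0.25, 0.25, 0.25, 0.25, 0.25, 0.25, 1.0, 1.0)

#: Reaching distances printed for the setup (visual2D cm, virtual3D cm),
#: keyed by (row, column kind). These are measured values for the concrete
#: apparatus and are kept verbatim; real3D distances follow by multiplying
#: the virtual3D entry with the gain factor.
PRINTED_REACH_CM = {
    (1, "middle"): (4.2, 6.60),
    (2, "middle"): (5.8, 7.89),
    (3, "middle"): (7.9, 9.61),
    (1, "peripheral"): (4.6, 7.46),
    (2, "peripheral"): (6.3, 8.62),
    (3, "peripheral"): (8.5, 10.22),
}


@dataclass(frozen=True)
class FrameSpec:
    """Conversion constants linking the four reference frames.

    Parameters
    ----------
    screen_cm_per_unit : float
        Visual scale of the scene on the laptop screen (cm per Unity unit).
    hand_separation_real_cm : float
        Physical distance between the two hands in the start posture.
    hand_separation_virtual_cm : float
        Mean separation of the rendered hands on screen used to calibrate
        the real-space gain.
    hand_separation_screen_cm : float
        Separation of the start-square centres on the screen.
    depth_cm : float
        Mean separation between the hand start plane and the stimulus plane
        in virtual depth.
    bottom_row_y_cm : float
        Height of the bottom stimulus row above the start-square centres on
        the screen. The default reproduces the printed 4.2 cm reach to the
        bottom middle cube given the 2.75 cm horizontal half-separation.
    """

    screen_cm_per_unit: float = 2.4
    hand_separation_real_cm: float = 22.1
    hand_separation_virtual_cm: float = 5.53
    hand_separation_screen_cm: float = 5.5
    depth_cm: float = 5.37
    bottom_row_y_cm: float = math.sqrt(4.2**2 - 2.75**2)

    @property
    def real_gain(self) -> int:
        """Rounded real-space gain: real separation over on-screen separation."""
        return round(self.hand_separation_real_cm / self.hand_separation_virtual_cm)

    @property
    def real_cm_per_unit(self) -> float:
        """Composite Unity -> real3D horizontal scale (9.6 cm/unit by default)."""
        return self.screen_cm_per_unit * self.real_gain

    def scale(self, frame: str) -> float:
        """Multiplier taking Unity coordinates into ``frame``."""
        _check_frame(frame)
        if frame == "unity3D":
            return 1.0
        if frame in ("visual2D", "virtual3D"):
            return self.screen_cm_per_unit
        return self.real_cm_per_unit


@dataclass(frozen=True)
class FramePoint:
    """A coordinate triple tagged with the frame it lives in."""

    frame: str
    x: float
    y: float = 0.0
    z: float = 0.0

    def __post_init__(self) -> None:
        _check_frame(self.frame)


def _check_frame(frame: str) -> None:
    if frame not in FRAMES:
        raise ValueError(f"unknown reference frame {frame!r}; expected one of {FRAMES}")


def convert(point: FramePoint, target_frame: str, spec: FrameSpec | None = None) -> FramePoint:
    """Convert a tagged point between reference frames.

    Conversions are pure rescalings about the grid midline: Unity to
    visual2D/virtual3D multiplies by the screen scale, visual2D to real3D by
    the gain factor. They are bijective and composable, and never change the
    sign of the horizontal coordinate.
    """
    spec = spec or FrameSpec()
    _check_frame(target_frame)
    factor = spec.scale(target_frame) / spec.scale(point.frame)
    return FramePoint(target_frame, point.x * factor, point.y * factor, point.z * factor)


def real3d_from_virtual(virtual3d_cm: float, spec: FrameSpec | None = None) -> float:
    """Real-space distance from an on-screen virtual3D distance (x gain)."""
    spec = spec or FrameSpec()
    return virtual3d_cm * spec.real_gain


@dataclass(frozen=True)
class StimulusGrid:
    """The 3 x 13 lattice of cube centres.

    ``column_offsets`` are midline-relative horizontal centres in Unity
    units; the scene's absolute centre (``center_x``) is retained only so
    raw logs recorded in scene coordinates can be re-centred on ingest.
    ``repeats`` gives per-column presentation counts per row: the middle
    three columns appear twice per round, every other column once, for 48
    presentations per round.
    """

    column_offsets: tuple[float, ...] = field(
        default_factory=lambda: _column_offsets_from_gaps(COLUMN_GAPS)
    )
    row_offsets: tuple[float, ...] = (0.0, 1.0, 2.0)
    cube_edge: float = 1.0
    center_x: float = 4.0
    repeats: tuple[int, ...] = (1, 1, 1, 1, 1, 2, 2, 2, 1, 1, 1, 1, 1)

    def __post_init__(self) -> None:
        if len(self.column_offsets) != len(self.repeats):
            raise ValueError("column_offsets and repeats must have equal length")
        diffs = np.diff(self.column_offsets)
        if not np.all(diffs > 0):
            raise ValueError("column_offsets must be strictly increasing")

    @property
    def n_rows(self) -> int:
        return len(self.row_offsets)

    @property
    def n_columns(self) -> int:
        return len(self.column_offsets)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_columns

    @property
    def presentations_per_round(self) -> int:
        return self.n_rows * sum(self.repeats)

    @property
    def horizontal_range(self) -> float:
        """Centre-to-centre horizontal span in Unity units (6 for the canonical grid)."""
        return self.column_offsets[-1] - self.column_offsets[0]

    def x_of(self, column_index: int) -> float:
        """Midline-relative x of a 0-based column index."""
        return self.column_offsets[column_index]

    def y_of(self, row: int) -> float:
        """Vertical offset of a 1-based row (row 1 is lowest)."""
        return self.row_offsets[row - 1]

    def cells(self) -> Iterator[tuple[int, int]]:
        """All 39 distinct (row, column_index) cells."""
        for row in range(1, self.n_rows + 1):
            for col in range(self.n_columns):
                yield (row, col)

    def presentations(self) -> list[tuple[int, int]]:
        """The canonical per-round multiset of (row, column_index), with repeats."""
        out: list[tuple[int, int]] = []
        for row in range(1, self.n_rows + 1):
            for col, rep in enumerate(self.repeats):
                out.extend([(row, col)] * rep)
        return out

    def contains(self, row: int, column_index: int, x: float, y: float) -> bool:
        """Whether (x, y) in Unity units lies inside the closed cube extent."""
        half = self.cube_edge / 2.0
        return (
            abs(x - self.x_of(column_index)) <= half
            and abs(y - self.y_of(row)) <= half
        )


def _column_offsets_from_gaps(gaps: tuple[float, ...]) -> tuple[float, ...]:
    pos = np.concatenate([[0.0], np.cumsum(gaps)])
    centred = pos - pos[-1] / 2.0
    return tuple(float(v) for v in centred)


def build_grid() -> StimulusGrid:
    """The canonical stimulus grid: 39 cells, 48 presentations per round."""
    return StimulusGrid()


def start_positions_visual2d(spec: FrameSpec | None = None) -> dict[str, tuple[float, float]]:
    """Start-square centres for each hand in midline-relative visual2D cm."""
    spec = spec or FrameSpec()
    half = spec.hand_separation_screen_cm / 2.0
    return {"L": (-half, 0.0), "R": (half, 0.0)}


def reach_distance(
    row: int,
    column_index: int,
    frame: str,
    spec: FrameSpec | None = None,
    grid: StimulusGrid | None = None,
) -> float:
    """Reach length from the nearer hand's start square to a cube centre.

    visual2D is the planar screen distance; virtual3D adds the configured
    depth in quadrature; real3D multiplies virtual3D by the gain factor.
    """
    spec = spec or FrameSpec()
    grid = grid or build_grid()
    if frame not in ("visual2D", "virtual3D", "real3D"):
        raise ValueError(f"reach_distance is defined for cm frames, not {frame!r}")
    if not 1 <= row <= grid.n_rows:
        raise ValueError(f"row must be in 1..{grid.n_rows}, got {row}")
    if not 0 <= column_index < grid.n_columns:
        raise ValueError(f"column_index must be in 0..{grid.n_columns - 1}, got {column_index}")

    sx = grid.x_of(column_index) * spec.screen_cm_per_unit
    sy = spec.bottom_row_y_cm + grid.y_of(row) * spec.screen_cm_per_unit
    planar = min(
        math.hypot(sx - hx, sy - hy)
        for hx, hy in start_positions_visual2d(spec).values()
    )
    if frame == "visual2D":
        return planar
    virtual = math.hypot(planar, spec.depth_cm)
    if frame == "virtual3D":
        return virtual
    return virtual * spec.real_gain
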