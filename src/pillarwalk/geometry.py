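"""Obstacle geometry for the pillar-forest migration arena.

The arena is a 2D raster of lattice nodes at a fixed physical resolution
(default 1.31 um per node).  A regular array of disc-shaped pillars sits
between two open clearings: cells are seeded in the lower (entry) clearing
and chemokine diffuses from a hole in the upper clearing.  Microscopy only
covers the pillar forest itself, which is modelled by a rectangular
"visible window" in which trajectories are recorded.

Coordinate convention: raster arrays are indexed ``[row, col]``; physical
coordinates are ``x = (col + 0.5) * resolution`` and
``y = (row + 0.5) * resolution`` so that y increases toward the chemokine
source (row 0 is the entry side).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

DEFAULT_RESOLUTION = 1.31  # um per lattice node


@dataclass(frozen=True)
class Rect:
    """Axis-aligned half-open rectangle in node coordinates."""

    col0: int
    row0: int
    col1: int
    row1: int

    def __post_init__(self) -> None:
        if self.col1 <= self.col0 or self.row1 <= self.row0:
            raise ValueError(f"degenerate rectangle {self}")

    def contains(self, col: float, row: float) -> bool:
        return (self.col0 <= col < self.col1) and (self.row0 <= row < self.row1)

    def contains_xy(self, x: float, y: float, resolution: float) -> bool:
        """Containment test for physical (um) coordinates.

        The rectangle edges sit on node boundaries, i.e. the covered
        physical region is ``[col0 * res, col1 * res) x [row0 * res, row1 * res)``.
        """
        return self.contains(x / resolution, y / resolution)

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.col0 + self.col1), 0.5 * (self.row0 + self.row1))

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.col0, self.row0, self.col1, self.row1)


@dataclass
class Geometry:
    """Raster description of the migration arena.

    Attributes
    ----------
    obstacle_mask
        Boolean raster, True on pillar (forbidden) nodes.
    visible_window
        Region in which trajectories are observed.
    entry_region
        Region in which cells are seeded; must be obstacle free.
    target_region
        The "chemokine hole"; arrivals are counted on entry to this region.
    resolution
        Physical node size in um.
    """

    obstacle_mask: np.ndarray
    visible_window: Rect
    entry_region: Rect
    target_region: Rect
    resolution: float = DEFAULT_RESOLUTION

    def __post_init__(self) -> None:
        self.obstacle_mask = np.asarray(self.obstacle_mask, dtype=bool)
        if self.obstacle_mask.ndim != 2:
            raise ValueError("obstacle_mask must be a 2D raster")
        h, w = self.obstacle_mask.shape
        for name in ("visible_window", "entry_region", "target_region"):
            r: Rect = getattr(self, name)
            if r.col0 < 0 or r.row0 < 0 or r.col1 > w or r.row1 > h:
                raise ValueError(f"{name} {r} lies outside the {h}x{w} raster")
        entry = self.entry_region
        if self.obstacle_mask[entry.row0 : entry.row1, entry.col0 : entry.col1].any():
            raise ValueError("entry region overlaps obstacles")

    @property
    def shape(self) -> tuple[int, int]:
        return self.obstacle_mask.shape

    def node_centers_um(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) physical coordinates of every node center, each (H, W)."""
        h, w = self.shape
        x = (np.arange(w) + 0.5) * self.resolution
        y = (np.arange(h) + 0.5) * self.resolution
        return np.broadcast_to(x, (h, w)).copy(), np.broadcast_to(y[:, None], (h, w)).copy()

    def without_pillars(self) -> "Geometry":
        """Same arena with an empty obstacle mask (open-arena condition)."""
        return Geometry(
            np.zeros_like(self.obstacle_mask),
            self.visible_window,
            self.entry_region,
            self.target_region,
            self.resolution,
        )

    # ------------------------------------------------------------------
    # serialization: PGM raster + JSON sidecar
    # ------------------------------------------------------------------
    def save(self, raster_path: str | Path) -> None:
        from PIL import Image

        raster_path = Path(raster_path)
        img = Image.fromarray((self.obstacle_mask * 255).astype(np.uint8), mode="L")
        img.save(raster_path)
        sidecar = {
            "resolution_um_per_node": self.resolution,
            "visible_window": self.visible_window.as_tuple(),
            "entry_region": self.entry_region.as_tuple(),
            "target_region": self.target_region.as_tuple(),
        }
        raster_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, raster_path: str | Path) -> "Geometry":
        from PIL import Image

        raster_path = Path(raster_path)
        mask = np.asarray(Image.open(raster_path).convert("L")) > 0
        meta = json.loads(raster_path.with_suffix(".json").read_text())
        return cls(
            mask,
            Rect(*meta["visible_window"]),
            Rect(*meta["entry_region"]),
            Rect(*meta["target_region"]),
            float(meta["resolution_um_per_node"]),
        )


def build_pillar_forest(
    rows: int,
    cols: int,
    pillar_diameter_um: float,
    gap_um: float,
    window: Rect | None = None,
    resolution: float = DEFAULT_RESOLUTION,
    clearing_um: float = 40.0,
) -> Geometry:
    """Build a regular pillar-forest arena.

    ``rows x cols`` disc obstacles with edge-to-edge spacing ``gap_um``
    (center pitch = diameter + gap) fill a band across the arena, with open
    clearings of height ``clearing_um`` below (entry side) and above
    (chemokine side).  ``pillar_diameter_um = 0`` or ``rows == 0`` yields an
    open arena with the same footprint.

    The default visible window is the pillar band itself; the entry region
    is the lower clearing and the target region ("chemokine hole") is the
    center of the upper clearing.
    """
    if rows < 0 or cols < 0:
        raise ValueError("pillar counts must be non-negative")
    if pillar_diameter_um < 0:
        raise ValueError("pillar diameter must be non-negative")
    if gap_um <= 0:
        raise ValueError("gap must be positive")
    if resolution <= 0:
        raise ValueError("resolution must be positive")

    pitch_um = pillar_diameter_um + gap_um
    ncols_eff = max(cols, 1)
    width_um = ncols_eff * pitch_um
    band_um = max(rows, 1) * pitch_um
    w = max(int(round(width_um / resolution)), 4)
    band = max(int(round(band_um / resolution)), 2)
    clearing = max(int(round(clearing_um / resolution)), 3)
    h = band + 2 * clearing

    mask = np.zeros((h, w), dtype=bool)
    radius_um = pillar_diameter_um / 2.0
    if radius_um > 0 and rows > 0 and cols > 0:
        x_um = (np.arange(w) + 0.5) * resolution
        y_um = (np.arange(h) + 0.5) * resolution
        xx, yy = np.meshgrid(x_um, y_um)
        for i in range(rows):
            cy = clearing * resolution + (i + 0.5) * pitch_um
            for j in range(cols):
                cx = (j + 0.5) * pitch_um
                mask |= (xx - cx) ** 2 + (yy - cy) ** 2 <= radius_um**2

    if window is None:
        window = Rect(0, clearing, w, clearing + band)
    entry = Rect(0, 1, w, clearing - 1)
    hole_w = max(w // 3, 2)
    target = Rect((w - hole_w) // 2, h - clearing + 1, (w + hole_w) // 2, h - 1)
    return Geometry(mask, window, entry, target, resolution)
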