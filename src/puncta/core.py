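"""Shared data model for smFISH puncta analysis.

Conventions
-----------
Physical coordinates are continuous micrometres with the origin at the ROI
top-left corner, x rightward and y downward.  Pixel ``(row, col)`` indices are
0-based; pixel ``(row, col)`` covers the half-open square
``[col/s, (col+1)/s) x [row/s, (row+1)/s)`` where ``s`` is the pixel scale in
pixels per micrometre.  The default scale (9.6679 px/µm) matches 63x
wide-field acquisition of hippocampal tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, Iterator, Optional, Tuple

import numpy as np

#: pixels per micrometre of the study's 63x acquisitions
DEFAULT_PIXEL_SCALE = 9.6679

PixelSet = FrozenSet[Tuple[int, int]]


@dataclass(frozen=True)
class RoiSpec:
    """Physical extent and sampling of a rectangular region of interest."""

    width_um: float
    height_um: float
    pixel_scale: float = DEFAULT_PIXEL_SCALE

    def __post_init__(self) -> None:
        if self.width_um <= 0 or self.height_um <= 0:
            raise ValueError("ROI extent must be positive")
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive")

    @property
    def shape(self) -> Tuple[int, int]:
        """Pixel grid dimensions ``(n_rows, n_cols)``."""
        return (
            int(round(self.height_um * self.pixel_scale)),
            int(round(self.width_um * self.pixel_scale)),
        )

    @property
    def area_um2(self) -> float:
        return self.width_um * self.height_um

    def contains(self, x_um: float, y_um: float) -> bool:
        return 0.0 <= x_um <= self.width_um and 0.0 <= y_um <= self.height_um

    def um_to_pixel(self, x_um: float, y_um: float) -> Tuple[int, int]:
        """Map a µm point to the (row, col) of the pixel containing it."""
        n_rows, n_cols = self.shape
        col = min(int(np.floor(x_um * self.pixel_scale)), n_cols - 1)
        row = min(int(np.floor(y_um * self.pixel_scale)), n_rows - 1)
        return max(row, 0), max(col, 0)

    def pixel_center_um(self, row: int, col: int) -> Tuple[float, float]:
        return (col + 0.5) / self.pixel_scale, (row + 0.5) / self.pixel_scale


@dataclass(frozen=True)
class Punctum:
    """One segmented fluorescent spot.

    ``area`` is in µm², ``feret_diameter`` (maximum caliper) in µm,
    intensities in arbitrary units.  ``pixels`` is the optional set of
    integer (row, col) member pixels; when present,
    ``total_intensity == mean_intensity * len(pixels)`` holds by construction
    of the segmentation.
    """

    id: int
    channel: str
    centroid_xy: Tuple[float, float]
    area: float
    feret_diameter: float
    total_intensity: float
    mean_intensity: float
    pixels: Optional[PixelSet] = None

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError(f"punctum {self.id}: area must be positive")

    @property
    def radius(self) -> float:
        """Half the Feret diameter (the 'radius' of the centroid criterion)."""
        return self.feret_diameter / 2.0


@dataclass
class PunctaSet:
    """All puncta of one channel within one ROI."""

    channel: str
    roi: RoiSpec
    puncta: list = field(default_factory=list)
    provenance: str = "constructed"

    def __post_init__(self) -> None:
        ids = [p.id for p in self.puncta]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate punctum ids in channel {self.channel!r}")
        for p in self.puncta:
            if p.channel != self.channel:
                raise ValueError(
                    f"punctum {p.id} labelled {p.channel!r} in set {self.channel!r}"
                )

    def __len__(self) -> int:
        return len(self.puncta)

    def __iter__(self) -> Iterator[Punctum]:
        return iter(self.puncta)

    def centroids(self) -> np.ndarray:
        """(n, 2) array of centroid (x, y) in µm."""
        if not self.puncta:
            return np.empty((0, 2))
        return np.array([p.centroid_xy for p in self.puncta])

    def radii(self) -> np.ndarray:
        return np.array([p.radius for p in self.puncta])

    def ids(self) -> list:
        return [p.id for p in self.puncta]


@dataclass
class BinaryMask:
    """Boolean pixel grid tied to an ROI."""

    grid: np.ndarray
    roi: RoiSpec

    def __post_init__(self) -> None:
        if tuple(self.grid.shape) != self.roi.shape:
            raise ValueError(
                f"mask shape {self.grid.shape} inconsistent with ROI grid {self.roi.shape}"
            )
        self.grid = np.asarray(self.grid, dtype=bool)


def disc_pixels(
    centroid_xy: Tuple[float, float], diameter: float, roi: RoiSpec
) -> PixelSet:
    """Grid pixels whose centers lie within ``diameter/2`` of the centroid.

    Clipped to the ROI; always returns at least the pixel nearest the
    centroid, so sub-pixel-pitch discs have a one-pixel footprint.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    cx, cy = centroid_xy
    if not roi.contains(cx, cy):
        raise ValueError(f"centroid {centroid_xy} outside ROI")
    s = roi.pixel_scale
    n_rows, n_cols = roi.shape
    r = diameter / 2.0
    row_lo = max(int(np.floor((cy - r) * s)) - 1, 0)
    row_hi = min(int(np.ceil((cy + r) * s)) + 1, n_rows)
    col_lo = max(int(np.floor((cx - r) * s)) - 1, 0)
    col_hi = min(int(np.ceil((cx + r) * s)) + 1, n_cols)
    rows = np.arange(row_lo, row_hi)
    cols = np.arange(col_lo, col_hi)
    if rows.size and cols.size:
        cys = (rows + 0.5) / s
        cxs = (cols + 0.5) / s
        dy2 = (cys - cy) ** 2
        dx2 = (cxs - cx) ** 2
        inside = dy2[:, None] + dx2[None, :] <= r * r
        rr, cc = np.nonzero(inside)
        out = {(int(rows[i]), int(cols[j])) for i, j in zip(rr, cc)}
    else:
        out = set()
    if not out:
        out = {roi.um_to_pixel(cx, cy)}
    return frozenset(out)


def puncta_to_mask(pset: PunctaSet) -> BinaryMask:
    """Union of member-pixel footprints as a binary mask.

    Every punctum must carry a pixel set; puncta from coordinate tables
    should be materialized first (see :func:`materialize_pixels`).
    """
    grid = np.zeros(pset.roi.shape, dtype=bool)
    for p in pset:
        if p.pixels is None:
            raise ValueError(
                f"punctum {p.id} in channel {pset.channel!r} has no pixel set; "
                "materialize discs before requesting a mask"
            )
        for row, col in p.pixels:
            grid[row, col] = True
    return BinaryMask(grid, pset.roi)


def materialize_pixels(pset: PunctaSet) -> PunctaSet:
    """Give every pixel-less punctum a disc footprint of its Feret diameter.

    Coordinate-table puncta carry only centroid/area/Feret; pixel-overlap
    operations need a footprint, and a disc of the recorded Feret diameter is
    the minimal shape consistent with the recorded caliper.
    """
    out = []
    for p in pset:
        if p.pixels is not None:
            out.append(p)
        else:
            px = disc_pixels(p.centroid_xy, p.feret_diameter, pset.roi)
            out.append(
                Punctum(
                    id=p.id,
                    channel=p.channel,
                    centroid_xy=p.centroid_xy,
                    area=p.area,
                    feret_diameter=p.feret_diameter,
                    total_intensity=p.total_intensity,
                    mean_intensity=p.mean_intensity,
                    pixels=px,
                )
            )
    return PunctaSet(pset.channel, pset.roi, out, provenance=pset.provenance)


def feret_diameter_um(pixels: Iterable[Tuple[int, int]], pixel_scale: float) -> float:
    """Maximum caliper diameter of a pixel set, in µm.

    Defined over the corner points of the member pixels (the standard
    particle-analysis convention), so a single pixel has Feret equal to its
    diagonal.  Uses the convex hull for sets large enough to benefit.
    """
    pts = np.asarray(list(pixels), dtype=float)
    if pts.size == 0:
        raise ValueError("empty pixel set")
    # corner points of each pixel: (row, col), (row+1, col), (row, col+1), (row+1, col+1)
    corners = np.concatenate(
        [pts + off for off in ((0, 0), (1, 0), (0, 1), (1, 1))], axis=0
    )
    corners = np.unique(corners, axis=0)
    if len(corners) > 16:
        from scipy.spatial import ConvexHull

        try:
            corners = corners[ConvexHull(corners).vertices]
        except Exception:  # degenerate (collinear) sets
            pass
    d2 = np.sum((corners[:, None, :] - corners[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()) / pixel_scale)
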