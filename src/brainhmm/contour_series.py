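"""Gray-matter boundary extraction: from segmented slices to distance series.

Each axial slice of a tissue-labeled volume is reduced to a 1-D signal: the
Euclidean distances from consecutive points on the outer gray-matter (GM)
boundary to the GM center of mass of that slice.  One slice yields one
series; a whole brain yields an ordered stack of series (top to bottom)
that downstream modules treat as a sequence.

Conventions (deterministic, stated once):

* centroid = arithmetic mean of ALL GM pixel coordinates in the slice;
* boundary = Moore-neighbor trace of the largest 8-connected component,
  clockwise (in image display orientation, row down / column right),
  starting at the top-most then left-most boundary pixel;
* coordinates are 0-based ``(row, col)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

log = logging.getLogger(__name__)

__all__ = [
    "ConfigError",
    "SliceSkip",
    "SliceMask",
    "BoundarySeries",
    "SeriesConfig",
    "gm_mask_from_labels",
    "gm_centroid",
    "trace_outer_boundary",
    "boundary_distance_series",
    "volume_to_series",
    "load_volume",
    "series_to_frame",
]


class ConfigError(ValueError):
    """Invalid extraction configuration."""


class SliceSkip(Exception):
    """A slice cannot yield a usable series; carries the reason."""

    def __init__(self, slice_index: int, reason: str):
        self.slice_index = slice_index
        self.reason = reason
        super().__init__(f"slice {slice_index}: {reason}")


@dataclass
class SliceMask:
    """One slice's binary GM mask (True = gray matter)."""

    grid: np.ndarray
    slice_index: int

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise ValueError("mask grid must be 2-D")


@dataclass
class BoundarySeries:
    """Ordered distances from outer-boundary points to the GM centroid."""

    distances: np.ndarray
    boundary_points: np.ndarray  # (n, 2) int (row, col)
    centroid: tuple[float, float]
    slice_index: int

    def __len__(self) -> int:
        return len(self.distances)


@dataclass
class SeriesConfig:
    """Extraction settings.

    ``gm_label`` defaults to the common 4-class map (0 background, 1 CSF,
    2 GM, 3 WM); synthetic cohorts use ``gm_label=1``.  ``reverse_slices``
    flips the slice order when the stored axis runs bottom-to-top.
    """

    gm_label: int = 2
    min_boundary_length: int = 20
    slice_axis: int = 2
    reverse_slices: bool = False
    label_map: dict = field(
        default_factory=lambda: {"background": 0, "csf": 1, "gm": 2, "wm": 3}
    )

    def __post_init__(self) -> None:
        if self.gm_label not in self.label_map.values():
            raise ConfigError(
                f"gm_label {self.gm_label} not present in label map {self.label_map}"
            )
        if self.min_boundary_length < 1:
            raise ConfigError("min_boundary_length must be >= 1")


def load_volume(path: str | Path) -> np.ndarray:
    """Read a labeled volume from NIfTI-1 (.nii/.nii.gz) or Analyze 7.5 (.hdr/.img)."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    return np.rint(data).astype(np.int32)


def gm_mask_from_labels(
    volume: np.ndarray, gm_label: int, slice_axis: int = 2, reverse: bool = False
) -> list[SliceMask]:
    """Select the GM label per slice, preserving top-to-bottom order."""
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got ndim={volume.ndim}")
    n = volume.shape[slice_axis]
    order = range(n - 1, -1, -1) if reverse else range(n)
    masks = []
    for out_index, s in enumerate(order):
        sl = np.take(volume, s, axis=slice_axis)
        masks.append(SliceMask(grid=(sl == gm_label), slice_index=out_index))
    return masks


def gm_centroid(mask: SliceMask) -> tuple[float, float]:
    """Center of mass of the full GM mask (all true pixels, all components)."""
    coords = np.argwhere(mask.grid)
    if coords.size == 0:
        raise SliceSkip(mask.slice_index, "empty GM mask")
    r, c = coords.mean(axis=0)
    return float(r), float(c)


# Moore neighborhood in clockwise order for (row down, col right) display:
# E, SE, S, SW, W, NW, N, NE
_MOORE = (
    (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1),
)
_EIGHT = np.ones((3, 3), dtype=int)


def _largest_component(grid: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(grid, structure=_EIGHT)
    if n == 0:
        return np.zeros_like(grid, dtype=bool)
    sizes = np.bincount(labels.ravel())[1:]
    return labels == (int(np.argmax(sizes)) + 1)  # ties -> lowest label


def trace_outer_boundary(
    mask: SliceMask, min_length: int = 20
) -> np.ndarray:
    """Clockwise Moore-neighbor trace of the largest 8-connected component.

    Starts at the top-most then left-most pixel of the component; every
    returned point is a component pixel adjacent to background.  Stops on
    re-entering the start pixel with the initial backtrack configuration.
    """
    comp = _largest_component(mask.grid)
    n_pixels = int(comp.sum())
    if n_pixels == 0:
        raise SliceSkip(mask.slice_index, "empty GM mask")

    coords = np.argwhere(comp)
    start = tuple(coords[np.lexsort((coords[:, 1], coords[:, 0]))][0])
    rows, cols = comp.shape

    def fg(p: tuple[int, int]) -> bool:
        r, c = p
        return 0 <= r < rows and 0 <= c < cols and comp[r, c]

    initial_back = (start[0], start[1] - 1)  # west of start: background by choice of start
    contour = [start]
    p, back = start, initial_back
    max_steps = 4 * n_pixels + 8
    for _ in range(max_steps):
        d0 = _MOORE.index((back[0] - p[0], back[1] - p[1]))
        nxt = None
        for k in range(1, 9):
            d = (d0 + k) % 8
            q = (p[0] + _MOORE[d][0], p[1] + _MOORE[d][1])
            if fg(q):
                prev_d = (d0 + k - 1) % 8
                nxt = q
                back = (p[0] + _MOORE[prev_d][0], p[1] + _MOORE[prev_d][1])
                break
        if nxt is None:  # isolated single pixel
            break
        if nxt == start and back == initial_back:
            break
        contour.append(nxt)
        p = nxt

    if len(contour) < min_length:
        raise SliceSkip(
            mask.slice_index,
            f"boundary of {len(contour)} points below minimum {min_length}",
        )
    return np.array(contour, dtype=int)


def boundary_distance_series(
    boundary: np.ndarray,
    centroid: tuple[float, float],
    slice_index: int = 0,
) -> BoundarySeries:
    """Euclidean distance from each boundary point to the centroid, in order."""
    boundary = np.asarray(boundary)
    if boundary.size == 0:
        raise ValueError("boundary must be nonempty")
    delta = boundary.astype(float) - np.asarray(centroid, dtype=float)
    distances = np.hypot(delta[:, 0], delta[:, 1])
    return BoundarySeries(
        distances=distances,
        boundary_points=boundary,
        centroid=(float(centroid[0]), float(centroid[1])),
        slice_index=slice_index,
    )


def volume_to_series(
    volume: np.ndarray, config: SeriesConfig | None = None
) -> list[BoundarySeries]:
    """One BoundarySeries per usable slice of a labeled volume.

    Slices with empty GM or a boundary shorter than the configured minimum
    are skipped (logged with the reason); slice order is preserved.  Raises
    ``ValueError`` when no slice is usable.
    """
    config = config or SeriesConfig()
    masks = gm_mask_from_labels(
        volume, config.gm_label, slice_axis=config.slice_axis,
        reverse=config.reverse_slices,
    )
    out: list[BoundarySeries] = []
    for mask in masks:
        try:
            centroid = gm_centroid(mask)
            boundary = trace_outer_boundary(mask, min_length=config.min_boundary_length)
        except SliceSkip as skip:
            log.info("skipping %s", skip)
            continue
        out.append(boundary_distance_series(boundary, centroid, mask.slice_index))
    if not out:
        raise ValueError("no usable slice in volume (all GM masks empty or too small)")
    return out


def series_to_frame(series_list: list[BoundarySeries], subject_id: str = "") -> pd.DataFrame:
    """Tidy table of boundary points: one row per point."""
    rows = []
    for s in series_list:
        for i, ((r, c), d) in enumerate(zip(s.boundary_points, s.distances)):
            rows.append((subject_id, s.slice_index, i, int(r), int(c), float(d)))
    return pd.DataFrame(
        rows, columns=["subject", "slice_index", "point_index", "row", "col", "distance"]
    )
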