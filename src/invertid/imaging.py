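"""Silhouette detection and geometric measurement of specimen frames.

Each frame shows a dark specimen on a bright backlit background. The blob —
the connected silhouette of the specimen — is segmented by thresholding
(Otsu by default), keeping the largest 8-connected component and filling
internal holes so translucent body parts do not fragment the area proxy.
From the blob we measure area (foreground pixel count), perimeter (length of
the traced outer boundary), maximum diameter (max Feret: the largest pairwise
distance between boundary pixel centers), centroid and inclusive bounding box.

The standard crop keeps the full 496-px cuvette width and windows the frame
vertically to 496 px centered on the blob; blobs taller than the window force
a taller crop. Body size in mm2 follows from the cuvette geometry: 10 mm of
cuvette width span 496 px, so one pixel covers (10/496)^2 ~ 4.06e-4 mm2.

Coordinates are 0-based, row-major, origin top-left; bounding boxes are
inclusive on both ends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage.filters import threshold_otsu

from .synthetic import BACKGROUND, Frame

__all__ = [
    "BlobMask",
    "GeometricFeatures",
    "BodySize",
    "NoBlobFoundError",
    "detect_blob",
    "blob_features",
    "crop_to_standard",
    "crop_with_mask",
    "estimate_body_size",
    "CUVETTE_WIDTH_PX",
    "CUVETTE_WIDTH_MM",
]

logger = logging.getLogger(__name__)

CUVETTE_WIDTH_PX = 496
CUVETTE_WIDTH_MM = 10.0


class NoBlobFoundError(RuntimeError):
    """Raised when thresholding leaves no foreground pixel (empty frame)."""


@dataclass
class BlobMask:
    """Binary silhouette mask congruent with its source frame."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not self.mask.any():
            raise ValueError("mask must contain at least one foreground pixel")

    @property
    def n_foreground(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class GeometricFeatures:
    area: int
    perimeter: float
    max_diameter: float
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]  # (row_min, col_min, row_max, col_max), inclusive


@dataclass(frozen=True)
class BodySize:
    mean_area_px: float
    mean_area_mm2: float
    px_to_mm2: float


def detect_blob(frame: Frame, threshold: str | float = "otsu") -> BlobMask:
    """Segment the specimen silhouette from a backlit frame.

    Foreground is every pixel strictly darker than the threshold ("otsu" or a
    fixed value in [0, 1]); the largest 8-connected component is kept and its
    holes filled. Raises :class:`NoBlobFoundError` if nothing lies below the
    threshold — the caller should skip such frames with a logged warning.
    """
    pixels = frame.pixels
    if threshold == "otsu":
        # the histogram is estimated on a 2x-decimated grid; the threshold is
        # then applied at full resolution (silhouette histograms are strongly
        # bimodal, so the decimation does not move the split point materially)
        sample = pixels[::2, ::2] if min(pixels.shape) >= 8 else pixels
        thr = float(threshold_otsu(sample))
    else:
        thr = float(threshold)
    fg = pixels < thr
    if not fg.any():
        raise NoBlobFoundError(f"no pixel below threshold {thr:.4f}")
    labels, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        counts = np.bincount(labels.ravel())[1:]
        fg = labels == (int(np.argmax(counts)) + 1)
    # fill holes inside the component; work on its bounding slice only
    window = ndimage.find_objects(fg.astype(np.int8))[0]
    fg[window] = ndimage.binary_fill_holes(fg[window])
    return BlobMask(fg)


_MOORE = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def _trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Moore-neighbour trace of the outer boundary; returns the cyclic pixel
    sequence (padding-free coordinates).

    The walk starts at the raster-first foreground pixel entered from the
    west and proceeds clockwise, re-scanning from the backtrack pixel; it
    terminates on re-entering the start pixel with the same continuation as
    the first move (Jacob's criterion). One-pixel-wide spurs are traversed on
    both sides, so their two flanks both contribute to the walk length.
    """
    if mask.sum() == 1:
        return np.argwhere(mask)
    padded = np.pad(mask, 1)
    fg = np.argwhere(padded)
    start = tuple(fg[np.lexsort((fg[:, 1], fg[:, 0]))][0])
    backtrack = (start[0], start[1] - 1)  # background by raster-order choice
    contour: list[tuple[int, int]] = []
    cur, first_move = start, None
    limit = 8 * int(mask.sum()) + 16
    while True:
        bi = _MOORE.index((backtrack[0] - cur[0], backtrack[1] - cur[1]))
        nxt = new_bt = None
        for i in range(1, 9):
            d = (bi + i) % 8
            cand = (cur[0] + _MOORE[d][0], cur[1] + _MOORE[d][1])
            if padded[cand[0], cand[1]]:
                nxt = cand
                pb = (d - 1) % 8
                new_bt = (cur[0] + _MOORE[pb][0], cur[1] + _MOORE[pb][1])
                break
        if nxt is None:  # unreachable for connected blobs of area >= 2
            break
        if cur == start:
            if first_move == nxt:
                break
            if first_move is None:
                first_move = nxt
        contour.append(cur)
        cur, backtrack = nxt, new_bt
        if len(contour) > limit:  # safety against pathological masks
            break
    pts = np.array(contour)
    return pts - 1  # undo padding offset


def _boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels touching background through a 4-neighbour (or edge)."""
    window = ndimage.find_objects(mask.astype(np.int8))[0]
    sub = mask[window]
    eroded = ndimage.binary_erosion(sub, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool), border_value=0)
    pts = np.argwhere(sub & ~eroded)
    return pts + np.array([window[0].start, window[1].start])


def blob_features(blob: BlobMask) -> GeometricFeatures:
    """Area, perimeter, max Feret diameter, centroid and bbox of a blob.

    Perimeter is the Euclidean length of the traced outer boundary walk (axis
    steps count 1, diagonal steps sqrt(2)); a 10x10 solid square measures
    exactly 36. Maximum diameter is the largest pairwise distance between
    boundary pixel centers — for a filled set this equals the maximum over
    all foreground pixel pairs, since diameters are attained on the boundary.
    """
    mask = blob.mask
    area = blob.n_foreground
    coords = np.argwhere(mask)
    centroid = (float(coords[:, 0].mean()), float(coords[:, 1].mean()))
    bbox = (
        int(coords[:, 0].min()),
        int(coords[:, 1].min()),
        int(coords[:, 0].max()),
        int(coords[:, 1].max()),
    )
    if area == 1:
        return GeometricFeatures(1, 0.0, 0.0, centroid, bbox)
    contour = _trace_boundary(mask)
    steps = np.diff(np.vstack([contour, contour[:1]]).astype(float), axis=0)
    perimeter = float(np.linalg.norm(steps, axis=1).sum())
    boundary = _boundary_pixels(mask).astype(float)
    if len(boundary) > 400:
        try:
            boundary = boundary[ConvexHull(boundary).vertices]
        except Exception:  # degenerate (collinear) point sets
            pass
    max_diameter = float(pdist(boundary).max()) if len(boundary) > 1 else 0.0
    return GeometricFeatures(area, perimeter, max_diameter, centroid, bbox)


def _crop_window(frame_height: int, blob_rows: np.ndarray, crop_height: int) -> tuple[int, int]:
    """Vertical window (top, height) centered on the blob, clamped to frame."""
    bbox_height = int(blob_rows[-1] - blob_rows[0] + 1)
    out_height = max(crop_height, bbox_height)
    center = (blob_rows[0] + blob_rows[-1]) / 2.0
    top = int(round(center - out_height / 2.0))
    if frame_height >= out_height:
        top = max(0, min(top, frame_height - out_height))
    else:
        top = 0
    return top, out_height


def crop_to_standard(frame: Frame, blob: BlobMask, crop_height: int = 496) -> Frame:
    """Crop to the cuvette-standard geometry: full 496-px width, 496-px height
    (or the blob's bbox height when taller) vertically centered on the blob.

    The vertical window is clamped to the frame and padded with the background
    intensity where it would overhang, so the output shape is exact.
    """
    return crop_with_mask(frame, blob, crop_height)[0]


def crop_with_mask(
    frame: Frame, blob: BlobMask, crop_height: int = 496
) -> tuple[Frame, np.ndarray]:
    """Like :func:`crop_to_standard` but also returns the congruently cropped
    blob mask (padded with background / False where the window overhangs)."""
    if frame.width != CUVETTE_WIDTH_PX:
        raise ValueError(
            f"frame width {frame.width} != cuvette standard {CUVETTE_WIDTH_PX}"
        )
    if blob.mask.shape != frame.pixels.shape:
        raise ValueError("blob mask must come from this frame")
    rows = np.nonzero(blob.mask.any(axis=1))[0]
    top, out_height = _crop_window(frame.height, rows, crop_height)
    out = np.full((out_height, CUVETTE_WIDTH_PX), BACKGROUND)
    out_mask = np.zeros((out_height, CUVETTE_WIDTH_PX), dtype=bool)
    src_lo = max(top, 0)
    src_hi = min(top + out_height, frame.height)
    out[src_lo - top : src_hi - top, :] = frame.pixels[src_lo:src_hi, :]
    out_mask[src_lo - top : src_hi - top, :] = blob.mask[src_lo:src_hi, :]
    return Frame(out), out_mask


def estimate_body_size(
    areas: list[float] | np.ndarray,
    field_width_mm: float = CUVETTE_WIDTH_MM,
    field_width_px: int = CUVETTE_WIDTH_PX,
) -> BodySize:
    """Convert per-frame silhouette areas (px) into a body-size estimate (mm2).

    Body size is the mean area across all of a specimen's frames; the
    conversion factor is the squared pixel pitch implied by the cuvette
    width, (field_width_mm / field_width_px)^2.
    """
    areas = np.asarray(areas, dtype=float)
    if areas.size == 0:
        raise ValueError("at least one area required")
    if (areas < 1).any():
        raise ValueError("areas must be >= 1 px")
    px_to_mm2 = (field_width_mm / field_width_px) ** 2
    mean_px = float(areas.mean())
    return BodySize(mean_px, mean_px * px_to_mm2, px_to_mm2)
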