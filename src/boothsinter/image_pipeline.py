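"""From a raw 8-bit backlit frame to a centered, polar-converted contour.

The pipeline mirrors standard morphological image analysis of a backlit
silhouette of two coalescing filaments:

1. crop a region of interest (grey levels untouched);
2. threshold to a binary mask (dark object on bright background by default),
   keep the largest 8-connected component and fill enclosed holes;
3. extract the contour as the pixels removed by one binary erosion with a
   3x3 square structuring element, optionally excluding a bottom "oven base"
   strip;
4. locate the centroid of the mask;
5. measure the maximum horizontal length L_max (whole-pixel, side to side);
6. re-center the contour on (row of L_max, centroid column) and convert to
   polar coordinates r = sqrt(x^2 + y^2), phi = atan2(y, x).

Coordinate conventions, in one place: image arrays are indexed (row, col)
with row 0 at the top; centered coordinates are x = col - centroid_col,
y = row_of_L_max - row, so y increases upward and phi is measured from the
positive x axis in (-pi, pi].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

__all__ = [
    "FrameImage",
    "BinaryMask",
    "RawContour",
    "ContourPointSet",
    "Rect",
    "crop_roi",
    "segment",
    "contour_pixels",
    "centroid",
    "max_horizontal_length",
    "center_and_polarize",
    "extract_contour",
]

_STRUCT_3X3 = np.ones((3, 3), dtype=bool)


@dataclass
class FrameImage:
    """One 8-bit grayscale frame with acquisition time and pixel scale."""

    pixels: np.ndarray  # 2-D uint8-valued array, grey levels 0-255
    time_s: float = 0.0
    pixel_scale: float = 1.0  # pixels per mm
    name: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"frame must be 2-D grayscale, got shape {px.shape}")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("grey levels must lie within [0, 255] (8-bit)")
        self.pixels = px


@dataclass
class BinaryMask:
    """Binary object mask: one filled foreground component, value True."""

    pixels: np.ndarray  # 2-D bool
    threshold: float | None = None
    polarity: str = "dark_object"

    @property
    def n_foreground(self) -> int:
        return int(self.pixels.sum())


@dataclass
class RawContour:
    """Contour pixels in image coordinates, before centering.

    ``rows``/``cols`` index the retained contour pixels; the counts keep the
    conservation bookkeeping |contour| + |interior| + |excluded| = |mask|.
    """

    rows: np.ndarray
    cols: np.ndarray
    n_interior: int
    n_excluded: int
    mask_shape: tuple[int, int]

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class ContourPointSet:
    """Centered Cartesian and polar contour coordinates of one frame."""

    x: np.ndarray
    y: np.ndarray
    r: np.ndarray
    phi: np.ndarray
    center: tuple[float, float]  # (row_of_L_max, centroid_col) in image coords
    L_max: int
    time_s: float = 0.0
    name: str = ""
    #: True when the points are rasterized pixel centers (the physical edge
    #: then passes about half a pixel outside them); False for exact samples.
    pixel_grid: bool = False

    def __len__(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class Rect:
    """Rectangular ROI in image coordinates (top-left corner + size)."""

    row: int
    col: int
    height: int
    width: int


def crop_roi(frame: FrameImage, roi: Rect) -> FrameImage:
    """Crop the region of interest; grey levels and 8-bit coding unchanged."""
    nrows, ncols = frame.pixels.shape
    if roi.height <= 0 or roi.width <= 0:
        raise ValueError(f"empty ROI {roi}")
    if roi.row < 0 or roi.col < 0 or roi.row + roi.height > nrows or roi.col + roi.width > ncols:
        raise ValueError(f"ROI {roi} extends outside a {nrows}x{ncols} frame")
    sub = frame.pixels[roi.row : roi.row + roi.height, roi.col : roi.col + roi.width]
    return FrameImage(sub.copy(), time_s=frame.time_s, pixel_scale=frame.pixel_scale, name=frame.name)


def segment(frame: FrameImage, threshold: float, polarity: str = "dark_object") -> BinaryMask:
    """Threshold the frame into a single filled foreground object.

    ``dark_object``: foreground = grey <= threshold (backlit silhouette);
    ``bright_object``: foreground = grey >= threshold.  Only the largest
    8-connected component is kept and its enclosed holes are filled, so the
    mask is one solid object regardless of internal bubbles.
    """
    if not 0 <= threshold <= 255:
        raise ValueError(f"threshold must be in [0, 255], got {threshold}")
    if polarity == "dark_object":
        fg = frame.pixels <= threshold
    elif polarity == "bright_object":
        fg = frame.pixels >= threshold
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    if not fg.any():
        raise ValueError("segmentation produced an empty foreground")
    labels = measure.label(fg, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    keep = labels == counts.argmax()
    keep = ndimage.binary_fill_holes(keep)
    return BinaryMask(pixels=keep, threshold=float(threshold), polarity=polarity)


def contour_pixels(mask: BinaryMask, base_rows_excluded: int = 0) -> RawContour:
    """Contour = mask minus its 3x3 binary erosion, minus the base strip.

    Pixels outside the image count as background, so foreground pixels on the
    image border are always contour.  The bottom ``base_rows_excluded`` rows
    (the oven base) are removed from the contour but kept in the bookkeeping.
    """
    m = mask.pixels
    eroded = ndimage.binary_erosion(m, structure=_STRUCT_3X3, border_value=0)
    if not eroded.any():
        raise ValueError("mask vanishes under 3x3 erosion (object thinner than 3 px)")
    contour = m & ~eroded
    nrows = m.shape[0]
    if base_rows_excluded > 0:
        base = np.zeros_like(contour)
        base[nrows - base_rows_excluded :, :] = True
        excluded = contour & base
        contour = contour & ~base
    else:
        excluded = np.zeros_like(contour)
    rows, cols = np.nonzero(contour)
    return RawContour(
        rows=rows,
        cols=cols,
        n_interior=int(eroded.sum()),
        n_excluded=int(excluded.sum()),
        mask_shape=m.shape,
    )


def centroid(mask: BinaryMask) -> tuple[float, float]:
    """Centroid (mean row, mean col) of the foreground; may be fractional."""
    rows, cols = np.nonzero(mask.pixels)
    if len(rows) == 0:
        raise ValueError("empty mask has no centroid")
    return float(rows.mean()), float(cols.mean())


def max_horizontal_length(mask: BinaryMask) -> tuple[int, int]:
    """Maximum side-to-side horizontal extent L_max and the row where it occurs.

    Row length is rightmost minus leftmost foreground column plus one (gaps
    included).  Ties are broken toward the centroid row, then the smaller row.
    """
    m = mask.pixels
    if not m.any():
        raise ValueError("empty mask has no horizontal extent")
    any_fg = m.any(axis=1)
    left = np.where(any_fg, m.argmax(axis=1), 0)
    right = np.where(any_fg, m.shape[1] - 1 - m[:, ::-1].argmax(axis=1), -1)
    lengths = np.where(any_fg, right - left + 1, 0)
    L_max = int(lengths.max())
    tied = np.nonzero(lengths == L_max)[0]
    c_row, _ = centroid(mask)
    dist = np.abs(tied - c_row)
    best = tied[np.lexsort((tied, dist))][0]
    return L_max, int(best)


def center_and_polarize(
    contour: RawContour, centroid_col: float, row_of_L_max: int, *, time_s: float = 0.0, name: str = ""
) -> ContourPointSet:
    """Center the contour and convert to polar coordinates.

    x = col - centroid_col, y = row_of_L_max - row (y points up),
    r = sqrt(x^2 + y^2), phi = atan2(y, x) in (-pi, pi] (phi = 0 at the
    origin by the atan2 convention).
    """
    if len(contour) == 0:
        raise ValueError("empty contour")
    x = contour.cols.astype(float) - float(centroid_col)
    y = float(row_of_L_max) - contour.rows.astype(float)
    r = np.hypot(x, y)
    phi = np.arctan2(y, x)
    return ContourPointSet(
        x=x, y=y, r=r, phi=phi,
        center=(float(row_of_L_max), float(centroid_col)),
        L_max=0, time_s=time_s, name=name, pixel_grid=True,
    )


def extract_contour(
    frame: FrameImage,
    threshold: float,
    polarity: str = "dark_object",
    roi: Rect | None = None,
    base_rows_excluded: int = 0,
) -> ContourPointSet:
    """Run steps 1-6 on one frame and return the centered polar contour.

    Convenience composition of :func:`crop_roi`, :func:`segment`,
    :func:`contour_pixels`, :func:`centroid`, :func:`max_horizontal_length`
    and :func:`center_and_polarize`; the returned point set carries L_max.
    """
    if roi is not None:
        frame = crop_roi(frame, roi)
    mask = segment(frame, threshold, polarity)
    raw = contour_pixels(mask, base_rows_excluded)
    _, c_col = centroid(mask)
    L_max, row_L = max_horizontal_length(mask)
    pts = center_and_polarize(raw, c_col, row_L, time_s=frame.time_s, name=frame.name)
    pts.L_max = L_max
    return pts
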