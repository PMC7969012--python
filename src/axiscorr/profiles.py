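"""Width-averaged intensity profiles along traced chromosome axes.

Mirrors the ImageJ wide-line workflow used for chromosome-spread images:
an axis fragment is a polyline trace over a grayscale channel; the
profile value at each unit step of arc length is the mean of ``width_px``
bilinearly interpolated samples taken perpendicular to the local trace
direction, centered on the trace.  A per-cell background mean, measured
over 2-3 nuclear regions free of axes, is subtracted from every channel.

Coordinate convention: ``(row, col)``, 0-based, pixel centers at integer
coordinates.  Traces and regions use this convention throughout,
including the ImageJ ROI reader (which converts from ImageJ's x/y).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path as _MplPath
from scipy import ndimage

__all__ = [
    "OutOfBoundsError",
    "InvalidWidthError",
    "ImageChannel",
    "AxisTrace",
    "BackgroundSet",
    "AxisProfile",
    "rect_region",
    "sample_profile",
    "measure_background",
    "subtract_background",
    "extract_profiles",
]


class OutOfBoundsError(ValueError):
    """A trace (after width expansion) or region leaves the image."""


class InvalidWidthError(ValueError):
    """Sampling width must be an odd positive integer."""


@dataclass(frozen=True)
class ImageChannel:
    """One grayscale channel of a microscopy image.

    ``pixels`` holds non-negative intensities in arbitrary units;
    ``pixel_size_nm`` is the physical pixel size along the axis
    (65 nm for the spread images this package targets).
    """

    pixels: np.ndarray
    channel_name: str
    pixel_size_nm: float = 65.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if not np.all(np.isfinite(px)) or np.any(px < 0):
            raise ValueError("intensities must be finite and >= 0")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class AxisTrace:
    """A polyline axis trace in (row, col) pixel coordinates."""

    vertices: np.ndarray
    width_px: int = 5
    cell_id: str = ""
    fragment_id: str = ""

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.vertices, dtype=float))
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
            raise ValueError("vertices must be an (n >= 2, 2) array of (row, col)")
        if not np.all(np.isfinite(v)):
            raise ValueError("vertices must be finite")
        if np.any(np.all(np.diff(v, axis=0) == 0, axis=1)):
            raise ValueError("consecutive vertices must be distinct")
        if self.width_px < 1:
            raise InvalidWidthError("width_px must be >= 1")
        if self.width_px % 2 == 0:
            raise InvalidWidthError("width_px must be odd")
        object.__setattr__(self, "vertices", v)

    @property
    def arc_length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.vertices, axis=0), axis=1)))


@dataclass
class BackgroundSet:
    """Polygonal background regions shared by all channels of a cell.

    Each region is an (n, 2) array of (row, col) polygon vertices; a
    pixel belongs to a region if its center lies inside the polygon.
    Overlapping regions are counted once (union semantics).
    """

    regions: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.regions:
            raise ValueError("at least one background region required")
        self.regions = [np.asarray(r, dtype=float) for r in self.regions]
        for r in self.regions:
            if r.ndim != 2 or r.shape[1] != 2 or r.shape[0] < 3:
                raise ValueError("each region needs >= 3 (row, col) vertices")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean union mask of all regions on a pixel grid."""
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        centers = np.column_stack([rr.ravel(), cc.ravel()])
        mask = np.zeros(shape[0] * shape[1], dtype=bool)
        for poly in self.regions:
            path = _MplPath(poly)
            inside = path.contains_points(centers)
            if not inside.any():
                raise ValueError("background region contains no pixel centers")
            mask |= inside
        return mask.reshape(shape)


@dataclass
class AxisProfile:
    """Background-subtracted per-position intensities of one fragment.

    ``intensities`` maps channel name to a length-L vector; values may
    be negative after background subtraction (retained deliberately —
    per-fragment scaling removes the mean later anyway).
    """

    intensities: dict
    cell_id: str = ""
    fragment_id: str = ""
    condition: str = ""
    pixel_size_nm: float = 65.0

    def __post_init__(self) -> None:
        if not self.intensities:
            raise ValueError("profile needs at least one channel")
        clean = {k: np.asarray(v, dtype=float) for k, v in self.intensities.items()}
        lengths = {v.size for v in clean.values()}
        if len(lengths) != 1:
            raise ValueError("all channel vectors must share one length")
        if min(lengths) < 2:
            raise ValueError("profile length must be >= 2")
        for v in clean.values():
            if v.ndim != 1 or not np.all(np.isfinite(v)):
                raise ValueError("channel vectors must be finite 1-D arrays")
        self.intensities = clean

    @property
    def length(self) -> int:
        return next(iter(self.intensities.values())).size

    @property
    def positions_px(self) -> np.ndarray:
        return np.arange(self.length)

    @property
    def channels(self) -> list:
        return list(self.intensities)


def rect_region(row0: int, row1: int, col0: int, col1: int) -> np.ndarray:
    """Polygon covering pixel centers ``row0..row1`` x ``col0..col1`` inclusive."""
    return np.array(
        [
            [row0 - 0.5, col0 - 0.5],
            [row0 - 0.5, col1 + 0.5],
            [row1 + 0.5, col1 + 0.5],
            [row1 + 0.5, col0 - 0.5],
        ]
    )


def _arc_samples(trace: AxisTrace) -> tuple[np.ndarray, np.ndarray]:
    """Points and unit tangents at unit arc-length steps along the polyline.

    Returns ``(points, tangents)`` of shape (L, 2) with
    ``L = floor(total arc length) + 1``; the tangent at a sample is the
    direction of the polyline segment the sample falls on.
    """
    verts = trace.vertices
    seg = np.diff(verts, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    t = np.arange(int(np.floor(total)) + 1, dtype=float)
    # segment index for each sample; the final sample may sit exactly on
    # the last vertex, clamp it onto the last segment
    idx = np.clip(np.searchsorted(cum, t, side="right") - 1, 0, len(seg) - 1)
    frac = (t - cum[idx]) / seg_len[idx]
    points = verts[idx] + frac[:, None] * seg[idx]
    tangents = seg[idx] / seg_len[idx][:, None]
    return points, tangents


def sample_profile(channel: ImageChannel, trace: AxisTrace) -> np.ndarray:
    """Width-averaged intensity at each unit arc-length step of a trace.

    Each output value is the mean of ``trace.width_px`` samples spaced
    one pixel apart along the local normal, centered on the trace, with
    bilinear interpolation at fractional coordinates.  Raises
    :class:`OutOfBoundsError` if any sample falls outside the image.
    """
    points, tangents = _arc_samples(trace)
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])
    w = trace.width_px
    offsets = np.arange(w, dtype=float) - (w - 1) / 2.0
    # (L, w, 2) sample coordinates
    coords = points[:, None, :] + offsets[None, :, None] * normals[:, None, :]
    nrow, ncol = channel.shape
    rows, cols = coords[..., 0], coords[..., 1]
    if (
        rows.min() < 0
        or cols.min() < 0
        or rows.max() > nrow - 1
        or cols.max() > ncol - 1
    ):
        raise OutOfBoundsError(
            "trace leaves the image after width expansion "
            f"(rows {rows.min():.2f}..{rows.max():.2f}, "
            f"cols {cols.min():.2f}..{cols.max():.2f}, image {nrow}x{ncol})"
        )
    sampled = ndimage.map_coordinates(
        channel.pixels, [rows.ravel(), cols.ravel()], order=1, mode="nearest"
    ).reshape(rows.shape)
    return sampled.mean(axis=1)


def measure_background(channel: ImageChannel, regions: BackgroundSet) -> float:
    """Mean intensity over the union of background-region pixels."""
    mask = regions.mask(channel.shape)
    return float(channel.pixels[mask].mean())


def subtract_background(profile: np.ndarray, background: float) -> np.ndarray:
    """Subtract a scalar background; negative values are retained."""
    if not np.isfinite(background):
        raise ValueError("background must be finite")
    v = np.asarray(profile, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("profile contains non-finite values")
    return v - background


def extract_profiles(
    channels,
    traces,
    backgrounds: BackgroundSet | None = None,
    condition: str = "",
) -> list[AxisProfile]:
    """Sample every trace across all channels and subtract backgrounds.

    ``channels`` is a list of :class:`ImageChannel` sharing dimensions.
    All channels are sampled along identical geometry; each is corrected
    with its own background mean measured over the shared region set
    (``backgrounds=None`` skips subtraction).
    """
    channels = list(channels)
    if not channels:
        raise ValueError("need at least one channel")
    shapes = {c.shape for c in channels}
    if len(shapes) != 1:
        raise ValueError(f"channels must share dimensions, got {shapes}")
    bg = {
        c.channel_name: (measure_background(c, backgrounds) if backgrounds else 0.0)
        for c in channels
    }
    profiles = []
    for trace in traces:
        intensities = {
            c.channel_name: subtract_background(sample_profile(c, trace), bg[c.channel_name])
            for c in channels
        }
        profiles.append(
            AxisProfile(
                intensities=intensities,
                cell_id=trace.cell_id,
                fragment_id=trace.fragment_id,
                condition=condition,
                pixel_size_nm=channels[0].pixel_size_nm,
            )
        )
    return profiles
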