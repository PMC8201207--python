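"""Radiometric RoI segmentation and false-color rendering.

The segmentation chain works directly on the temperature matrix rather than
on a rendered picture: normalize the grid to [0, 1], zero everything below a
threshold (default 0.8), binarize, label 4-connected components, and keep
the largest, most central component as the region of interest (RoI).  Warm
interference blobs near the borders are smaller than the limb and are
discarded by the area criterion, without any morphological operators.

The method inherits a documented limitation: if an interference is so hot
that, after range normalization, the limb itself falls below the threshold,
the interference is selected instead of the limb.  The phantom generator can
construct exactly this condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from matplotlib import colormaps
from skimage import measure

from .errors import DegenerateFrameError, EmptyRoIWarning, ParameterError, ValidationError
from .io import TemperatureFrame

DEFAULT_TAU = 0.8


@dataclass(frozen=True)
class NormalizedFrame:
    """Range-normalized grid in [0, 1] plus the Celsius extrema used."""

    values: np.ndarray
    src_min_c: float
    src_max_c: float

    def denormalize(self) -> np.ndarray:
        """Map the normalized grid back to degrees Celsius."""
        return self.values * (self.src_max_c - self.src_min_c) + self.src_min_c


@dataclass(frozen=True)
class ThresholdedFrame:
    """Normalized grid with sub-threshold cells zeroed."""

    values: np.ndarray
    tau: float


@dataclass(frozen=True)
class BinaryMask:
    """Indicator grid of cells that survived thresholding."""

    values: np.ndarray  # uint8 {0, 1}


@dataclass(frozen=True)
class RegionInfo:
    """Summary of one 4-connected foreground component."""

    label: int
    area_px: int
    centroid: tuple[float, float]  # (row, col)
    bbox: tuple[int, int, int, int]  # (top, left, height, width)
    touches_border: bool


@dataclass(frozen=True)
class SegmentationResult:
    """All intermediate and final products of the segmentation chain.

    ``cleaned`` is the thresholded grid with every non-RoI component zeroed;
    ``roi_temps_c`` holds the *original* Celsius values at RoI pixels (the
    chain never alters temperatures), and ``roi_mask`` their support.
    """

    normalized: NormalizedFrame
    thresholded: ThresholdedFrame
    mask: BinaryMask
    regions: tuple[RegionInfo, ...]
    roi_label: int | None
    cleaned: ThresholdedFrame
    roi_mask: np.ndarray  # bool H x W
    roi_temps_c: np.ndarray  # 1-D, raster order

    @property
    def roi_area_px(self) -> int:
        return int(self.roi_mask.sum())


def normalize(frame: TemperatureFrame) -> NormalizedFrame:
    """Affinely map the temperature grid onto [0, 1].

    Raises :class:`DegenerateFrameError` for a constant grid, which carries
    no contrast to segment.
    """
    lo = float(frame.values.min())
    hi = float(frame.values.max())
    if hi <= lo:
        raise DegenerateFrameError(
            f"constant grid at {lo} C cannot be normalized"
        )
    return NormalizedFrame((frame.values - lo) / (hi - lo), lo, hi)


def threshold(norm: NormalizedFrame, tau: float = DEFAULT_TAU) -> ThresholdedFrame:
    """Zero normalized cells below ``tau``; cells >= ``tau`` are kept as-is."""
    if not 0.0 < tau < 1.0:
        raise ParameterError(f"tau must lie in (0, 1), got {tau}")
    return ThresholdedFrame(np.where(norm.values >= tau, norm.values, 0.0), tau)


def binarize(thresh: ThresholdedFrame) -> BinaryMask:
    """Indicator of nonzero thresholded cells."""
    return BinaryMask((thresh.values > 0).astype(np.uint8))


def label_components(mask: BinaryMask) -> tuple[RegionInfo, ...]:
    """Label 4-connected foreground components (Manhattan radius 1).

    Labels follow raster order of each component's first pixel.  Diagonal
    contact does not connect under 4-connectivity.
    """
    labeled = measure.label(mask.values, connectivity=1)
    h, w = mask.values.shape
    regions = []
    for rp in measure.regionprops(labeled):
        top, left, bottom, right = rp.bbox
        regions.append(
            RegionInfo(
                label=int(rp.label),
                area_px=int(rp.area),
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
                bbox=(int(top), int(left), int(bottom - top), int(right - left)),
                touches_border=top == 0 or left == 0 or bottom == h or right == w,
            )
        )
    regions.sort(key=lambda r: r.label)
    return tuple(regions)


def select_roi(regions: Sequence[RegionInfo], frame_shape: tuple[int, int]) -> int | None:
    """Pick the RoI label: largest area, then most central, then lowest label.

    The limb is always the largest warm component near the frame center;
    interferences are smaller and sit at the borders.  Returns ``None`` for
    an empty region list.
    """
    if not regions:
        return None
    center = ((frame_shape[0] - 1) / 2.0, (frame_shape[1] - 1) / 2.0)

    def key(r: RegionInfo):
        dist = np.hypot(r.centroid[0] - center[0], r.centroid[1] - center[1])
        return (-r.area_px, dist, r.label)

    return min(regions, key=key).label


def segment(frame: TemperatureFrame, tau: float = DEFAULT_TAU) -> SegmentationResult:
    """Run the full chain: normalize, threshold, binarize, label, select RoI.

    Every non-RoI component of the thresholded grid is zeroed; the Celsius
    values of the original frame at RoI pixels are extracted untouched.
    """
    norm = normalize(frame)
    thr = threshold(norm, tau)
    mask = binarize(thr)
    regions = label_components(mask)
    roi = select_roi(regions, frame.shape)
    labeled = measure.label(mask.values, connectivity=1)
    if roi is None:
        warnings.warn(
            f"frame {frame.frame_id!r}: no region survived thresholding", EmptyRoIWarning
        )
        roi_mask = np.zeros(frame.shape, dtype=bool)
    else:
        roi_mask = labeled == roi
    cleaned = ThresholdedFrame(np.where(roi_mask, thr.values, 0.0), tau)
    return SegmentationResult(
        normalized=norm,
        thresholded=thr,
        mask=mask,
        regions=regions,
        roi_label=roi,
        cleaned=cleaned,
        roi_mask=roi_mask,
        roi_temps_c=np.asarray(frame.values)[roi_mask],
    )


def roi_percentage(roi_area_px: int, frame_shape: tuple[int, int] = (240, 320)) -> float:
    """Share of frame pixels occupied by the RoI, in percent (two decimals)."""
    total = frame_shape[0] * frame_shape[1]
    if not 0 <= roi_area_px <= total:
        raise ValidationError(
            f"RoI area {roi_area_px} outside [0, {total}] for shape {frame_shape}"
        )
    return round(100.0 * roi_area_px / total, 2)


@dataclass(frozen=True)
class FalseColorImage:
    """False-color rendering of a segmented frame with an invertible mapping.

    The 256-entry colormap lookup table reserves entry 0 for the background;
    RoI values are mapped linearly over entries 1..255 from the RoI's lowest
    normalized value up to 1.  ``background_color`` is therefore never used
    by any RoI pixel, which makes background keying exact downstream.
    """

    pixels: np.ndarray  # H x W x 3 uint8
    background_color: tuple[int, int, int]
    lut: np.ndarray  # 256 x 3 uint8
    norm_range: tuple[float, float]  # (lowest RoI normalized value, 1.0)
    temp_range_c: tuple[float, float]  # Celsius values of norm_range endpoints
    roi_mask: np.ndarray  # bool H x W

    def value_for_index(self, idx: np.ndarray | int) -> np.ndarray | float:
        """Normalized value encoded by LUT entries 1..255."""
        lo, hi = self.norm_range
        return lo + (np.asarray(idx) - 1) / 254.0 * (hi - lo)

    def index_for_value(self, value: np.ndarray | float) -> np.ndarray:
        return _index_for_value(value, *self.norm_range)

    def temp_for_index(self, idx: np.ndarray | int) -> np.ndarray | float:
        """Celsius temperature encoded by LUT entries 1..255."""
        lo, hi = self.temp_range_c
        return lo + (np.asarray(idx) - 1) / 254.0 * (hi - lo)

    def temp_for_color(self, rgb, tol: int = 8):
        """Invert RoI colors to temperatures by nearest LUT entry (1..255).

        Colors farther than ``tol`` per-channel units from every RoI LUT
        entry — including the reserved background entry 0 — yield NaN.
        """
        color = np.asarray(rgb, dtype=int)
        diff = np.abs(self.lut.astype(int) - color[..., None, :]).max(axis=-1)
        idx = diff.argmin(axis=-1)
        ok = (diff.min(axis=-1) <= tol) & (idx > 0)
        return np.where(ok, self.temp_for_index(np.maximum(idx, 1)), np.nan)


def _index_for_value(value, lo: float, hi: float) -> np.ndarray:
    """Map normalized values in [lo, hi] onto LUT entries 1..255."""
    arr = np.asarray(value, dtype=float)
    if hi <= lo:
        return np.full(arr.shape, 255, dtype=int)
    return 1 + np.clip(np.rint((arr - lo) / (hi - lo) * 254), 0, 254).astype(int)


def colormap_lut(name: str = "jet") -> np.ndarray:
    """256 x 3 uint8 lookup table for a matplotlib colormap, made injective.

    8-bit quantization can collapse neighboring entries onto the same color
    (jet saturates at pure blue for a few entries); colliding entries are
    nudged by single 8-bit units so every entry is unique and the table is
    exactly invertible by color lookup.
    """
    cmap = colormaps[name]
    lut = np.rint(np.asarray(cmap(np.linspace(0.0, 1.0, 256)))[:, :3] * 255).astype(np.uint8)
    seen = set()
    for i in range(256):
        color = tuple(int(c) for c in lut[i])
        bump = 0
        while color in seen:
            bump += 1
            for ch in (1, 0, 2):  # prefer nudging green: most headroom in jet
                for cand in (color[ch] + bump, color[ch] - bump):
                    if 0 <= cand <= 255:
                        trial = list(color)
                        trial[ch] = cand
                        if tuple(trial) not in seen:
                            color = tuple(trial)
                            break
                else:
                    continue
                break
        seen.add(color)
        lut[i] = color
    return lut


def render_false_color(result: SegmentationResult, colormap: str = "jet") -> FalseColorImage:
    """Render the cleaned frame as a false-color image (blue = background).

    The blue end of the colormap is reserved for the background; RoI values
    span the rest of the colormap from the RoI's coolest surviving value to
    the frame maximum, boosting contrast inside the limb.  The value-to-color
    mapping is recorded so colors can be inverted back to values.
    """
    lut = colormap_lut(colormap)
    h, w = result.cleaned.values.shape
    pixels = np.empty((h, w, 3), dtype=np.uint8)
    pixels[:] = lut[0]
    roi = result.roi_mask
    if not roi.any():
        warnings.warn("empty RoI: rendering uniform background image", EmptyRoIWarning)
        lo = hi = 1.0
    else:
        vals = result.cleaned.values[roi]
        lo, hi = float(vals.min()), 1.0
        pixels[roi] = lut[_index_for_value(vals, lo, hi)]
    nrm = result.normalized
    temp_lo = lo * (nrm.src_max_c - nrm.src_min_c) + nrm.src_min_c
    return FalseColorImage(
        pixels=pixels,
        background_color=tuple(int(c) for c in lut[0]),
        lut=lut,
        norm_range=(lo, hi),
        temp_range_c=(temp_lo, nrm.src_max_c),
        roi_mask=roi,
    )
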