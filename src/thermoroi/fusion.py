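"""IR/visible multimodal fusion.

The bifocal camera captures both modalities in one shot with a fixed
geometry, so no per-pair registration is estimated: the visible photograph
is rescaled by the fixed inter-sensor factor (default 1.25), the false-color
RoI overlay is composited center-aligned with its background keyed out, and
the result is cropped to the shared field of view (default 400 x 300).

The overlay is never resampled: interpolating colors across the RoI edge
would invent temperatures that were never measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image

from .errors import GeometryError, ParameterError
from .io import as_uint8_rgb
from .segmentation import FalseColorImage

DEFAULT_SCALE = 1.25
DEFAULT_CROP = (400, 300)  # (width, height)
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class OverlayImage:
    """RGBA overlay whose alpha is 0 exactly on the keyed-out background."""

    pixels: np.ndarray  # H x W x 4 uint8
    alpha: np.ndarray  # H x W float in [0, 1]


@dataclass(frozen=True)
class MergedImage:
    """Composited IR-over-visible image cropped to the shared field of view."""

    pixels: np.ndarray  # crop_h x crop_w x 3 uint8
    provenance: dict = field(default_factory=dict)


def background_to_black(img: FalseColorImage) -> FalseColorImage:
    """Replace background pixels with black, leaving the RoI untouched.

    The segmentation mask carried by the image is the authoritative
    background definition; pixels equal to the recorded background sentinel
    color (historically blue, e.g. RGB(0, 0, 131)) are chased as well for
    compatibility with externally produced renderings.  Idempotent.
    """
    pixels = img.pixels.copy()
    sentinel = np.all(pixels == np.array(img.background_color, dtype=np.uint8), axis=-1)
    background = sentinel | ~img.roi_mask
    pixels[background] = 0
    return FalseColorImage(
        pixels=pixels,
        background_color=(0, 0, 0),
        lut=img.lut,
        norm_range=img.norm_range,
        temp_range_c=img.temp_range_c,
        roi_mask=img.roi_mask,
    )


def alpha_mask(img: FalseColorImage, a: float = 1.0) -> OverlayImage:
    """Make exactly-black pixels fully transparent, all others opacity ``a``.

    Only exact black is keyed; an RoI pixel that happens to be nearly black
    (e.g. RGB(0, 0, 1)) stays opaque.
    """
    if not 0.0 <= a <= 1.0:
        raise ParameterError(f"opacity must lie in [0, 1], got {a}")
    rgb = as_uint8_rgb(img.pixels)
    black = np.all(rgb == 0, axis=-1)
    alpha = np.where(black, 0.0, float(a))
    rgba = np.dstack([rgb, np.rint(alpha * 255).astype(np.uint8)])
    return OverlayImage(pixels=rgba, alpha=alpha)


def _rescale_visible(visible: np.ndarray, scale: float) -> np.ndarray:
    """Bilinearly rescale the visible photograph by the inter-sensor factor."""
    h, w = visible.shape[:2]
    out_size = (int(round(w * scale)), int(round(h * scale)))
    return np.asarray(Image.fromarray(visible).resize(out_size, Image.BILINEAR))


def coregister(
    visible: np.ndarray,
    overlay: OverlayImage,
    scale: float = DEFAULT_SCALE,
    crop: tuple[int, int] = DEFAULT_CROP,
    frame_ids: tuple[str, str] = ("", ""),
) -> MergedImage:
    """Composite the IR overlay onto the rescaled visible frame and crop.

    The visible frame is rescaled by ``scale`` (bilinear), the overlay is
    alpha-composited center-aligned (no resampling of the overlay itself),
    and the central ``crop`` = (width, height) window is extracted.  Where
    the overlay alpha is 0 the output is bit-identical to the rescaled
    visible image; where it is 1, to the overlay colors.
    """
    visible = as_uint8_rgb(visible)
    if scale <= 0:
        raise ParameterError(f"scale must be positive, got {scale}")
    base = _rescale_visible(visible, scale)
    bh, bw = base.shape[:2]
    oh, ow = overlay.pixels.shape[:2]
    crop_w, crop_h = crop
    if crop_w > bw or crop_h > bh:
        raise GeometryError(
            f"crop {crop_w}x{crop_h} exceeds composited extent {bw}x{bh}"
        )
    if oh > bh or ow > bw:
        raise GeometryError(
            f"overlay {ow}x{oh} larger than rescaled visible {bw}x{bh}"
        )
    top, left = (bh - oh) // 2, (bw - ow) // 2
    comp = base.copy()
    region = comp[top : top + oh, left : left + ow].astype(float)
    fg = overlay.pixels[..., :3].astype(float)
    a = overlay.alpha[..., None]
    blended = np.rint(a * fg + (1.0 - a) * region).astype(np.uint8)
    # exact passthrough at the binary endpoints keeps conservation bit-exact
    opaque = overlay.alpha >= 1.0
    transparent = overlay.alpha <= 0.0
    blended[opaque] = overlay.pixels[..., :3][opaque]
    blended[transparent] = comp[top : top + oh, left : left + ow][transparent]
    comp[top : top + oh, left : left + ow] = blended
    ctop, cleft = (bh - crop_h) // 2, (bw - crop_w) // 2
    pixels = comp[ctop : ctop + crop_h, cleft : cleft + crop_w]
    return MergedImage(
        pixels=np.ascontiguousarray(pixels),
        provenance={
            "scale": scale,
            "crop_window": (int(ctop), int(cleft), int(crop_h), int(crop_w)),
            "overlay_offset": (int(top), int(left)),
            "visible_frame": frame_ids[0],
            "ir_frame": frame_ids[1],
        },
    )


def to_grayscale(img: MergedImage, weights: tuple[float, float, float] = LUMA_WEIGHTS) -> np.ndarray:
    """Weighted R/G/B addition normalized by the weight sum, as 8-bit gray."""
    w = np.asarray(weights, dtype=float)
    if w.min() < 0 or w.sum() <= 0:
        raise ParameterError(f"weights must be nonnegative with positive sum, got {weights}")
    gray = img.pixels.astype(float) @ (w / w.sum())
    return np.rint(gray).astype(np.uint8)
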