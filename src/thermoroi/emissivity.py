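"""Angular-emissivity error measurement and compensation.

Skin emissivity drops as the viewing angle becomes oblique, which biases
the apparent temperature of a rotating-camera sweep.  A linear directional
model quantifies the error of each viewpoint against the normal (frontal)
reference capture:

    delta = (Tn - Ttheta) / (Tn - Ta)

where ``Tn`` is the average temperature of a homogeneous reference zone
(between metatarsal and heel) seen at the normal angle, ``Ttheta`` the same
zone's average at viewing angle theta, and ``Ta`` the room temperature.
``delta`` is a dimensionless fraction; reports print its magnitude as a
percentage.  Compensation adds the constant ``Tn - Ttheta`` back to every
RoI pixel, so the reference-zone average is restored to the normal-view
value while within-RoI temperature differences are preserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, ValidationError
from .io import TemperatureFrame
from .segmentation import BinaryMask, segment


@dataclass(frozen=True)
class ReferenceBox:
    """Axis-aligned pixel box (top, left, height, width) over the reference zone."""

    bbox: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        top, left, h, w = self.bbox
        if h < 1 or w < 1 or top < 0 or left < 0:
            raise ValidationError(f"invalid reference box {self.bbox}")

    def slices(self) -> tuple[slice, slice]:
        top, left, h, w = self.bbox
        return slice(top, top + h), slice(left, left + w)


@dataclass(frozen=True)
class EmissivityRecord:
    """Per-angle directional-emissivity error sample.

    ``delta_t`` keeps its sign (negative when the oblique view reads warmer
    than the normal view, as observed on skin); the reporting layer prints
    magnitudes.
    """

    angle_deg: float
    tn_c: float
    ttheta_c: float
    ta_c: float
    delta_t: float

    @property
    def delta_t_percent(self) -> float:
        """Magnitude of the error as a percentage, two decimals."""
        return round(abs(self.delta_t) * 100.0, 2)

    @property
    def offset_c(self) -> float:
        """Additive Celsius correction restoring the normal-view average."""
        return self.tn_c - self.ttheta_c


def angular_error(tn_c: float, ttheta_c: float, ta_c: float) -> float:
    """Normalized directional-emissivity error (Tn - Ttheta) / (Tn - Ta)."""
    if tn_c == ta_c:
        raise ValidationError(
            f"reference temperature equals room temperature ({tn_c} C): error undefined"
        )
    return (tn_c - ttheta_c) / (tn_c - ta_c)


def region_average(
    frame: TemperatureFrame, box: ReferenceBox, mask: BinaryMask | np.ndarray | None = None
) -> float:
    """Mean temperature over the reference box, restricted to masked pixels."""
    rows, cols = box.slices()
    h, w = frame.shape
    if rows.stop > h or cols.stop > w:
        raise ValidationError(f"reference box {box.bbox} exceeds frame shape {(h, w)}")
    patch = frame.values[rows, cols]
    if mask is not None:
        m = mask.values if isinstance(mask, BinaryMask) else np.asarray(mask)
        sel = m[rows, cols].astype(bool)
        if not sel.any():
            raise ValidationError("reference box does not intersect the RoI mask")
        patch = patch[sel]
    return float(patch.mean())


def profile_from_averages(
    angles_deg: Sequence[float],
    averages_c: Sequence[float],
    ta_c: float,
    ref_angle_deg: float = 0.0,
) -> list[EmissivityRecord]:
    """Build an error profile from already-measured per-angle zone averages."""
    if len(angles_deg) != len(averages_c):
        raise ValidationError("angles and averages differ in length")
    try:
        ref_i = list(angles_deg).index(ref_angle_deg)
    except ValueError:
        raise ConfigurationError(
            f"reference angle {ref_angle_deg} missing from {list(angles_deg)}"
        ) from None
    tn = float(averages_c[ref_i])
    return [
        EmissivityRecord(
            angle_deg=float(theta),
            tn_c=tn,
            ttheta_c=float(t),
            ta_c=float(ta_c),
            delta_t=angular_error(tn, float(t), float(ta_c)),
        )
        for theta, t in zip(angles_deg, averages_c)
    ]


def default_reference_box(roi_bbox: tuple[int, int, int, int]) -> ReferenceBox:
    """Centered box spanning 40% of the RoI bbox height and 20% of its width.

    Approximates the homogeneous zone between metatarsal and heel without
    anatomical landmarks.  The tall-and-narrow shape keeps the box on the
    limb even in oblique views where the silhouette narrows; override with
    an explicit box when landmarks are available.
    """
    top, left, h, w = roi_bbox
    bh = max(1, int(round(0.4 * h)))
    bw = max(1, int(round(0.2 * w)))
    return ReferenceBox((top + (h - bh) // 2, left + (w - bw) // 2, bh, bw))


def build_error_profile(
    frames: Sequence[TemperatureFrame],
    box: ReferenceBox,
    masks: Sequence[np.ndarray] | None = None,
    ref_angle_deg: float = 0.0,
    ta_c: float | None = None,
    tau: float = 0.8,
) -> list[EmissivityRecord]:
    """Measure the per-angle error profile of a sweep.

    The reference-zone average is computed for every frame (segmenting each
    frame for its RoI mask unless masks are supplied); the frame at
    ``ref_angle_deg`` provides ``Tn`` and gets ``delta_t`` exactly 0.
    """
    if masks is None:
        masks = [segment(f, tau).roi_mask for f in frames]
    angles = [f.angle_deg for f in frames]
    if ref_angle_deg not in angles:
        raise ConfigurationError(
            f"reference angle {ref_angle_deg} missing from sweep angles {angles}"
        )
    if ta_c is None:
        ta_c = frames[angles.index(ref_angle_deg)].room_temp_c
    averages = [region_average(f, box, m) for f, m in zip(frames, masks)]
    return profile_from_averages(angles, averages, ta_c, ref_angle_deg)


def interpolate_delta(profile: Sequence[EmissivityRecord], angle_deg: float) -> float:
    """Signed ``delta_t`` at an arbitrary angle, by angular distance to normal.

    Profiles are typically measured on 0-90 degrees only; sweeps extend
    further.  The angle is folded to its distance from the normal view and
    ``delta_t`` is interpolated linearly between the measured samples
    (clamped beyond the last one).
    """
    dist = float(angle_deg) % 360.0
    if dist > 180.0:
        dist = 360.0 - dist
    pts = sorted((r.angle_deg, r.delta_t) for r in profile)
    xs = [p[0] for p in pts]
    ys = [p[1] for p in pts]
    return float(np.interp(dist, xs, ys))


def compensate(
    frame: TemperatureFrame, record: EmissivityRecord, mask: BinaryMask | np.ndarray
) -> TemperatureFrame:
    """Add the constant angular correction to RoI pixels only.

    After compensation the reference-zone average equals ``Tn`` exactly; the
    background is untouched so segmentation contrast is preserved, and all
    pairwise RoI temperature differences are invariant (constant shift).
    """
    m = mask.values if isinstance(mask, BinaryMask) else np.asarray(mask)
    m = m.astype(bool)
    if m.shape != frame.shape:
        raise ValidationError(f"mask shape {m.shape} differs from frame shape {frame.shape}")
    if not m.any():
        raise ValidationError("cannot compensate a frame with an empty RoI mask")
    values = frame.values.copy()
    values[m] += record.offset_c
    return frame.with_values(values)
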