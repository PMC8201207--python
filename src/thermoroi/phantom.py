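"""Synthetic radiometric/visible capture sweeps with ground truth.

The generator emulates the study acquisition: a warm foot-like region
(around 34 C with a smooth within-region gradient) on a cool background
(around 22 C), imaged in a rotating sweep of 15 viewpoints spaced 12
degrees apart.  As the camera turns, the silhouette shrinks horizontally
with ``|cos(theta)|`` (never below roughly a tenth of the frame), a
per-angle additive drift can emulate the directional-emissivity bias, warm
interference blobs can be stamped near the borders, and i.i.d. Gaussian
pixel noise models the sensor's thermal sensitivity (default sd 0.05 C,
i.e. 50 mK).  Paired visible photographs render the silhouette skin-toned
on a procedurally textured background.

Every frame comes with exact ground truth (masks, pre-noise temperatures,
drift offsets), making each stage of the chain checkable with zero
tolerance for masks and 1e-9 C for temperatures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .io import CaptureSet, TemperatureFrame

DEFAULT_ANGLES = tuple(range(0, 180, 12))  # 15 viewpoints, 12-degree step


@dataclass(frozen=True)
class Interference:
    """A warm disk stamped into a frame (max rule: never cools a pixel)."""

    center: tuple[int, int]  # (row, col)
    radius_px: int
    temp_c: float
    at_border: bool = True


@dataclass
class PhantomSpec:
    """Parameters of a synthetic acquisition sweep.

    ``drift_profile`` maps an angle in degrees to an additive Celsius offset
    applied to silhouette pixels (callable or mapping; None means no drift).
    ``frame_jitter_sd_c`` adds one Gaussian-distributed constant per frame to
    the silhouette, emulating capture-to-capture extrema variation.
    """

    frame_shape: tuple[int, int] = (240, 320)
    foot_temp_c: float = 34.0
    foot_gradient_c: float = 1.0
    background_temp_c: float = 22.0
    room_temp_c: float = 20.0
    angles_deg: tuple[float, ...] = DEFAULT_ANGLES
    drift_profile: Callable[[float], float] | Mapping[float, float] | None = None
    interferences: tuple[Interference, ...] = ()
    noise_sd_c: float = 0.05
    frame_jitter_sd_c: float = 0.0
    seed: int = 0
    render_visible: bool = True
    visible_scale: int = 2

    def drift(self, angle_deg: float) -> float:
        if self.drift_profile is None:
            return 0.0
        if callable(self.drift_profile):
            return float(self.drift_profile(angle_deg))
        return float(self.drift_profile.get(angle_deg, 0.0))

    def validate(self) -> None:
        if self.foot_temp_c <= self.background_temp_c:
            raise ValidationError("foot must be warmer than background")
        min_area = silhouette_mask(self.frame_shape, 90.0).sum()
        for blob in self.interferences:
            area = np.pi * blob.radius_px**2
            if area >= min_area:
                raise ValidationError(
                    f"interference area {area:.0f} px not smaller than the "
                    f"smallest silhouette ({min_area} px)"
                )


def silhouette_mask(shape: tuple[int, int], angle_deg: float) -> np.ndarray:
    """Foot-like silhouette at a given viewpoint: ellipse plus toe bumps.

    The horizontal semi-axis scales with ``|cos(theta)|`` (floored at 0.35
    of its frontal value) to mimic the rotating viewpoint; the vertical
    extent is viewpoint-invariant.
    """
    h, w = shape
    rows, cols = np.mgrid[0:h, 0:w]
    cr, cc = 0.54 * h, 0.5 * w
    b = 0.32 * h
    a = 0.28 * w * max(abs(np.cos(np.radians(angle_deg))), 0.35)
    mask = ((rows - cr) / b) ** 2 + ((cols - cc) / a) ** 2 <= 1.0
    # three toe bumps along the top edge of the ellipse
    toe_r = 0.06 * h
    toe_row = cr - b
    for frac in (-0.45, 0.0, 0.45):
        mask |= (rows - toe_row) ** 2 + (cols - (cc + frac * a)) ** 2 <= toe_r**2
    return mask


def _temperature_field(spec: PhantomSpec, mask: np.ndarray) -> np.ndarray:
    """Noiseless, drift-free temperatures: background plus warm silhouette.

    The within-silhouette gradient depends on the row only, so a fixed
    reference zone sees the same gradient contribution at every viewpoint.
    """
    h, _ = spec.frame_shape
    rows = np.arange(h, dtype=float)[:, None]
    gradient = spec.foot_gradient_c * rows / max(h - 1, 1)
    values = np.full(spec.frame_shape, spec.background_temp_c, dtype=float)
    values[mask] = (spec.foot_temp_c + np.broadcast_to(gradient, spec.frame_shape))[mask]
    return values


def inject_interference(frame: TemperatureFrame, blob: Interference) -> TemperatureFrame:
    """Stamp a warm disk into a frame using the max rule."""
    h, w = frame.shape
    r0, c0 = blob.center
    if not (0 <= r0 < h and 0 <= c0 < w):
        raise ValidationError(f"interference center {blob.center} outside frame {(h, w)}")
    rows, cols = np.mgrid[0:h, 0:w]
    disk = (rows - r0) ** 2 + (cols - c0) ** 2 <= blob.radius_px**2
    values = frame.values.copy()
    values[disk] = np.maximum(values[disk], blob.temp_c)
    return frame.with_values(values)


def _interference_disk(shape: tuple[int, int], blob: Interference) -> np.ndarray:
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rows - blob.center[0]) ** 2 + (cols - blob.center[1]) ** 2 <= blob.radius_px**2


@dataclass
class PhantomTruth:
    """Exact ground truth accompanying a generated sweep."""

    roi_masks: list[np.ndarray] = field(default_factory=list)
    noiseless_frames: list[np.ndarray] = field(default_factory=list)
    undrifted_frames: list[np.ndarray] = field(default_factory=list)
    extrema_c: list[tuple[float, float]] = field(default_factory=list)
    drift_c: list[float] = field(default_factory=list)
    interference_masks: list[np.ndarray] = field(default_factory=list)


def _render_visible(spec: PhantomSpec, mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Procedural visible-light photograph: textured scene, skin-toned limb.

    Checkerboard plus smooth value noise gives the background enough
    features for external structure-from-motion tools to latch onto.
    """
    s = spec.visible_scale
    h, w = spec.frame_shape[0] * s, spec.frame_shape[1] * s
    rows, cols = np.mgrid[0:h, 0:w]
    checker = (((rows // 32) + (cols // 32)) % 2).astype(float)
    coarse = rng.uniform(0.0, 1.0, (h // 16 + 1, w // 16 + 1))
    noise = np.kron(coarse, np.ones((16, 16)))[:h, :w]
    base = 80 + 60 * checker + 40 * noise
    img = np.dstack([base, base * 0.96, base * 0.92])
    big_mask = np.kron(mask, np.ones((s, s), dtype=bool))[:h, :w]
    skin = np.array([205.0, 170.0, 150.0])
    img[big_mask] = skin + 12.0 * (noise[big_mask, None] - 0.5)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_sweep(spec: PhantomSpec) -> tuple[CaptureSet, PhantomTruth]:
    """Generate a full angular sweep with paired visible frames and truth.

    With a fixed seed the output is bit-identical across runs; the infrared
    stream does not depend on whether visible frames are rendered.
    """
    spec.validate()
    ir_seed, vis_seed = np.random.SeedSequence(spec.seed).spawn(2)
    rng = np.random.default_rng(ir_seed)
    rng_vis = np.random.default_rng(vis_seed)
    truth = PhantomTruth()
    frames: list[TemperatureFrame] = []
    visibles: list[np.ndarray] = []
    for i, angle in enumerate(spec.angles_deg):
        mask = silhouette_mask(spec.frame_shape, angle)
        undrifted = _temperature_field(spec, mask)
        jitter = rng.normal(0.0, spec.frame_jitter_sd_c) if spec.frame_jitter_sd_c > 0 else 0.0
        drift = spec.drift(angle)
        noiseless = undrifted.copy()
        noiseless[mask] += drift + jitter
        blob_mask = np.zeros(spec.frame_shape, dtype=bool)
        for blob in spec.interferences:
            disk = _interference_disk(spec.frame_shape, blob)
            noiseless[disk] = np.maximum(noiseless[disk], blob.temp_c)
            blob_mask |= disk
        values = noiseless
        if spec.noise_sd_c > 0:
            values = noiseless + rng.normal(0.0, spec.noise_sd_c, spec.frame_shape)
        frames.append(
            TemperatureFrame(
                values=values,
                frame_id=f"phantom-{i:03d}",
                angle_deg=float(angle),
                room_temp_c=spec.room_temp_c,
            )
        )
        if spec.render_visible:
            visibles.append(_render_visible(spec, mask, rng_vis))
        truth.roi_masks.append(mask)
        truth.noiseless_frames.append(noiseless)
        truth.undrifted_frames.append(undrifted)
        truth.extrema_c.append((float(noiseless[mask].min()), float(noiseless[mask].max())))
        truth.drift_c.append(drift)
        truth.interference_masks.append(blob_mask)
    return CaptureSet(frames=frames, visibles=visibles), truth


def failure_interference_temp(spec: PhantomSpec, margin_c: float = 2.5, tau: float = 0.8) -> float:
    """Blob temperature hot enough to push the silhouette below threshold.

    From the normalization algebra: the silhouette survives thresholding iff
    ``(foot_max - bg_min) >= tau * (frame_max - bg_min)``.  A blob hotter
    than ``bg_min + (foot_max - bg_min) / tau`` therefore demotes the limb
    to background, reproducing the documented failure mode.  The margin
    absorbs the within-silhouette gradient and pixel noise.
    """
    bg_min = spec.background_temp_c
    foot_max = spec.foot_temp_c + spec.foot_gradient_c
    return bg_min + (foot_max - bg_min) / tau + margin_c
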