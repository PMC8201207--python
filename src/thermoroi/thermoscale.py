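"""Temperature sidebar association.

Each frame of a sweep has its own RoI extrema, so a single color scale for
the whole set (and the 3D model textured from it) is derived by averaging
the per-frame RoI minima and maxima.  The standard deviations of those
lists measure how stable the extrema are across viewpoints; under passive
thermography in a controlled room they stay below one degree.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import EmptyRoIWarning, ValidationError
from .segmentation import SegmentationResult, colormap_lut


@dataclass(frozen=True)
class ColorbarLimits:
    """Per-frame RoI extrema and their set-level averages (degrees Celsius)."""

    per_frame_min_c: tuple[float, ...]
    per_frame_max_c: tuple[float, ...]
    avg_min_c: float
    avg_max_c: float
    sd_min_c: float
    sd_max_c: float

    def to_dict(self) -> dict:
        return {
            "per_frame_min_c": list(self.per_frame_min_c),
            "per_frame_max_c": list(self.per_frame_max_c),
            "avg_min_c": self.avg_min_c,
            "avg_max_c": self.avg_max_c,
            "sd_min_c": self.sd_min_c,
            "sd_max_c": self.sd_max_c,
        }


@dataclass(frozen=True)
class SidebarMapping:
    """Invertible linear map between [avg_min, avg_max] Celsius and a colormap.

    Temperatures outside the limits clamp to the endpoint colors: limits are
    set-level averages, so individual frames routinely exceed them slightly.
    """

    lut: np.ndarray  # 256 x 3 uint8
    tmin_c: float
    tmax_c: float
    colormap: str = "jet"

    def index_for(self, temp_c: np.ndarray | float) -> np.ndarray:
        frac = (np.asarray(temp_c, dtype=float) - self.tmin_c) / (self.tmax_c - self.tmin_c)
        return np.clip(np.rint(frac * 255), 0, 255).astype(int)

    def color_for(self, temp_c: np.ndarray | float) -> np.ndarray:
        """RGB uint8 color(s) for temperature(s), clamped to the limits."""
        return self.lut[self.index_for(temp_c)]

    def temp_for_index(self, idx: np.ndarray | int) -> np.ndarray | float:
        return self.tmin_c + np.asarray(idx) / 255.0 * (self.tmax_c - self.tmin_c)

    def temp_for_color(self, rgb, tol: int = 8):
        """Invert a color to a temperature by nearest LUT entry.

        Returns NaN when no LUT entry lies within ``tol`` per-channel
        distance: such a color is not on the recorded colormap curve and
        belongs to the visible-light scene, not to the thermal RoI.
        """
        color = np.asarray(rgb, dtype=int)
        diff = np.abs(self.lut.astype(int) - color[..., None, :])  # ... x 256 x 3
        worst = diff.max(axis=-1)
        idx = worst.argmin(axis=-1)
        temp = self.temp_for_index(idx)
        return np.where(np.min(worst, axis=-1) <= tol, temp, np.nan)

    def to_dict(self) -> dict:
        return {
            "colormap": self.colormap,
            "tmin_c": self.tmin_c,
            "tmax_c": self.tmax_c,
            "lut": self.lut.tolist(),
        }


def frame_extrema(result: SegmentationResult) -> tuple[float, float] | None:
    """RoI-only (min, max) in Celsius; None (with a warning) for an empty RoI."""
    if result.roi_temps_c.size == 0:
        warnings.warn("empty RoI: no extrema for this frame", EmptyRoIWarning)
        return None
    return float(result.roi_temps_c.min()), float(result.roi_temps_c.max())


def colorbar_limits(extrema: Sequence[tuple[float, float]]) -> ColorbarLimits:
    """Average the per-frame RoI extrema into set-level colorbar limits.

    Standard deviations use the sample (n-1) estimator; a single frame gets
    sd 0.
    """
    pairs = [e for e in extrema if e is not None]
    if not pairs:
        raise ValidationError("no frame extrema supplied")
    mins = np.array([p[0] for p in pairs], dtype=float)
    maxes = np.array([p[1] for p in pairs], dtype=float)
    sd = (lambda a: float(a.std(ddof=1)) if a.size > 1 else 0.0)
    limits = ColorbarLimits(
        per_frame_min_c=tuple(mins.tolist()),
        per_frame_max_c=tuple(maxes.tolist()),
        avg_min_c=float(mins.mean()),
        avg_max_c=float(maxes.mean()),
        sd_min_c=sd(mins),
        sd_max_c=sd(maxes),
    )
    if not limits.avg_min_c < limits.avg_max_c:
        raise ValidationError(
            f"degenerate limits: avg_min {limits.avg_min_c} >= avg_max {limits.avg_max_c}"
        )
    return limits


def sidebar_mapping(limits: ColorbarLimits, colormap: str = "jet") -> SidebarMapping:
    """Linear temperature-to-color mapping over [avg_min, avg_max]."""
    return SidebarMapping(
        lut=colormap_lut(colormap),
        tmin_c=limits.avg_min_c,
        tmax_c=limits.avg_max_c,
        colormap=colormap,
    )


def save_limits(limits: ColorbarLimits, mapping: SidebarMapping, path) -> None:
    """Serialize limits and mapping as JSON for the viewer / mesh bridge."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"limits": limits.to_dict(), "mapping": mapping.to_dict()}, fh, indent=1)


def render_sidebar(mapping: SidebarMapping, path, width_px: int = 40, height_px: int = 256,
                   n_ticks: int = 5) -> None:
    """Export the sidebar as a PNG strip with Celsius tick labels."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    strip = mapping.lut[::-1][:, None, :].repeat(width_px, axis=1)
    fig, ax = plt.subplots(figsize=(1.2, 3.2), dpi=max(100, height_px // 3))
    ax.imshow(strip, extent=(0, 1, mapping.tmin_c, mapping.tmax_c), aspect="auto")
    ax.set_xticks([])
    ax.set_yticks(np.linspace(mapping.tmin_c, mapping.tmax_c, n_ticks))
    ax.set_ylabel("Temperature (\N{DEGREE SIGN}C)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
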