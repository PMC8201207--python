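"""End-to-end processing pipeline with provenance logging.

Stage order is fixed: calibration offset, segmentation, angular-emissivity
compensation, false-color rendering and fusion, colorbar-limit association,
export.  False colors are rendered from the uncompensated segmentation (the
angular correction is a constant shift of RoI temperatures, so it changes
the temperature scale, not the color distribution inside the RoI).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .bridge import export_sequence
from .emissivity import (
    EmissivityRecord,
    ReferenceBox,
    build_error_profile,
    compensate,
    default_reference_box,
)
from .errors import ConfigurationError, ParameterError, ThermoRoiError
from .fusion import alpha_mask, background_to_black, coregister
from .io import CaptureSet, apply_calibration_offset
from .segmentation import render_false_color, roi_percentage, segment
from .thermoscale import colorbar_limits, frame_extrema, save_limits, sidebar_mapping


@dataclass
class RunConfig:
    """Complete, serializable parameter set of one pipeline run."""

    tau: float = 0.8
    colormap: str = "jet"
    scale: float = 1.25
    crop: tuple[int, int] = (400, 300)
    alpha: float = 1.0
    room_temp_c: float = 20.0
    ref_angle_deg: float = 0.0
    reference_box: tuple[int, int, int, int] | None = None
    calibration_offset_c: float = 0.0
    compensate_angles: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.tau < 1.0:
            raise ParameterError(f"tau must lie in (0, 1), got {self.tau}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ParameterError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.scale <= 0:
            raise ParameterError(f"scale must be positive, got {self.scale}")
        if self.crop[0] < 1 or self.crop[1] < 1:
            raise ParameterError(f"invalid crop {self.crop}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["version"] = __version__
        return d


@dataclass
class PipelineResult:
    """In-memory bundle of everything one run produced."""

    merged: list = field(default_factory=list)
    segmentations: list = field(default_factory=list)
    profile: list[EmissivityRecord] = field(default_factory=list)
    limits: object = None
    mapping: object = None
    log: list[dict] = field(default_factory=list)


def run_pipeline(capture_set: CaptureSet, config: RunConfig, out_dir=None) -> PipelineResult:
    """Process a capture set through the full chain.

    Parameters are validated before any work; a stage failure is re-raised
    with the stage name and frame id attached.  With ``out_dir`` set, merged
    PNGs, the error-profile CSV, the limits JSON and a JSON-lines run log
    are written; the bundle is byte-reproducible from the config alone.
    """
    config.validate()
    if not capture_set.frames:
        raise ConfigurationError("empty capture set")
    result = PipelineResult()

    def stage(name: str, frame_id: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except ThermoRoiError as exc:
            raise type(exc)(f"stage {name!r}, frame {frame_id!r}: {exc}") from exc

    frames = [
        stage("calibration", f.frame_id, apply_calibration_offset, f, config.calibration_offset_c)
        for f in capture_set.frames
    ]
    segs = [stage("segmentation", f.frame_id, segment, f, config.tau) for f in frames]
    result.segmentations = segs

    if config.reference_box is not None:
        box = ReferenceBox(config.reference_box)
    else:
        ref_i = capture_set.angles_deg.index(config.ref_angle_deg) \
            if config.ref_angle_deg in capture_set.angles_deg else 0
        ref_regions = [r for r in segs[ref_i].regions if r.label == segs[ref_i].roi_label]
        if not ref_regions:
            raise ConfigurationError("reference frame has no RoI to place the reference box")
        box = default_reference_box(ref_regions[0].bbox)

    compensated = frames
    if config.compensate_angles:
        result.profile = stage(
            "emissivity", "", build_error_profile,
            frames, box, [s.roi_mask for s in segs],
            ref_angle_deg=config.ref_angle_deg, ta_c=config.room_temp_c, tau=config.tau,
        )
        compensated = [
            stage("compensation", f.frame_id, compensate, f, rec, s.roi_mask)
            for f, rec, s in zip(frames, result.profile, segs)
        ]

    extrema = []
    for f, s in zip(compensated, segs):
        comp_seg = dataclasses.replace(s, roi_temps_c=f.values[s.roi_mask])
        extrema.append(frame_extrema(comp_seg))
    result.limits = stage("scale", "", colorbar_limits, extrema)
    result.mapping = sidebar_mapping(result.limits, config.colormap)

    for f, s, visible in zip(frames, segs, capture_set.visibles or [None] * len(frames)):
        false_color = stage("render", f.frame_id, render_false_color, s, config.colormap)
        overlay = alpha_mask(background_to_black(false_color), config.alpha)
        if visible is not None:
            merged = stage(
                "fusion", f.frame_id, coregister,
                visible, overlay, config.scale, config.crop, ("visible", f.frame_id),
            )
            result.merged.append(merged)
        result.log.append(
            {
                "frame_id": f.frame_id,
                "angle_deg": f.angle_deg,
                "roi_area_px": s.roi_area_px,
                "roi_percent": roi_percentage(s.roi_area_px, f.shape),
                "roi_min_c": float(f.values[s.roi_mask].min()) if s.roi_mask.any() else None,
                "roi_max_c": float(f.values[s.roi_mask].max()) if s.roi_mask.any() else None,
            }
        )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if result.merged:
            export_sequence(result.merged, out / "merged", angles_deg=capture_set.angles_deg)
        if result.profile:
            with open(out / "error_profile.csv", "w", encoding="utf-8") as fh:
                fh.write("angle_deg,tn_c,ttheta_c,ta_c,delta_t_percent\n")
                for r in result.profile:
                    fh.write(
                        f"{r.angle_deg},{r.tn_c},{r.ttheta_c},{r.ta_c},{r.delta_t_percent}\n"
                    )
        save_limits(result.limits, result.mapping, out / "limits.json")
        with open(out / "run_log.jsonl", "w", encoding="utf-8") as fh:
            fh.write(json.dumps({"config": config.to_dict()}, sort_keys=True) + "\n")
            for rec in result.log:
                fh.write(json.dumps(rec, sort_keys=True) + "\n")
    return result
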