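"""Measure and compensate the viewing-angle emissivity error on a sweep.

Skin emissivity drops at oblique viewing angles, so a rotating sweep reads
increasingly biased temperatures.  This script generates a phantom sweep
with a known per-angle additive drift, measures the error profile from a
reference zone with the linear directional model, and compensates each
frame back to its normal-view temperatures.
"""

import numpy as np

import thermoroi as tr

drift = lambda angle: 0.0011 * min(angle, 90.0) * 14.0  # degrees C, grows with angle
spec = tr.PhantomSpec(seed=3, noise_sd_c=0.0, drift_profile=drift, render_visible=False)
captures, truth = tr.generate_sweep(spec)

segs = [tr.segment(f) for f in captures.frames]
roi = next(r for r in segs[0].regions if r.label == segs[0].roi_label)
box = tr.default_reference_box(roi.bbox)
profile = tr.build_error_profile(captures.frames, box, [s.roi_mask for s in segs], ta_c=20.0)

print("angle  zone avg (C)  |dT| (%)")
for rec in profile:
    print(f"{rec.angle_deg:5.0f}  {rec.ttheta_c:12.2f}  {rec.delta_t_percent:8.2f}")

worst = 0.0
for frame, rec, seg, undrifted in zip(captures.frames, profile, segs, truth.undrifted_frames):
    comp = tr.compensate(frame, rec, seg.roi_mask)
    worst = max(worst, float(np.abs(comp.values[seg.roi_mask] - undrifted[seg.roi_mask]).max()))

print(
    f"\nAfter compensation the worst deviation from the normal-view\n"
    f"temperatures over all RoI pixels and angles is {worst:.2e} C: the\n"
    f"error model is a single additive constant per frame, so an exactly\n"
    f"additive drift is removed exactly."
)
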