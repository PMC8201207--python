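"""Segment a synthetic 15-view sweep and discard a border interference.

Builds a phantom acquisition (warm foot-like region on a cool background,
camera rotating in 12-degree steps) with a warm blob stamped near one
corner, runs the radiometric segmentation chain on every frame, and prints
the recovered RoI size per view.  The blob survives thresholding but is
smaller than the limb, so the largest-central-region rule removes it in
every frame.
"""

import numpy as np

import thermoroi as tr

spec = tr.PhantomSpec(seed=7, interferences=(tr.Interference((10, 12), 10, 34.1),),
                      render_visible=False)
captures, truth = tr.generate_sweep(spec)

print("angle  RoI px   RoI %   matches truth")
for frame, mask in zip(captures.frames, truth.roi_masks):
    seg = tr.segment(frame)  # tau = 0.8
    pct = tr.roi_percentage(seg.roi_area_px, frame.shape)
    exact = np.array_equal(seg.roi_mask, mask)
    print(f"{frame.angle_deg:5.0f}  {seg.roi_area_px:6d}  {pct:6.2f}   {exact}")

print(
    "\nEach row is one viewpoint: the RoI shrinks as the camera turns away\n"
    "from the frontal view, and 'True' means the recovered mask equals the\n"
    "generator's ground truth pixel-for-pixel (interference removed)."
)
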