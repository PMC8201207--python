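"""Fuse a false-color RoI overlay into its paired visible-light photograph.

Segments one phantom capture, renders the RoI in the jet colormap with the
background reserved at the lowest entry, keys the background to black, makes
it transparent, and composites the overlay center-aligned onto the visible
frame rescaled by the fixed inter-sensor factor (1.25), cropped to the
shared 400 x 300 field of view.  The merged PNG lands in scratch/.
"""

from pathlib import Path

import numpy as np
from PIL import Image

import thermoroi as tr

captures, truth = tr.generate_sweep(tr.PhantomSpec(seed=5, angles_deg=(0.0,)))
frame, visible = captures.frames[0], captures.visibles[0]

seg = tr.segment(frame)
false_color = tr.render_false_color(seg)
overlay = tr.alpha_mask(tr.background_to_black(false_color), a=1.0)
merged = tr.coregister(visible, overlay)

out = Path("scratch")
out.mkdir(exist_ok=True)
Image.fromarray(merged.pixels).save(out / "merged.png")

h, w = merged.pixels.shape[:2]
inside = int(seg.roi_mask.sum())
print(f"merged image: {w} x {h} px, IR RoI covers {inside} px "
      f"({tr.roi_percentage(seg.roi_area_px, frame.shape):.2f}% of the sensor grid)")
print(f"RoI temperatures span [{seg.roi_temps_c.min():.2f}, {seg.roi_temps_c.max():.2f}] C,")
print(f"rendered over colormap entries 1..255 (entry 0 reserved for background).")
print(f"wrote {out / 'merged.png'}: visible scene everywhere except the false-color RoI.")
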