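"""Attach a temperature scale to a textured mesh.

External photogrammetry tools reconstruct a textured 3D surface from the
merged image sequence; this package then inverts the recorded colormap at
each vertex's texture sample to recover a temperature, leaving visible-light
(background) vertices without one.  Here a flat two-triangle mesh stands in
for the reconstructed surface: half its texture is painted with exact
colormap colors, half with a gray scene color.
"""

import numpy as np

import thermoroi as tr

limits = tr.colorbar_limits([(29.9, 36.5), (30.1, 36.6), (29.7, 36.5)])
mapping = tr.sidebar_mapping(limits)
print(f"colorbar limits: [{limits.avg_min_c:.2f}, {limits.avg_max_c:.2f}] C "
      f"(sd of per-frame minima {limits.sd_min_c:.2f} C, maxima {limits.sd_max_c:.2f} C)")

# texture: left half sweeps the colormap from avg_min to avg_max, right half is scene gray
temps = np.linspace(limits.avg_min_c, limits.avg_max_c, 32)
texture = np.full((32, 64, 3), 120, dtype=np.uint8)
texture[:, :32] = mapping.color_for(temps)[:, None, :]

uv = np.array([[0.1, 0.2], [0.25, 0.8], [0.4, 0.5], [0.9, 0.5]])  # last vertex on gray half
mesh = tr.Mesh(
    vertices=np.column_stack([uv, np.zeros(4)]),
    faces=np.array([[0, 1, 2], [1, 2, 3]]),
    uv=uv,
    texture=texture,
)
model = tr.attach_temperature(mesh, limits, mapping)

for i, t in enumerate(model.per_vertex_temp_c):
    state = "non-thermal (scene)" if np.isnan(t) else f"{t:.2f} C"
    print(f"vertex {i}: {state}")
print("\nVertices sampling colormap colors receive temperatures on the sidebar\n"
      "scale; the gray scene vertex is never assigned one.")
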