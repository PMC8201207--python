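"""Bridge to external photogrammetry tools.

Structure-from-motion and multi-view-stereo reconstruction (e.g. COLMAP and
Open-MVS) are third-party programs invoked by the user; this module only
speaks their file-level interfaces: it stages the merged image sequence
they consume, loads the textured mesh they produce (OBJ or ASCII PLY with a
PNG texture), and re-attaches temperatures to the mesh by inverting the
recorded colormap at each vertex's texture sample.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh
from PIL import Image

from .errors import EmptyRoIWarning, FormatError, ValidationError
from .fusion import MergedImage
from .thermoscale import ColorbarLimits, SidebarMapping


@dataclass
class Mesh:
    """Triangulated surface with per-vertex texture coordinates."""

    vertices: np.ndarray  # (n, 3) float
    faces: np.ndarray  # (m, 3) int
    uv: np.ndarray  # (n, 2) float in [0, 1]^2
    texture: np.ndarray  # H x W x 3 uint8

    def __post_init__(self) -> None:
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise FormatError(
                f"face index out of range: max {self.faces.max()} for {len(self.vertices)} vertices"
            )
        if self.uv is None or len(self.uv) != len(self.vertices):
            raise FormatError("mesh is missing per-vertex texture coordinates")


@dataclass
class ThermalModel:
    """Mesh plus per-vertex temperature estimates (NaN = non-thermal vertex)."""

    mesh: Mesh
    limits: ColorbarLimits
    per_vertex_temp_c: np.ndarray  # (n,) float, NaN where not on the colormap

    @property
    def thermal_vertices(self) -> np.ndarray:
        return np.flatnonzero(~np.isnan(self.per_vertex_temp_c))


def export_sequence(merged: list[MergedImage], out_dir, angles_deg=None) -> dict:
    """Write numbered PNGs plus a JSON manifest preserving the sweep order."""
    if not merged:
        raise ValidationError("cannot export an empty image sequence")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, img in enumerate(merged, start=1):
        name = f"{i:03d}.png"
        Image.fromarray(img.pixels).save(out / name)
        entries.append(
            {
                "file": name,
                "index": i,
                "angle_deg": None if angles_deg is None else float(angles_deg[i - 1]),
                "provenance": {k: v for k, v in img.provenance.items()},
            }
        )
    manifest = {"count": len(entries), "images": entries}
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def load_mesh(model_path, texture_path) -> Mesh:
    """Load an OBJ or ASCII PLY mesh with per-vertex uv and a PNG texture."""
    try:
        loaded = trimesh.load(os.fspath(model_path), process=False, force="mesh")
    except Exception as exc:  # trimesh raises various types on malformed input
        raise FormatError(f"cannot parse mesh {model_path}: {exc}") from exc
    uv = getattr(loaded.visual, "uv", None)
    if uv is None or len(uv) != len(loaded.vertices):
        raise FormatError(f"{model_path}: no per-vertex texture coordinates")
    texture = np.asarray(Image.open(texture_path).convert("RGB"))
    return Mesh(
        vertices=np.asarray(loaded.vertices, dtype=float),
        faces=np.asarray(loaded.faces, dtype=int),
        uv=np.asarray(uv, dtype=float),
        texture=texture,
    )


def save_mesh_obj(mesh: Mesh, model_path, texture_path=None) -> None:
    """Write the mesh as OBJ (v/vt/f with matching indices)."""
    lines = []
    for v in mesh.vertices:
        lines.append(f"v {float(v[0])!r} {float(v[1])!r} {float(v[2])!r}")
    for t in mesh.uv:
        lines.append(f"vt {float(t[0])!r} {float(t[1])!r}")
    for f in mesh.faces:
        lines.append("f " + " ".join(f"{i + 1}/{i + 1}" for i in f))
    Path(model_path).write_text("\n".join(lines) + "\n", encoding="utf-8")
    if texture_path is not None:
        Image.fromarray(mesh.texture).save(texture_path)


def sample_texture(mesh: Mesh) -> np.ndarray:
    """Nearest-texel color at each vertex's uv coordinate.

    Nearest sampling (no bilinear blend) avoids mixing RoI and background
    colors at the silhouette edge, which would fabricate temperatures.
    """
    h, w = mesh.texture.shape[:2]
    u = np.clip(mesh.uv[:, 0], 0.0, 1.0)
    v = np.clip(mesh.uv[:, 1], 0.0, 1.0)
    cols = np.rint(u * (w - 1)).astype(int)
    rows = np.rint((1.0 - v) * (h - 1)).astype(int)
    return mesh.texture[rows, cols]


def attach_temperature(
    mesh: Mesh, limits: ColorbarLimits, mapping: SidebarMapping, tol: int = 8
) -> ThermalModel:
    """Estimate per-vertex temperatures by inverting the recorded colormap.

    A vertex whose texture color is within ``tol`` per-channel units of the
    colormap curve gets the temperature of the nearest lookup-table entry;
    any other vertex (visible-light scene) is marked non-thermal (NaN), so
    the background never acquires a temperature.
    """
    colors = sample_texture(mesh)
    temps = mapping.temp_for_color(colors, tol=tol)
    temps = np.asarray(temps, dtype=float)
    if np.all(np.isnan(temps)):
        warnings.warn("no vertex color lies on the recorded colormap", EmptyRoIWarning)
    return ThermalModel(mesh=mesh, limits=limits, per_vertex_temp_c=temps)


def export_vertex_temperatures(model: ThermalModel, path) -> None:
    """Write per-vertex temperature estimates as CSV (index, x, y, z, temp_c)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("vertex,x,y,z,temp_c\n")
        for i, (v, t) in enumerate(zip(model.mesh.vertices, model.per_vertex_temp_c)):
            tval = "" if np.isnan(t) else f"{t:.4f}"
            fh.write(f"{i},{v[0]!r},{v[1]!r},{v[2]!r},{tval}\n")
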