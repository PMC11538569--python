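"""Export of a quantized height map as a 3D-printable STL solid.

The part is meshed as a tiling of closed rectangular columns, one per lens
pixel, each running from the build plate (z = 0) through the base slab to
z = base_thickness + h(x, y).  Coincident internal walls between columns are
retained (every column is an individually closed body, the standard
representation stereolithography slicers consume), so the triangle count is
a fixed function of the pixel count: 12 per column.  Units are millimeters.
"""

from __future__ import annotations

import numpy as np
import trimesh

from .errors import InvalidStateError
from .lens import HeightMap

__all__ = ["height_map_mesh", "write_stl"]


def height_map_mesh(height_map: HeightMap) -> trimesh.Trimesh:
    """Build the millimeter-unit column mesh for a quantized height map."""
    if not height_map.quantized:
        raise InvalidStateError(
            "height map must be quantized to the print resolution before "
            "meshing; call quantize_heights() first"
        )
    spec = height_map.lens
    nx, ny = spec.n_pixels
    w = spec.pixel_width * 1e3  # mm
    base = spec.base_thickness * 1e3
    tops = base + height_map.heights * 1e3  # (nx, ny) column heights, mm

    template = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    tv = np.asarray(template.vertices)  # 8 verts at +-0.5
    tf = np.asarray(template.faces)  # 12 outward-wound triangles

    x0 = -nx * w / 2.0
    y0 = -ny * w / 2.0
    vertices = np.empty((nx * ny * 8, 3))
    faces = np.empty((nx * ny * 12, 3), dtype=np.int64)
    col = 0
    for i in range(nx):
        for j in range(ny):
            h = tops[i, j]
            scale = np.array([w, w, h])
            center = np.array([x0 + (i + 0.5) * w, y0 + (j + 0.5) * w, h / 2.0])
            vertices[col * 8 : col * 8 + 8] = tv * scale + center
            faces[col * 12 : col * 12 + 12] = tf + col * 8
            col += 1
    return trimesh.Trimesh(vertices=vertices, faces=faces, process=False)


def write_stl(height_map: HeightMap, path) -> trimesh.Trimesh:
    """Write the binary STL for a quantized height map; returns the mesh."""
    mesh = height_map_mesh(height_map)
    mesh.export(path, file_type="stl")
    return mesh
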