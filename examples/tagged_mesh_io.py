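"""Round-trip a tagged mesh through the tagged-PLY dialect.

Generates the rounded cuboid used in the shape-effect experiments, writes
it with its cell-face tags and cell-edge records, reads it back and prints
the tag inventory.
"""

import tempfile
from pathlib import Path

from mtcortex import load_tagged_mesh, make_rounded_cuboid, write_tagged_ply

surf = make_rounded_cuboid(13.0, 7.5, 5.0, rounding=1.0, n_triangles=1280)
path = Path(tempfile.mkdtemp()) / "cuboid.ply"
write_tagged_ply(surf, path)
back = load_tagged_mesh(path)

print(f"wrote and re-read {path.name}: {back.n_faces} triangles, "
      f"area {back.total_area:.1f} um^2")
for tag in sorted(set(back.face_tags.tolist())):
    n = int((back.face_tags == tag).sum())
    kind = "rounded strip" if tag == 0 else "flat face"
    print(f"  face_tag {tag}: {n:4d} triangles ({kind})")
print(f"  cell edges carrying dihedral angles: {len(back.cell_edges())}")
print("axes metadata:", surf.metadata["axes"])
print("-> face tags drive face-specific stability; tagged edges drive "
      "edge-catastrophes in the bending-angle model.")
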