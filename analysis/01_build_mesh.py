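#!/usr/bin/env python
"""Build the parametric ovine disc mesh and record its geometric audit.

Generates the default model (30 x 22 mm cross-section, annulus 4.5 mm
anterior / 2.5 mm posterior, 0.1 mm cartilaginous and 0.5 mm bony
endplates), verifies the gross dimensions and element quality, and exports
the mesh with region labels, fiber directions and local frames for visual
inspection.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from discfem import geometry as geo
from discfem import hexelem
from discfem.vtkio import write_vtu

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"
SCRATCH.mkdir(exist_ok=True)

cfg = geo.DiscGeometryConfig()
mesh = geo.build_disc_mesh(cfg)

vols = mesh.volumes()
rows = []
for label in sorted(set(mesh.region)):
    idx = mesh.region_elements(label)
    rows.append({"region": label, "elements": len(idx),
                 "volume_mm3": vols[idx].sum()})
stats = pd.DataFrame(rows)
stats.to_csv(OUT / "mesh_regions.csv", index=False)

width = mesh.nodes[:, 0].max() - mesh.nodes[:, 0].min()
depth = mesh.nodes[:, 1].max() - mesh.nodes[:, 1].min()
msj = hexelem.min_scaled_jacobian(mesh.nodes, mesh.hexes)
summary = pd.DataFrame([{
    "elements": mesh.n_elements, "nodes": mesh.n_nodes,
    "width_mm": width, "depth_mm": depth,
    "min_scaled_jacobian": msj, "total_volume_mm3": vols.sum(),
}])
summary.to_csv(OUT / "mesh_summary.csv", index=False)
write_vtu(SCRATCH / "disc_mesh.vtu", mesh)

print(f"Disc mesh: {mesh.n_elements} hexahedra, {mesh.n_nodes} nodes")
print(f"  width x depth = {width:.2f} x {depth:.2f} mm "
      f"(configured {cfg.width} x {cfg.depth})")
print(f"  min scaled Jacobian {msj:.3f}; total volume {vols.sum():.0f} mm^3")
print(stats.to_string(index=False))
print(f"Wrote {SCRATCH / 'disc_mesh.vtu'} for inspection.")
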