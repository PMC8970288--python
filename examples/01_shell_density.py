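"""Shell density basics on a single spherical cell.

Builds a radius-5 um spherical cell body with 10 varicosities placed inside
its ±1 um perisomatic shell, then measures signed distances, the shell
volume and the resulting density.
"""

import numpy as np

from varishell import ShellConfig, compute_densities, shell_volume, signed_distance
from varishell.synthetic import make_sphere_fixture

scene = make_sphere_fixture(radius=5.0, n_spots_in_shell=10, seed=1)
cell = scene.cells[0]
cfg = ShellConfig(half_width=1.0, voxel_pitch=0.25)

center = scene.bbox.mean(axis=0)
print(f"signed distance at the cell centre : {signed_distance(cell, center):+.2f} um")
print(f"signed distance 2 um above surface : {signed_distance(cell, center + [0, 0, 7]):+.2f} um")

v = shell_volume(cell, cfg)
closed_form = 4 * np.pi / 3 * (6.0**3 - 4.0**3)
print(f"voxelized shell volume             : {v:.1f} um^3 (closed form {closed_form:.1f})")

[rec] = [r for r in compute_densities(scene, cfg=cfg) if r.marker == "TH"]
print(f"TH varicosities in shell           : {rec.count}")
print(f"shell density                      : {rec.density:.2f} per 1,000 um^3")
print()
print("The density is the count of varicosities within 1 um of the cell surface")
print("(inside or outside) divided by the volume of that shell — a size-free")
print("measure of how densely axon terminals appose this cell body.")
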