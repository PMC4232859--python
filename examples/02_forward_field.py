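"""The spherical-conductor forward model.

Evaluates the closed-form magnetic field of a current dipole in a spherical
volume conductor over a helmet-shaped sensor array, and demonstrates the
model's two defining properties: tangential dipoles produce a dipolar field
pattern, and radial dipoles are magnetically silent.
"""

import numpy as np

from samface.containers import GridSpec
from samface.forward import HeadModel, forward_matrix, leadfield_grid
from samface.simulate import helmet_sensors

sensors = helmet_sensors(120, radius=0.12)
head = HeadModel(centres=np.zeros(3), radius=0.09)

pos = np.array([0.035, -0.050, -0.025])  # an inferior occipito-temporal site
radial = pos / np.linalg.norm(pos)
tangential = np.cross(radial, [0.0, 0.0, 1.0])
tangential /= np.linalg.norm(tangential)

for name, moment in (("tangential", tangential), ("radial", radial)):
    field = forward_matrix(pos, 20e-9 * moment, sensors, head)[:, 0]
    print(f"{name:10s} dipole, 20 nA·m : "
          f"max |B| = {np.abs(field).max():.3e} T, RMS = {np.sqrt((field**2).mean()):.3e} T")

# a leadfield grid carries, per voxel, the two tangential field patterns
grid = GridSpec.sphere(radius=0.075, spacing=0.01)
lf = leadfield_grid(grid, sensors, head)
print(f"leadfield grid: {lf.valid.sum()} valid voxels at 10 mm spacing")
print(f"per-voxel leadfield shape: {lf.lf.shape[1:]}  (channels x tangential basis)")
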