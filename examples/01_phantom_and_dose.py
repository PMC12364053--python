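"""Build a synthetic head-and-neck phantom and its dose-influence matrix.

Generates the default 64x64 single-slice anatomy (3 disjoint CTVs + 12
OARs), simulates tumor progression (+2 mm) and regression (-3 mm), and
computes the sparse pencil-beam dose-influence matrix D that maps beamlet
intensities to voxel doses.
"""

import replanrl as rl

geom = rl.generate_phantom(rl.PhantomConfig.default(), seed=7)
print(f"grid {geom.grid_shape}, spacing {geom.spacing} mm, "
      f"voxel volume {geom.voxel_volume} cc")
for name in geom.ctv_names:
    print(f"  {name}: {geom.masks[name].sum():4d} voxels, "
          f"prescription {geom.prescriptions[name]} GyRBE")
print(f"  OARs: {len(geom.oar_names)} structures "
      f"({sum(geom.masks[n].sum() for n in geom.oar_names)} voxels)")

progression = rl.augment_anatomy(geom, "progression")  # CTVs dilated 2 mm
regression = rl.augment_anatomy(geom, "regression")    # CTVs eroded 3 mm
for label, g in [("progression", progression), ("regression", regression)]:
    delta = {n: int(g.masks[n].sum()) - int(geom.masks[n].sum())
             for n in geom.ctv_names}
    print(f"{label}: CTV voxel change {delta}")

dinf = rl.compute_dose_influence(geom, rl.BeamConfig())
print(f"dose-influence matrix: {dinf.matrix.shape[0]} voxels x "
      f"{dinf.n_beamlets} beamlets, {dinf.matrix.nnz} nonzeros")
# Each column is one beamlet's dose pattern: Bragg peak at the target,
# lateral Gaussian falloff; the CTV voxel-count changes above are what an
# agent must re-plan around.
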