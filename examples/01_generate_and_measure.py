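"""Generate a synthetic notched hemp-like fiber and measure it back.

Builds the FXU4-like bundle (9% porosity, shape factor 3.23, U-notch) at
desk scale, then runs the segmentation/morphometrics chain and prints the
recovered descriptors next to the generating values.
"""

import fibrekin as fk

spec, notch = fk.scaled_preset("FXU4", diameter_voxels=48, length_diameters=1.0)
print(f"generating: d={spec.diameter} um, shape factor {spec.shape_factor}, "
      f"porosity {spec.lumen_area_fraction:.0%}, voxel {spec.voxel_size:.2f} um")

volume = fk.generate_fiber(spec, seed=7)
print(f"volume {volume.shape} = {volume.physical_volume():.3g} um^3")
notched = fk.carve_notch(volume, notch)
print(f"notch: {notch.type.value}, w={notch.w} um, h={notch.h} um, "
      f"opening angle {notch.theta:.1f} deg, removed "
      f"{int(volume.solid_mask().sum() - notched.solid_mask().sum())} voxels")

# morphometrics on the un-notched fiber
seg = fk.segment(volume, threshold=127)
lumen = fk.extract_lumen(seg)
poro = fk.porosity(seg, lumen)
desc = fk.fiber_descriptors(seg)
stats = fk.slice_ellipse_stats(lumen, seg.voxel_size, seg=seg)

print(f"measured porosity      {poro:.3f}   (requested {spec.lumen_area_fraction})")
print(f"measured shape factor  {desc.shape_factor:.2f}    (requested {spec.shape_factor})")
print(f"equivalent diameter    {desc.equivalent_diameter:.1f} um (requested {spec.diameter})")
print(f"lumen ellipse aspect   mean {stats.mean_aspect:.2f} / median {stats.median_aspect:.2f}")
print(f"lumen area             mean {stats.mean_area:.1f} um^2 / median {stats.median_area:.1f} um^2")
# The mean/median pairs quantify how elongated and how variable the
# tubular cavity is; porosity is internal air over (internal air + solid).
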