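"""Segment one field and measure every myotube.

Simulates a single vehicle field in memory, runs marker/nuclear
segmentation with the default parameters (per-field Otsu threshold,
200 µm² myotube gate, 40 µm² nucleus gate), assigns nuclei to myotubes by
centroid containment, and prints the per-object morphometry table.
"""

import numpy as np

from myoscreen import PlateSpec, analyze_field, condition_preset
from myoscreen.morphometry import myotubes_to_frame
from myoscreen.synthetic import simulate_field

preset = condition_preset("vehicle")
spec = PlateSpec(
    wells=[("A01", preset)], field_shape=(512, 512), pixel_size=1.0,
    rng_seed=23,
)
rng = np.random.default_rng(23)
field, truth = simulate_field(preset, spec, rng)

myotubes, cells = analyze_field(field)
table = myotubes_to_frame(myotubes)

print(f"field A01 site 1: {len(myotubes)} myotubes, {len(cells)} nuclei "
      f"({sum(c.assigned_object is not None for c in cells)} inside myotubes)")
print("\nper-myotube measurements (µm, µm², raw intensity units):")
print(table[["object_id", "length", "breadth", "area", "perimeter",
             "integrated_intensity", "nuclei_count", "border"]].round(1))
# length/breadth are max/min Feret (caliper) diameters; area is pixel count
# × pixel_size²; integrated intensity sums the raw marker signal over the
# region — the per-myotube marker-abundance readout.
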