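"""Simulate one synthetic brain DECT acquisition and inspect it.

Builds a 64x64 phantom slice (CSF / white / gray matter, optional hemorrhage,
smooth iodine enhancement), renders the ground-truth non-contrast image and
the low/high-energy pair under the 80/150Sn physics preset, and prints
per-tissue mean HU values.
"""

import numpy as np

import deepvnc as dv
from deepvnc.phantom import CSF, GRAY, HEMORRHAGE, WHITE

scene = dv.make_scene(64, 64, seed=1)
tnc = dv.render_tnc(scene, noise_sigma=2.0, seed=2)
pair = dv.simulate_dect(scene, dv.physics_preset("80/150Sn"), seed=3)

print(f"brain mask covers {scene.mask.pixels.mean():.0%} of the slice")
print(f"peak iodine enhancement: {25.0 * scene.iodine_map.max():.1f} HU at high energy")
print(f"{'tissue':<12}{'TNC':>8}{'low kVp':>10}{'high kVp':>10}")
for name, cls in [("CSF", CSF), ("white", WHITE), ("gray", GRAY), ("hemorrhage", HEMORRHAGE)]:
    sel = scene.labels == cls
    if sel.any():
        print(f"{name:<12}{tnc.pixels[sel].mean():>8.1f}"
              f"{pair.low.pixels[sel].mean():>10.1f}{pair.high.pixels[sel].mean():>10.1f}")

# Mean TNC values sit near the configured class means (CSF 8, white 25,
# gray 38, hemorrhage 65 HU); the low-energy channel reads higher wherever
# iodine is present because iodine enhances 2.12x more at low energy.
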