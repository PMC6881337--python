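"""Three-material decomposition: remove iodine from a dual-energy pair.

Decomposes a simulated contrast-enhanced pair into a virtual non-contrast
(S-VNC stand-in) image and an iodine image, and demonstrates the key physics
property: the VNC output is invariant to iodine enhancement.
"""

import numpy as np

import deepvnc as dv

physics = dv.physics_preset("80/150Sn")
scene = dv.make_scene(64, 64, seed=5)
pair = dv.simulate_dect(scene, physics, seed=6)

vnc, iodine = dv.decompose(pair, physics.basis)
tnc = dv.render_tnc(scene, noise_sigma=0.0, seed=0)
mask = scene.mask

enhanced_px = scene.iodine_map > 0.05
print(f"masked RMSE(S-VNC, TNC): {dv.masked_rmse(vnc, tnc, mask):.2f} HU")
print(f"mean recovered iodine in enhancing tissue: {iodine.pixels[enhanced_px].mean():.1f} HU "
      f"(simulated {25.0 * scene.iodine_map[enhanced_px].mean():.1f} HU)")

# iodine invariance: enhance the pair further and decompose again
enhanced = dv.enhance_with_iodine(pair, np.full(pair.shape, 2.0), physics.basis, gain=25.0)
vnc2, _ = dv.decompose(enhanced, physics.basis)
print(f"max |VNC change| after +50 HU iodine: {np.abs(vnc2.pixels - vnc.pixels).max():.2e} HU")

# The S-VNC error against TNC comes from acquisition noise amplified by the
# decomposition and from the small spectral tilt of each tissue class. The
# recovered iodine slightly exceeds the simulated amount for the same reason:
# any deviation from the two-base-material mixture is attributed to the third
# material, so tissue tilt leaks into the iodine image. The iodine-invariance
# residual is at floating-point level because the iodine direction spans the
# null space of the VNC projection.
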