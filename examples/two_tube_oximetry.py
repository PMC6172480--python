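"""Recover blood oxygen saturation from a simulated two-tube phantom.

Builds the bench-validation scene — two 1.5 mm tubes of flowing blood at
20 mm depth in a tank whose bulk optics match the average breast, left tube
fully oxygenated, right tube at 50% — then runs the full dual-wavelength
chain (757/1064 nm simulation, conditioning, back-projection, depth
normalization, spectral unmixing) and prints the recovered ROI oximetry.
Overlay PNGs and HDF5 intermediates are written to ./example_output.
"""

from oabreast import RunConfig, make_two_tube_phantom, run_pipeline

phantom = make_two_tube_phantom(
    depth_mm=20.0, diameter_mm=1.5, so2_left=1.00, so2_right=0.50,
    hematocrit=0.27, medium="aqueous",
)
manifest = run_pipeline(RunConfig(scene=phantom, out_dir="example_output", seed=0))

for s in manifest["roi_stats"]:
    print(
        f"tube at x = {s['center_mm'][0]:+5.1f} mm: true sO2 "
        f"{s['true_so2_percent']:5.1f}%  recovered {s['mean_so2_percent']:5.1f}%  "
        f"display color: {s['color_class']}"
    )
print(
    "\nRecovered values within a few percentage points of truth mean the "
    "chain's two wavelength channels stay spectrally consistent end to end; "
    "green marks normally oxygenated blood (>90%), red marks hypoxia (<85%)."
)
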