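# oabreast

Simulation and image-formation chain for dual-wavelength optoacoustic (OA)
plus ultrasound breast imaging: digital phantoms of blood-filled tubes and
tumor-like lesions, an ultrawide-band forward acoustic model for a 128-element
hand-held linear array, signal conditioning (Wiener deconvolution, band-pass,
angular-sensitivity compensation), 2D filtered back-projection, and conversion
of co-registered 757/1064 nm image pairs into depth-normalized functional maps
of total hemoglobin [tHb] and blood oxygen saturation [sO2], rendered as RGBA
overlays on a grayscale anatomical background.

It is written for people studying quantitative oximetry in hand-held
optoacoustic tomography: how accurately a limited-view, band-limited,
dual-laser system can recover the oxygenation of embedded blood targets, and
which parts of the processing chain that accuracy depends on.

## The model

Absorption of a short laser pulse creates an initial pressure

```
p0(r) = Γ μa(r) F(r),        F(z) = exp(−μeff z),   μeff = √(3 μa(μa+μs'))
```

with Γ the (constant) Grüneisen efficiency and F a 1D planar fluence model of
the breast bulk (μa = 0.039 / 0.122 cm⁻¹ and μs' = 9.0 / 4.0 cm⁻¹ at
757 / 1064 nm; roughly a threefold fluence loss per centimeter). Each source
voxel radiates the 3D free-space retarded potential; every array element
integrates it over its face, convolves with the laser-pulse profile and the
zero-phase electro-acoustic impulse response (−6 dB band 0.1–12 MHz), suffers
frequency-dependent acoustic attenuation `u(z) = u0·10^(−0.32 f^1.5 z / 20)`,
and adds white noise at the 1.3 Pa noise-equivalent pressure.

Images form by weighted filtered back-projection of the data function

```
p0(r) ∝ Σ_elements [ p(t) − t ∂p/∂t ]_{t=|r_T−r|/c} · dΩ/Ω0
```

whose derivative term acts as a ramp filter and balances spherical spreading,
so brightness is comparable across the field of view. Functional maps come
from depth-normalizing the per-wavelength brightness envelopes and inverting
the exact 2×2 oxy/deoxy extinction system pixelwise:

```
[tHb] = Hb + HbO2,     [sO2] = HbO2 / (Hb + HbO2)
```

with sO2 displayed through the clinical palette: red below 85%, transparent
in [85, 90]%, green above 90% (magenta/cyan at the hypoxic/arterial extremes),
and [tHb] in yellow above a display percentile.

## Worked example

`python examples/two_tube_oximetry.py` simulates the bench-validation scene —
two 1.5 mm tubes of flowing blood at 20 mm depth, left fully oxygenated,
right at 50% — and runs the full chain:

```
tube at x =  -6.0 mm: true sO2 100.0%  recovered  96.3%  display color: green
tube at x =  +6.0 mm: true sO2  50.0%  recovered  48.6%  display color: red
```

Both tubes recover within a few percentage points of truth and land in the
correct display class. `examples/depth_series.py` shows the recovery is
stable from 13 to 32 mm depth, `examples/sphere_oracle.py` checks the forward
model against the closed-form sphere N-wave (0.66% RMS), and
`examples/palette_demo.py` walks the display palette. A thin CLI mirrors the
stages (`oabreast phantom / simulate / filter / reconstruct / map / render /
run / fixtures`).

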