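# Methods

This note documents the physical models, parameter choices and numerical
decisions behind `oabreast`, and what its synthetic experiments do and do
not demonstrate about real imaging.

## Scene model

A phantom is a 2D imaging-plane scene (lateral × depth, probe face at
z = 0), default 38 × 38 mm at 0.15 mm spacing — the clinical display extent,
with spacing well below the system's axial resolution so discretization does
not dominate point-spread measurements. Inclusions are blood-filled tubes
seen in cross-section, spheres, or elliptical lesions; blood absorption is
`μa = ln10 · C_Hb · thb · (sO2·εHbO2 + (1−sO2)·εHb)` with C_Hb = 2.3 mM for
whole blood and the relative hemoglobin scale thb = 1 at hematocrit 41%.
The bundled extinction table is an approximate compilation of standard NIR
hemoglobin spectra; all oximetry in the package is self-consistent (the
generator and the unmixer share the table), so its absolute accuracy does
not affect recovery results. The Grüneisen parameter defaults to 1.0 in
relative units; the thermodynamic prefactor β c²/Cp is folded into it.

Background bulk optics are the average breast values (μa 0.039/0.122 cm⁻¹,
μs' 9.0/4.0 cm⁻¹ at 757/1064 nm — midpoints of the reported scattering
ranges). Tissue backgrounds additionally carry a seeded multiplicative μa
texture (σ = 0.2, 0.3 mm correlation) representing sub-resolution structural
heterogeneity; the same spatial field scales both wavelengths, as physical
microstructure does. Bench-phantom scenes (PVCP, milky water) use σ = 0.02:
those media are nearly homogeneous. Tube scenes default to a 12 mm
separation, symmetric about the array center.

## Forward model

Fluence is 1D planar: `F(z) = exp(−μeff z)` from diffusion theory on the
bulk optics (≈3× loss per cm averaged over the two lines). Initial pressure
is `p0 = Γ μa F`. Pressures are reported in pascals via a calibration of
4 kPa per unit of μa[cm⁻¹]·F, i.e. the skin-safe incident fluence of
20 mJ/cm² with Γ = 0.2 — this sets the signal scale against the 1.3 Pa
noise-equivalent pressure.

Acoustic propagation superposes the 3D free-space retarded potential of
every source voxel. In-plane objects (background, tubes, ellipses) are
treated as thin-slice sources — the same heuristic by which the 3D
back-projection formula is applied to 2D imaging, justified by the
elevation-focusing acoustic lens; spheres are voxelized as true 3D balls
(with anti-aliased surface coverage) so the simulator can be validated
against the closed-form N-wave. Numerically, each voxel is a short vertical
segment whose `∫ dR/√(R²−s²)` shell integral is accumulated per time bin in
closed form; the exact time derivative, a compensation of the bin-integration
box kernel (half-sample phase and sinc rolloff), the rectangular laser-pulse
smoothing (50 ns at 757 nm, 15 ns at 1064 nm) and the zero-phase EIR are
applied in the frequency domain with zero padding so acausal filter tails
cannot wrap into late samples. Element directivity arises physically from
5-point quadrature across the 0.25 mm element face, plus a soft-baffle
reception obliquity (cos θ) — without the baffle factor, near-grazing arcs
from shallow sources haze the deep image in a way real probes do not show.
Frequency-dependent attenuation (0.32 dB cm⁻¹ MHz⁻¹·⁵, amplitude-dB
convention, calibrated so 10 MHz loses ≈3× per cm) is applied per
propagation path at a 2 MHz reference frequency; full dispersion modeling
would dominate runtime and cancels anyway in the dual-wavelength ratio.
The sphere-oracle agreement is 0.6% RMS at 80 MHz sampling and 12.5 µm
voxels against a supersampled anti-aliased reference.

Probe geometry: 128 elements, 0.3125 mm pitch (40 mm aperture, matching the
two 40 × 6 mm illumination windows), EIR −6 dB edges at 0.1 and 12 MHz with
second-order Butterworth-type skirts, 40 MHz default sampling, 1.54 mm/µs
sound speed. Pitch, sampling rate and sound speed are standard values; none
is printed in the source system's description.

The skin-borne beam-edge artifact is modeled as a derivative-of-Gaussian
pulse launched at the two illumination-window edges and swept laterally
across the array (latest arrival at the center elements — the "V"). Its
width grows, and its amplitude and energy fall monotonically, as the beam
edge is softened; it is low-frequency, so the 67–100 kHz high-pass removes
most of its energy.

## Signal conditioning

The chain is: early-time dead-zone gate (1 µs cosine taper — the probe-face
arrival otherwise rings through the zero-phase filters and hazes the deep
image), per-channel gain compensation and bad-element zeroing, Wiener
deconvolution `H*/(|H|²+nsr)` of the system response, zero-phase band-pass,
and an angular-sensitivity (SIR) compensation tag consumed during
back-projection as regularized inverse directivity (floor 0.1). The Wiener
response includes the known laser-pulse smoothing along with the EIR: the
two laser lines have different pulse durations, and removing both restores
the same intrinsic spectrum for either wavelength — this is what makes the
dual-wavelength images spectrally comparable (verified by an identical-optics
control: cross-wavelength reconstruction ratio 1.001). The default
regularization is nsr = 10⁻³; the hardware value is not public.

The band-pass low cutoff is 67 kHz (100 kHz variant available). The high
cutoff, when not specified, is chosen from the data as the corner where the
channel-average spectrum sinks into the white thermoelectric noise floor
implied by the NEP — low-order zero-phase Butterworth sections are used
(order-2 high-pass + order-4 low-pass, applied forward-backward) so the
low-cutoff ringing stays short while deconvolution-amplified out-of-band
content is strongly suppressed.

## Reconstruction

Weighted filtered back-projection of the data function `p − t ∂p/∂t`
(central differences; ramp-filter-like), sampled at the acoustic time of
flight with linear interpolation and weighted by the element solid angle
relative to the total aperture per pixel (limited-view normalization). The
`t ∂p/∂t` term balances spherical spreading, so identical absorbers
reconstruct with comparable brightness across the field of view (verified
to ~1% laterally; a depth series of point targets is flat to ~10% before
any fluence effect). An analytic-signal variant back-projects the complex
data function and returns its magnitude — a carrier-phase-insensitive
brightness envelope used for localization; display envelopes are otherwise
taken along depth. Sub-resolution point targets localize to within one
0.15 mm grid cell over the 5–35 mm depth range; extended absorbers image as
their band-passed edges, which is physics, not error.

The B-mode background is deliberately simple: seeded band-limited speckle
on an echogenicity map with hypoechoic inclusions, co-registered with the
OA grid. It exists so overlays can be composited and tested; it is not a
beamformed ultrasound simulation.

## Functional mapping

Bright objects are segmented at a rowwise-robust threshold (median +
3·1.4826·MAD, morphologically closed). Depth normalization divides each
pixel by its row's background reference. Two reference modes exist:

- **Measured rows** (the three-step method: segment, row-average excluding
  objects, divide): exact on images whose background dominates — a pure
  exponential background flattens to 1 within 10⁻⁶ and embedded-vessel
  contrast is preserved within 10% across 13–32 mm depth. This is the
  display-flattening mode.
- **Bulk-calibration model**: divide by `exp(−μeff z)` of the known bulk
  optics. This is the quantitative mode used by the pipeline: at the
  tube/background contrast of the bench scenes (20–90×), limited-view
  reconstruction halo (3–17% of tube brightness) exceeds the true
  background level almost everywhere, so an image-measured reference is
  contaminated in a wavelength-inconsistent way, while the conditioning
  chain's wavelength symmetry makes model compensation exact up to a common
  gain — which cancels in the sO2 ratio. [tHb] is therefore relative, as
  the underlying method intends.

Unmixing inverts the 2×2 extinction system exactly per pixel; sO2 is clamped
to [0, 1] and marked undefined where tHb falls below 5% of the map's 99th
percentile (the ratio is unstable at low signal). Statistical mapping
standardizes a map against a reference region (default: background rows at
5–15 mm depth) as z-scores. ROI oximetry is reported as the
hemoglobin-weighted ROI mean — the reading of the vessel core rather than
of the dim pixels between bright rim responses.

## Rendering and frame pairing

The palette anchors are 85% (red/transparent) and 90% (transparent/green),
with the transparent band closed at both ends; magenta below 40% and cyan
above 98% are qualitative conventions for the extremes, configurable.
Opacity ramps linearly over 2 percentage points outside the transparent
band. [tHb] renders yellow above the 90th percentile of the map ("only the
highest relative values are colored"). Compositing is standard alpha over
the grayscale background, preserved bit-exactly wherever alpha is zero; the
"combined" mode shows sO2 color only on the tHb-colored support. Frame
pairing walks an alternating 757/1064 nm stream (5 ms inter-pulse delay,
10 frames/s → 5 pairs/s), dropping and logging unpaired or duplicate-
wavelength frames.

## Accuracy, problem sizes, and known limitations

End-to-end, noise-free two-tube scenes recover ROI sO2 within ±5 percentage
points of truth for saturations between 50 and 100% and depths 13–32 mm
(typically within 2–4 pp); with detection noise at the NEP the recovery
holds its color classification down to hematocrit 4%, while the [tHb]
signal-to-noise ratio falls monotonically with dilution. Simulations in the
test-suite and acceptance runs use the default 0.15 mm / 38 mm grids and
single-shot acquisitions; each dual-wavelength chain takes a few seconds.

Known limitations:

- **Embedded-contrast bias.** A blood tube displaces background, so its
  optoacoustic contrast is μa(tube) − μa(background); the unmixer treats
  the compensated brightness as μa(tube) because the absolute gain needed
  to add the background term back is not identifiable from the image. The
  resulting sO2 bias is about −0.5 to −1 pp at bench-scene contrasts (it
  scales with μa_bg/μa_tube). In particular, a tube at exactly 85% — the
  closed edge of the transparent display band — recovers ≈84.4% and
  renders red rather than transparent. Inter-tube halo cross-talk
  contributes comparably smaller shifts with tube-dependent sign.
- The fluence model is 1D planar; lateral beam structure and spectral
  changes of scattering are not modeled. Acoustic attenuation uses a single
  reference frequency per path (no dispersion). Sound speed is homogeneous.
- The background texture emulates sub-resolution heterogeneity
  statistically; real breast microvasculature is vessel-like and
  anisotropic, so passing tests demonstrate chain consistency, not clinical
  realism.
- Physical-bench numbers of the source system (absolute resolutions, NEP as
  an absolute) are represented only as orderings and scale conventions.
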