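"""Check the forward simulator against the closed-form sphere N-wave.

A uniformly absorbing sphere has an analytic pressure solution: a bipolar
N-shaped pulse of duration 2a/c whose amplitude falls as a/(2R).  The
simulator voxelizes the same sphere in 3D and superposes retarded point
contributions; after the shared system response (laser pulse + transducer
EIR) the two waveforms should agree to well under 1% RMS.
"""

import math

import numpy as np

from oabreast import ProbeModel
from oabreast.forward import (
    SimulationConfig,
    laser_pulse_ns,
    simulate_sinogram,
    sphere_nwave,
)
from oabreast.phantom import DigitalPhantom, Inclusion, OpticalProperties

probe = ProbeModel(n_elements=4)
phantom = DigitalPhantom(
    extent_mm=(10.0, 16.0), spacing_mm=0.0125,
    background_optics=OpticalProperties(mu_a={800.0: 0.0}, mu_s_prime={800.0: 1.0}),
    inclusions=(Inclusion(shape="sphere", center_mm=(0.0, 10.0), size_mm=(2.0,),
                          optics=OpticalProperties(mu_a={800.0: 1.0})),),
    texture_sigma=0.0,
)
cfg = SimulationConfig(noise=False, attenuation=False, n_quad=1, fs_mhz=80.0)
sino = simulate_sinogram(phantom, probe, 800.0, cfg)

e = int(np.argmin(np.abs(sino.element_x_mm)))
d = math.hypot(sino.element_x_mm[e], 10.0)
ss, n = 8, sino.n_samples
t_fine = np.arange(n * ss) / (cfg.fs_mhz * ss)
ana = sphere_nwave(t_fine, 1.0, d, cfg.speed_of_sound)
freqs = np.fft.rfftfreq(n * ss, d=1.0 / (cfg.fs_mhz * ss))
h = probe.eir_transfer(freqs) * np.sinc(freqs * laser_pulse_ns(800.0) * 1e-3)
ref = np.fft.irfft(np.fft.rfft(ana) * h, n=n * ss)[::ss] * cfg.pa_per_unit

err = np.sqrt(np.mean((sino.data[e] - ref) ** 2) / np.mean(ref**2))
print(f"sphere radius 1.0 mm at {d:.2f} mm; simulated vs analytic N-wave")
print(f"peak pressure: simulated {sino.data[e].max():.1f} Pa, "
      f"analytic {ref.max():.1f} Pa")
print(f"relative RMS mismatch: {100 * err:.2f}%  (voxelization + sampling error)")
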