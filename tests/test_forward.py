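"""Forward model: fluence, attenuation, N-wave oracle, simulator physics."""

import math

import numpy as np
import pytest

from oabreast import ProbeModel
from oabreast.forward import (
    SimulationConfig,
    acoustic_attenuation,
    effective_attenuation,
    fluence,
    initial_pressure,
    inject_edge_wave,
    laser_pulse_ns,
    simulate_sinogram,
    sphere_nwave,
)
from oabreast.phantom import (
    BREAST_MU_S_PRIME,
    DigitalPhantom,
    Inclusion,
    OpticalProperties,
    aqueous_background_acoustics,
)

ZERO_BG = OpticalProperties(
    mu_a={757.0: 0.0, 1064.0: 0.0}, mu_s_prime=dict(BREAST_MU_S_PRIME)
)


def _absorber(x, z, diameter=0.6, mu=1.0):
    return Inclusion(
        shape="tube", center_mm=(x, z), size_mm=(diameter,),
        optics=OpticalProperties(mu_a={757.0: mu, 1064.0: mu}),
    )


def _phantom(*incs, extent=(38.0, 38.0), spacing=0.15, bg=ZERO_BG):
    return DigitalPhantom(
        extent_mm=extent, spacing_mm=spacing, background_optics=bg,
        background_acoustics=aqueous_background_acoustics(),
        inclusions=incs, texture_sigma=0.0,
    )


# -- optics ----------------------------------------------------------------

def test_fluence_diffusion_arithmetic():
    """Breast bulk optics give mu_eff ~ 1.03 cm^-1 at 757 nm and a one-
    centimeter fluence factor of ~0.357."""
    mu_eff = effective_attenuation(0.039, 9.0)
    assert mu_eff == pytest.approx(1.0284, abs=2e-3)
    ph = DigitalPhantom(texture_sigma=0.0)
    f = fluence(ph, 757.0)
    z, _ = ph.axes_mm()
    iz = np.argmin(np.abs(z - 10.0))
    assert f[iz, 0] == pytest.approx(math.exp(-mu_eff), rel=2e-2)
    assert f[0, 0] == pytest.approx(1.0, abs=0.02)  # surface normalization
    assert np.all(np.diff(f[:, 0]) < 0)  # strictly decreasing with depth
    with pytest.raises(KeyError):
        fluence(ph, 800.0)


def test_initial_pressure_product_and_ratio():
    ph = DigitalPhantom(texture_sigma=0.0)
    f = fluence(ph, 757.0)
    p0 = initial_pressure(ph, f, 757.0)
    assert np.allclose(p0, 0.039 * f)
    tumor = _phantom(
        Inclusion(shape="ellipse", center_mm=(0.0, 20.0), size_mm=(10.0, 7.0),
                  optics=OpticalProperties(mu_a={757.0: 0.130})),
        bg=OpticalProperties(mu_a={757.0: 0.039}, mu_s_prime={757.0: 9.0}),
    )
    p0 = initial_pressure(tumor, fluence(tumor, 757.0), 757.0)
    iz = np.argmin(np.abs(tumor.axes_mm()[0] - 20.0))
    row = p0[iz]
    # lesion vs background at the same depth: fluence cancels exactly
    assert row.max() / row.min() == pytest.approx(0.130 / 0.039, rel=1e-6)
    with pytest.raises(ValueError):
        initial_pressure(tumor, f[:10, :10], 757.0)


def test_acoustic_attenuation_identities_and_breast_anchor():
    assert acoustic_attenuation(1.0, 5.0, 0.0) == 1.0
    assert acoustic_attenuation(1.0, 0.0, 3.0) == 1.0
    loss = 1.0 / acoustic_attenuation(1.0, 10.0, 1.0)
    assert loss == pytest.approx(10 ** (0.32 * 10**1.5 / 20.0), rel=1e-12)
    assert loss == pytest.approx(3.2, abs=0.1)
    rng = np.random.default_rng(0)
    f = np.sort(rng.uniform(0.1, 12.0, 20))
    z = np.sort(rng.uniform(0.1, 4.0, 20))
    assert np.all(np.diff(acoustic_attenuation(1.0, f, 2.0)) < 0)
    assert np.all(np.diff(acoustic_attenuation(1.0, 5.0, z)) < 0)
    with pytest.raises(ValueError):
        acoustic_attenuation(1.0, -1.0, 1.0)


def test_sphere_nwave_shape():
    t = np.arange(0, 20, 0.005)
    c, a, d = 1.54, 1.0, 12.0
    p = sphere_nwave(t, a, d, c)
    onset = (d - a) / c
    assert np.all(p[t < onset - 0.005] == 0.0)
    support = np.flatnonzero(p != 0.0)
    duration = t[support[-1]] - t[support[0]]
    assert duration == pytest.approx(2 * a / c, abs=0.02)
    assert np.trapezoid(p, t) == pytest.approx(0.0, abs=1e-4)
    assert p.max() == pytest.approx(a / (2 * d), rel=1e-2)
    with pytest.raises(ValueError):
        sphere_nwave(t, 2.0, 1.0)


# -- the simulator ---------------------------------------------------------

def test_empty_phantom_gives_silence(probe):
    ph = _phantom()
    sino = simulate_sinogram(ph, probe, 757.0, SimulationConfig(noise=False))
    assert np.all(sino.data == 0.0)


def test_sampling_below_nyquist_rejected(probe):
    with pytest.raises(ValueError):
        simulate_sinogram(_phantom(), probe, 757.0, SimulationConfig(fs_mhz=20.0))


def test_superposition_linearity(probe):
    cfg = SimulationConfig(noise=False, attenuation=False)
    a = _absorber(-4.0, 12.0)
    b = _absorber(5.0, 18.0)
    small = dict(extent=(24.0, 24.0), spacing=0.2)
    s_a = simulate_sinogram(_phantom(a, **small), probe, 757.0, cfg)
    s_b = simulate_sinogram(_phantom(b, **small), probe, 757.0, cfg)
    s_ab = simulate_sinogram(_phantom(a, b, **small), probe, 757.0, cfg)
    assert np.allclose(s_ab.data, s_a.data + s_b.data, atol=1e-9)


def test_earliest_arrival_time_of_flight(probe):
    z0 = 20.0
    ph = _phantom(_absorber(0.0, z0, diameter=0.4), extent=(24.0, 24.0), spacing=0.1)
    cfg = SimulationConfig(noise=False, attenuation=False)
    sino = simulate_sinogram(ph, probe, 757.0, cfg)
    e = int(np.argmin(np.abs(sino.element_x_mm)))
    t = sino.time_axis_us()
    peak_t = t[np.argmax(np.abs(sino.data[e]))]
    assert peak_t == pytest.approx(z0 / cfg.speed_of_sound, abs=0.3)
    # first arrival is at the central element
    peak_times = t[np.argmax(np.abs(sino.data), axis=1)]
    assert abs(sino.element_x_mm[np.argmin(peak_times)]) < 2.0


def test_two_tube_scene_shows_two_arcs(probe):
    from oabreast import make_two_tube_phantom
    from scipy.signal import hilbert

    ph = make_two_tube_phantom(depth_mm=10.0, diameter_mm=2.4)
    sino = simulate_sinogram(ph, probe, 757.0, SimulationConfig(noise=False))
    # an off-center element sees the two tubes at distinct times of flight
    e = int(np.argmin(np.abs(sino.element_x_mm - (-10.0))))
    env = np.abs(hilbert(sino.data[e]))
    t = sino.time_axis_us()
    c = 1.54
    t1 = math.hypot(-10.0 + 6.0, 10.0) / c
    t2 = math.hypot(-10.0 - 6.0, 10.0) / c
    between = (t > t1 + 1.0) & (t < t2 - 1.0)
    for tk in (t1, t2):
        window = (t > tk - 0.8) & (t < tk + 0.8)
        assert env[window].max() > 2 * env[between].max()


def test_depth_scaling_follows_fluence_and_spreading(probe):
    """Identical absorbers at increasing depth: the detected pulse
    amplitude tracks F(z)/R within 5%.

    The pulse amplitude is the RMS over the arrival window, normalized by
    the absorber's rasterized mass (the 0.6 mm disk quantizes onto the
    grid with a few-percent pixel-count jitter per position); a strong
    synthetic absorber keeps the coherent background-slab signal in the
    window negligible.
    """
    bg = OpticalProperties(mu_a={757.0: 0.039}, mu_s_prime={757.0: 9.0})
    cfg = SimulationConfig(noise=False, attenuation=False)
    mu_eff = effective_attenuation(0.039, 9.0)
    amps, model = [], []
    for z0 in (13.0, 19.0, 26.0, 32.0):
        ph = _phantom(_absorber(0.0, z0, diameter=0.6, mu=500.0), bg=bg)
        mass = (ph.mu_a_map(757.0) > 100.0).sum()
        sino = simulate_sinogram(ph, probe, 757.0, cfg)
        e = int(np.argmin(np.abs(sino.element_x_mm)))
        t = sino.time_axis_us()
        arrival = (t > z0 / cfg.speed_of_sound - 1.0) & (
            t < z0 / cfg.speed_of_sound + 1.0
        )
        amps.append(np.sqrt((sino.data[e][arrival] ** 2).sum()) / mass)
        model.append(math.exp(-mu_eff * z0 / 10.0) / z0)
    amps = np.array(amps) / amps[0]
    model = np.array(model) / model[0]
    assert np.allclose(amps, model, rtol=0.05)


def test_seeded_noise_reproducibility(probe):
    ph = _phantom(_absorber(0.0, 15.0), extent=(24.0, 24.0), spacing=0.2)
    cfg = SimulationConfig(noise=True, seed=11)
    s1 = simulate_sinogram(ph, probe, 757.0, cfg)
    s2 = simulate_sinogram(ph, probe, 757.0, cfg)
    assert np.array_equal(s1.data, s2.data)
    s3 = simulate_sinogram(ph, probe, 757.0, SimulationConfig(noise=True, seed=12))
    assert not np.array_equal(s1.data, s3.data)


def test_wavelength_selects_laser_pulse():
    assert laser_pulse_ns(757.0) == 50.0
    assert laser_pulse_ns(1064.0) == 15.0


# -- edge-wave artifact ----------------------------------------------------

def _silent_sinogram(probe):
    ph = _phantom()
    return simulate_sinogram(ph, probe, 757.0, SimulationConfig(noise=False))


def test_edge_wave_v_shape_and_center_delay(probe):
    sino = inject_edge_wave(_silent_sinogram(probe), probe, beam_edge="sharp",
                            base_sigma_us=0.2)
    t = sino.time_axis_us()
    # onset of the first (near-edge) branch per channel; each channel also
    # carries the later far-edge branch, so peak picking is ambiguous
    onset = np.array([
        t[np.argmax(np.abs(tr) > 0.3 * np.abs(tr).max())] for tr in sino.data
    ])
    center = probe.n_elements // 2
    assert onset[center] > onset[0]
    assert onset[center] > onset[-1]
    assert onset[center] == pytest.approx(
        probe.aperture_mm / 2.0 / sino.speed_of_sound, abs=1.0
    )
    # the sweep is ordered: quarter-aperture elements lie between the edge
    # and the apex
    quarter = probe.n_elements // 4
    assert onset[0] < onset[quarter] < onset[center]
    assert onset[-1] < onset[-quarter] < onset[center]


def test_edge_softening_reduces_artifact_energy(probe):
    base = _silent_sinogram(probe)
    energies = [
        float((inject_edge_wave(base, probe, beam_edge=edge,
                                edge_sigma_mm=sig).data ** 2).sum())
        for edge, sig in (("sharp", None), ("gaussian", 2.0),
                          ("gaussian", 5.0), ("gaussian", 10.0))
    ]
    assert all(a > b for a, b in zip(energies, energies[1:]))
    assert energies[-1] < 0.1 * energies[0]
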