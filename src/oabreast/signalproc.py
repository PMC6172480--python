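"""Restore intrinsic optoacoustic pressure profiles from raw channel data.

The conditioning chain mirrors the receive path of the clinical system:
per-channel gain compensation and zeroing of known-bad elements, Wiener
deconvolution of the electro-acoustic impulse response to restore the
intrinsic ultrasonic spectrum, band-pass filtering (low cutoff ~67 kHz,
high cutoff at the transducer band edge) to reject thermoelectric noise and
slow laser-induced artifacts, and a regularized angular-sensitivity (SIR)
compensation that is consumed as inverse directivity weighting inside the
back-projection.

Every stage is linear and zero-phase, preserving the arrival times on
which time-of-flight tomography depends.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .forward import Sinogram
from .probe import ProbeModel

__all__ = [
    "ChannelCalibration",
    "FilterSpec",
    "compensate_channels",
    "wiener_deconvolve_eir",
    "deconvolve_sir",
    "inverse_directivity_weight",
    "bandpass",
    "condition",
]


@dataclass(frozen=True)
class ChannelCalibration:
    """Per-element gain factors and the indices of dead channels."""

    gains: tuple[float, ...]
    bad_elements: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        bad = set(self.bad_elements)
        for i, g in enumerate(self.gains):
            if i not in bad and g <= 0:
                raise ValueError(f"gain of live element {i} must be positive")
        if any(not 0 <= b < len(self.gains) for b in bad):
            raise ValueError("bad element index out of range")

    @classmethod
    def identity(cls, n_elements: int) -> "ChannelCalibration":
        return cls(gains=(1.0,) * n_elements)


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass specification (MHz).  Zero-phase Butterworth by default.

    The low cutoff defaults to 67 kHz; the 100 kHz variant used for
    aggressive artifact rejection is obtained by passing low_mhz=0.1.
    ``order`` is the design order of the underlying Butterworth sections;
    the forward-backward (zero-phase) application doubles the effective
    magnitude order, so the default gives 4th-order low-edge skirts.  The
    low design order keeps the low-cutoff ringing short, which matters for
    the smooth bulk-background signal; the high edge uses the steeper
    ``lp_order`` to keep deconvolution-amplified out-of-band content out
    of the image.
    """

    low_mhz: float = 0.067
    high_mhz: float = 12.0
    order: int = 2
    lp_order: int = 4
    family: str = "butter"

    def __post_init__(self) -> None:
        if not 0 < self.low_mhz < self.high_mhz:
            raise ValueError("cutoffs must satisfy 0 < low < high")


def time_gate(
    sino: Sinogram, gate_us: float = 1.0, taper_us: float = 0.5
) -> Sinogram:
    """Zero the early-time dead zone with a cosine taper.

    The first microsecond of every trace is dominated by the skin-line /
    probe-surface arrival, which would otherwise ring through the zero-
    phase filters and haze the deep image rows; hand-held probes treat the
    region adjacent to the array face as a dead zone.  Gating before any
    filtering also gives the filters clean (zero) trace edges.
    """
    if gate_us < 0 or taper_us < 0:
        raise ValueError("gate and taper must be nonnegative")
    t = sino.time_axis_us()
    if taper_us > 0:
        ramp = np.clip((t - gate_us) / taper_us, 0.0, 1.0)
        window = 0.5 - 0.5 * np.cos(np.pi * ramp)
    else:
        window = (t >= gate_us).astype(float)
    return sino.copy_with(sino.data * window, time_gate_us=gate_us)


def compensate_channels(raw: Sinogram, cal: ChannelCalibration) -> Sinogram:
    """Divide each live channel by its gain; zero the bad channels."""
    if len(cal.gains) != raw.n_elements:
        raise ValueError("calibration length does not match element count")
    data = raw.data.copy()
    gains = np.asarray(cal.gains, dtype=float)
    bad = np.array(cal.bad_elements, dtype=int)
    live = np.ones(raw.n_elements, dtype=bool)
    if bad.size:
        live[bad] = False
    data[live] /= gains[live, None]
    if bad.size:
        data[bad] = 0.0
    return raw.copy_with(data, channel_compensated=True)


def wiener_deconvolve_eir(
    sino: Sinogram, probe: ProbeModel, nsr: float = 1e-3,
    include_pulse: bool = True,
) -> Sinogram:
    """Wiener deconvolution of the system response: H* / (|H|^2 + nsr).

    H is the transducer EIR and, by default, the known laser-pulse
    smoothing recorded in the sinogram metadata — the two laser lines have
    different pulse durations, and removing both restores the same
    intrinsic tissue spectrum for either wavelength, which is what makes
    the dual-wavelength images spectrally comparable.  For nsr -> 0 this
    inverts the band-limiting of detection exactly in-band; nsr
    regularizes the out-of-band division.
    """
    if nsr < 0:
        raise ValueError("noise-to-signal ratio must be nonnegative")
    n = sino.n_samples
    freqs = np.fft.rfftfreq(n, d=1.0 / sino.fs_mhz)
    h = probe.eir_transfer(freqs)
    if include_pulse:
        h = h * np.sinc(freqs * sino.pulse_ns * 1e-3)
    if not np.any(h):
        raise ValueError("EIR transfer function is identically zero")
    w = np.conj(h) / (np.abs(h) ** 2 + nsr)
    data = np.fft.irfft(np.fft.rfft(sino.data, axis=1) * w, n=n, axis=1)
    return sino.copy_with(data, eir_deconvolved=True, wiener_nsr=nsr)


def inverse_directivity_weight(
    sin_theta: np.ndarray | float,
    probe: ProbeModel,
    speed_of_sound: float = 1.54,
    floor: float = 0.1,
) -> np.ndarray:
    """Regularized inverse of the element directivity, capped at 1/floor."""
    d = probe.directivity(sin_theta, speed_of_sound)
    return 1.0 / np.clip(d, floor, None)


def deconvolve_sir(sino: Sinogram, probe: ProbeModel, floor: float = 0.1) -> Sinogram:
    """Mark the sinogram for angular-sensitivity (SIR) compensation.

    The finite element width narrows the angular acceptance; compensating
    for it widens the effective directivity.  Because the correction is a
    function of the source-to-element angle, it is applied in image
    coordinates during back-projection (see ``recon.backproject``), using
    ``inverse_directivity_weight`` with the regularization floor recorded
    here.  This stage only attaches the contract to the data's provenance.
    """
    if floor <= 0:
        raise ValueError("regularization floor must be positive")
    return sino.copy_with(sino.data, sir_compensate=True, sir_floor=floor)


def select_high_cutoff(
    sino: Sinogram,
    nep_pa: float,
    snr_factor: float = 2.0,
    fmin_mhz: float = 1.5,
    fmax_mhz: float = 12.0,
) -> float:
    """Choose the band-pass high cutoff just outside the noise-dominated band.

    The thermoelectric noise floor is white while the optoacoustic signal
    spectrum falls with frequency, so above some corner the channel data
    carry only noise.  This estimates the channel-averaged power spectrum,
    smooths it, and returns the lowest frequency (within
    [fmin_mhz, fmax_mhz]) above which the spectrum stays below
    ``snr_factor``^2 times the NEP noise floor; the transducer band edge
    is returned if the signal clears the floor everywhere.
    """
    n = sino.n_samples
    freqs = np.fft.rfftfreq(n, d=1.0 / sino.fs_mhz)
    psd = (np.abs(np.fft.rfft(sino.data, axis=1)) ** 2).mean(axis=0)
    noise_level = n * nep_pa**2  # E|X_k|^2 of white noise with std nep
    # moving-average smoothing over ~0.25 MHz
    win = max(3, int(0.25 / (freqs[1] - freqs[0])))
    kernel = np.ones(win) / win
    smooth = np.convolve(psd, kernel, mode="same")
    band = (freqs >= fmin_mhz) & (freqs <= fmax_mhz)
    below = smooth < (snr_factor**2) * noise_level
    idx = np.nonzero(band & below)[0]
    if idx.size == 0:
        return fmax_mhz
    # require the spectrum to stay below the floor from the corner on
    for i in idx:
        j = (freqs >= freqs[i]) & (freqs <= fmax_mhz)
        if np.mean(below[j]) > 0.9:
            return float(freqs[i])
    return fmax_mhz


def bandpass(sino: Sinogram, spec: FilterSpec = FilterSpec()) -> Sinogram:
    """Zero-phase band-pass per channel; removes DC and out-of-band noise."""
    nyq = sino.fs_mhz / 2.0
    if spec.high_mhz >= nyq:
        raise ValueError(f"high cutoff {spec.high_mhz} MHz >= Nyquist {nyq} MHz")
    if spec.family != "butter":
        raise ValueError(f"unsupported filter family {spec.family!r}")
    sos_hp = sps.butter(spec.order, spec.low_mhz, btype="highpass",
                        fs=sino.fs_mhz, output="sos")
    sos_lp = sps.butter(spec.lp_order, spec.high_mhz, btype="lowpass",
                        fs=sino.fs_mhz, output="sos")
    data = sps.sosfiltfilt(sos_hp, sino.data, axis=1)
    data = sps.sosfiltfilt(sos_lp, data, axis=1)
    return sino.copy_with(
        data, bandpass=(spec.low_mhz, spec.high_mhz), bandpass_order=spec.order
    )


def condition(
    raw: Sinogram,
    probe: ProbeModel,
    cal: ChannelCalibration | None = None,
    nsr: float = 1e-3,
    spec: FilterSpec | None = None,
    sir: bool = True,
    gate_us: float = 1.0,
) -> Sinogram:
    """Full conditioning chain: gate -> gains -> Wiener -> band-pass -> SIR tag.

    When no FilterSpec is given, the band-pass high cutoff is selected from
    the gated data as the corner where the signal spectrum sinks into the
    thermoelectric noise floor (see ``select_high_cutoff``).
    """
    cal = cal if cal is not None else ChannelCalibration.identity(raw.n_elements)
    out = time_gate(raw, gate_us=gate_us) if gate_us > 0 else raw
    if spec is None:
        spec = FilterSpec(high_mhz=select_high_cutoff(out, probe.nep_pa))
    out = compensate_channels(out, cal)
    out = wiener_deconvolve_eir(out, probe, nsr=nsr)
    out = bandpass(out, spec)
    if sir:
        out = deconvolve_sir(out, probe)
    return out
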