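"""Hand-held dual-modality probe model.

128-element linear transducer array with ultrawide-band sensitivity
(0.1-12 MHz at the -6 dB points) and two rectangular illumination windows
flanking the array.  The electro-acoustic impulse response (EIR) is modeled
as a zero-phase band-pass magnitude parameterized by its -6 dB edges; the
spatial impulse response of a finite-width element is represented by the
far-field flat-rectangle directivity and, in the forward simulator, by
quadrature averaging across the element face.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ProbeModel", "IlluminationWindow"]


@dataclass(frozen=True)
class IlluminationWindow:
    """One rectangular light-delivery window along the array.

    edge_profile "sharp" means an abrupt beam boundary on the skin (the
    worst case for skin-borne edge-wave artifacts); "gaussian" rolls the
    edge off with lateral sigma ``edge_sigma_mm``.
    """

    length_mm: float = 40.0
    width_mm: float = 6.0
    edge_profile: str = "sharp"
    edge_sigma_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.edge_profile not in ("sharp", "gaussian"):
            raise ValueError(f"unknown edge profile {self.edge_profile!r}")


@dataclass(frozen=True)
class ProbeModel:
    """Linear-array probe geometry and responses.

    n_elements x pitch gives a ~40 mm aperture matching the illumination
    window length; element width 0.25 mm keeps in-plane directivity wide.
    EIR band edges are the -6 dB points.  ``nep_pa`` is the noise-equivalent
    pressure of a single-channel, single-shot measurement.
    """

    n_elements: int = 128
    element_width_mm: float = 0.25
    pitch_mm: float = 0.3125
    eir_low_mhz: float = 0.1
    eir_high_mhz: float = 12.0
    eir_order: int = 2
    nep_pa: float = 1.3
    directivity_f_ref_mhz: float = 2.0
    illumination: tuple[IlluminationWindow, IlluminationWindow] = (
        IlluminationWindow(),
        IlluminationWindow(),
    )

    def __post_init__(self) -> None:
        if self.element_width_mm > self.pitch_mm:
            raise ValueError("element width cannot exceed the pitch")
        if not 0 < self.eir_low_mhz < self.eir_high_mhz:
            raise ValueError("EIR band edges must satisfy 0 < low < high")

    @property
    def aperture_mm(self) -> float:
        return self.n_elements * self.pitch_mm

    def element_positions_mm(self) -> np.ndarray:
        """Lateral element-center coordinates, symmetric about x = 0."""
        idx = np.arange(self.n_elements) - (self.n_elements - 1) / 2.0
        return idx * self.pitch_mm

    # -- electro-acoustic impulse response --------------------------------

    def eir_transfer(self, freqs_mhz: np.ndarray) -> np.ndarray:
        """Zero-phase EIR magnitude |H(f)| with -6 dB points at the band edges.

        Butterworth-type magnitude sections; the corner frequencies are
        placed so |H| = 1/2 exactly at ``eir_low_mhz`` and ``eir_high_mhz``.
        """
        f = np.abs(np.asarray(freqs_mhz, dtype=float))
        n = self.eir_order
        # |H|=0.5 at the edge  =>  (edge/corner)^(2n) = 3 for each section
        shift = 3.0 ** (1.0 / (2 * n))
        f_lo = self.eir_low_mhz * shift
        f_hi = self.eir_high_mhz / shift
        with np.errstate(divide="ignore"):
            hp = 1.0 / np.sqrt(1.0 + (f_lo / np.where(f > 0, f, np.inf)) ** (2 * n))
        lp = 1.0 / np.sqrt(1.0 + (f / f_hi) ** (2 * n))
        return hp * lp

    def apply_eir(self, traces: np.ndarray, fs_mhz: float) -> np.ndarray:
        """Convolve traces (…, n_samples) with the zero-phase EIR."""
        n = traces.shape[-1]
        freqs = np.fft.rfftfreq(n, d=1.0 / fs_mhz)
        spec = np.fft.rfft(traces, axis=-1) * self.eir_transfer(freqs)
        return np.fft.irfft(spec, n=n, axis=-1)

    # -- spatial (angular) response ----------------------------------------

    def directivity(self, sin_theta: np.ndarray | float,
                    speed_of_sound: float = 1.54) -> np.ndarray:
        """Far-field directivity of a flat rectangular element.

        |sinc(w f sin(theta) / c)| evaluated at the reference frequency;
        theta is measured from the element normal (depth axis).  Equal to 1
        at normal incidence.
        """
        arg = (
            self.element_width_mm
            * self.directivity_f_ref_mhz
            * np.asarray(sin_theta, dtype=float)
            / speed_of_sound
        )
        return np.abs(np.sinc(arg))

    def quadrature_offsets_mm(self, n_quad: int = 5) -> np.ndarray:
        """Sub-element lateral sample offsets for surface averaging."""
        if n_quad == 1:
            return np.zeros(1)
        return np.linspace(-0.5, 0.5, n_quad) * self.element_width_mm
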