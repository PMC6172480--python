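"""Hemoglobin optical properties for dual-wavelength oximetry.

The imaging system estimates total hemoglobin [tHb] and blood oxygen
saturation [sO2] from optoacoustic images acquired at two near-infrared
wavelengths chosen on opposite sides of the oxy/deoxy hemoglobin spectral
crossover (~800 nm): at 757 nm deoxyhemoglobin absorbs more strongly than
oxyhemoglobin, while at 1064 nm the ratio is inverted.  That sign flip is
what makes the pixelwise two-chromophore inversion well conditioned.

The bundled molar extinction table is compiled from standard published NIR
hemoglobin spectra (values are approximate, rounded compilations; see
``HEMOGLOBIN_TABLE.metadata``).  All downstream oximetry in this package is
self-consistent: the phantom generator and the spectral unmixer share the
same table, so relative [sO2]/[tHb] estimates do not depend on the absolute
accuracy of the tabulated values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "ChromophoreTable",
    "BloodState",
    "HEMOGLOBIN_TABLE",
    "blood_mu_a",
    "MOLAR_SCALE",
    "WHOLE_BLOOD_HEMOGLOBIN_M",
    "REFERENCE_HEMATOCRIT",
]

#: Hemoglobin concentration of whole blood (hematocrit ~41%), mol/L.
WHOLE_BLOOD_HEMOGLOBIN_M = 2.3e-3

#: Hematocrit at which the relative total-hemoglobin scale equals 1.
REFERENCE_HEMATOCRIT = 0.41

#: Converts (molar extinction x relative tHb) to an absorption coefficient in
#: cm^-1: ln(10) x whole-blood hemoglobin molarity.  mu_a = ln10 * eps * C.
MOLAR_SCALE = math.log(10.0) * WHOLE_BLOOD_HEMOGLOBIN_M


@dataclass(frozen=True)
class ChromophoreTable:
    """Molar extinction of deoxy- (Hb) and oxyhemoglobin (HbO2) vs wavelength.

    Units: cm^-1 M^-1.  Lookup is exact (no interpolation): the imaging
    system operates at two fixed laser lines.
    """

    wavelengths_nm: tuple[float, ...]
    eps_hb: tuple[float, ...]
    eps_hbo2: tuple[float, ...]
    metadata: str = ""

    def __post_init__(self) -> None:
        n = len(self.wavelengths_nm)
        if len(self.eps_hb) != n or len(self.eps_hbo2) != n:
            raise ValueError("table columns must have equal length")
        if any(e <= 0 for e in self.eps_hb) or any(e <= 0 for e in self.eps_hbo2):
            raise ValueError("extinction coefficients must be strictly positive")

    def _index(self, wavelength_nm: float) -> int:
        try:
            return self.wavelengths_nm.index(float(wavelength_nm))
        except ValueError:
            raise KeyError(
                f"wavelength {wavelength_nm} nm not tabulated; "
                f"available: {self.wavelengths_nm}"
            ) from None

    def extinction(self, wavelength_nm: float) -> tuple[float, float]:
        """Return ``(eps_Hb, eps_HbO2)`` at an exact tabulated wavelength."""
        i = self._index(wavelength_nm)
        return self.eps_hb[i], self.eps_hbo2[i]


#: Compiled NIR hemoglobin extinction spectrum (approximate standard values).
HEMOGLOBIN_TABLE = ChromophoreTable(
    wavelengths_nm=(700.0, 730.0, 750.0, 757.0, 760.0, 800.0,
                    850.0, 900.0, 950.0, 1000.0, 1064.0),
    eps_hb=(1794.3, 1102.2, 1405.2, 1505.0, 1548.5, 761.7,
            691.3, 761.8, 602.0, 498.0, 420.0),
    eps_hbo2=(290.0, 390.0, 518.0, 562.0, 586.0, 816.0,
              1058.0, 1198.0, 1204.0, 1190.0, 1028.0),
    metadata=(
        "Approximate compiled NIR molar extinction values (cm^-1 M^-1) for "
        "human deoxy/oxyhemoglobin, rounded from standard published "
        "tabulations. Bundled for self-consistent simulation + unmixing."
    ),
)


@dataclass(frozen=True)
class BloodState:
    """Physiological state of blood filling a phantom inclusion.

    so2: oxygen saturation as a fraction in [0, 1].
    hematocrit: red-cell volume fraction in (0, 1]; hemoglobin concentration
        (and hence the relative total-hemoglobin scale ``thb``) is
        proportional to hematocrit, with thb = 1 at hematocrit 41%.
    """

    so2: float
    hematocrit: float = REFERENCE_HEMATOCRIT

    def __post_init__(self) -> None:
        if not 0.0 <= self.so2 <= 1.0:
            raise ValueError(f"so2 must be in [0, 1], got {self.so2}")
        if not 0.0 < self.hematocrit <= 1.0:
            raise ValueError(f"hematocrit must be in (0, 1], got {self.hematocrit}")

    @property
    def thb(self) -> float:
        """Relative total hemoglobin concentration (1.0 at Ht = 41%)."""
        return self.hematocrit / REFERENCE_HEMATOCRIT


def blood_mu_a(
    state: BloodState,
    wavelength_nm: float,
    table: ChromophoreTable = HEMOGLOBIN_TABLE,
    scale: float = MOLAR_SCALE,
) -> float:
    """Optical absorption coefficient of blood at one wavelength (cm^-1).

    mu_a = scale * thb * (so2 * eps_HbO2 + (1 - so2) * eps_Hb)

    Exactly linear in the relative hemoglobin concentration ``thb`` and
    affine in ``so2``.  With the default ``scale`` the result is an absolute
    absorption coefficient in cm^-1 for whole blood at thb = 1; pass
    ``scale=1.0`` to stay on the bare extinction scale.
    """
    eps_hb, eps_hbo2 = table.extinction(wavelength_nm)
    return scale * state.thb * (state.so2 * eps_hbo2 + (1.0 - state.so2) * eps_hb)
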