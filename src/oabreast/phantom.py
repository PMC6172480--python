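"""Digital breast phantoms for dual-wavelength optoacoustic simulation.

A phantom is a 2D imaging-plane scene (lateral x, depth z, probe face at
z = 0) of a homogeneous background with embedded inclusions: blood-filled
tubes seen in cross-section, spheres, or elliptical tumor-like lesions.
Background bulk optics default to average breast tissue; inclusions carry
either a blood state (absorption derived from the bundled hemoglobin table)
or explicit per-wavelength optical properties.

Scenes round-trip through a documented YAML schema (units mm and cm^-1) and
rasterize onto a regular grid for the forward simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .chromophores import HEMOGLOBIN_TABLE, BloodState, ChromophoreTable, blood_mu_a

__all__ = [
    "OpticalProperties",
    "AcousticProperties",
    "Inclusion",
    "DigitalPhantom",
    "breast_background",
    "aqueous_background_acoustics",
    "make_two_tube_phantom",
    "make_tumor_phantom",
    "load_scene",
    "save_scene",
    "BREAST_MU_A",
    "BREAST_MU_S_PRIME",
    "TUMOR_MU_A",
]

#: Average breast-tissue absorption (cm^-1) at the two laser lines.
BREAST_MU_A = {757.0: 0.039, 1064.0: 0.122}

#: Average breast-tissue reduced scattering (cm^-1); midpoints of the
#: reported ranges ~7.0-11.0 (757 nm) and ~3.5-4.5 (1064 nm).
BREAST_MU_S_PRIME = {757.0: 9.0, 1064.0: 4.0}

#: Mean malignant-tumor absorption (cm^-1): 2-3x breast background at
#: 757 nm, only slightly elevated at 1064 nm.
TUMOR_MU_A = {757.0: 0.130, 1064.0: 0.154}

#: Breast acoustic attenuation coefficient, dB cm^-1 MHz^-1.5.
BREAST_ALPHA_US = 0.32

#: Soft-tissue speed of sound, mm/us.
DEFAULT_SOS = 1.54


@dataclass(frozen=True)
class OpticalProperties:
    """Per-wavelength absorption/scattering plus thermoacoustic efficiency.

    mu_a, mu_s_prime: dict wavelength (nm) -> coefficient (cm^-1).
    grueneisen: relative thermoacoustic efficiency (dimensionless); the
        thermodynamic prefactor beta*c^2/Cp is folded into this constant.
    """

    mu_a: dict[float, float]
    mu_s_prime: dict[float, float] = field(default_factory=dict)
    grueneisen: float = 1.0

    def __post_init__(self) -> None:
        for d in (self.mu_a, self.mu_s_prime):
            if any(v < 0 for v in d.values()):
                raise ValueError("optical coefficients must be nonnegative")
        if self.grueneisen < 0:
            raise ValueError("grueneisen must be nonnegative")

    def mu_a_at(self, wavelength_nm: float) -> float:
        try:
            return self.mu_a[float(wavelength_nm)]
        except KeyError:
            raise KeyError(f"mu_a not defined at {wavelength_nm} nm") from None

    def mu_s_prime_at(self, wavelength_nm: float) -> float:
        try:
            return self.mu_s_prime[float(wavelength_nm)]
        except KeyError:
            raise KeyError(f"mu_s' not defined at {wavelength_nm} nm") from None


@dataclass(frozen=True)
class AcousticProperties:
    """Bulk acoustic medium parameters.

    speed_of_sound: mm/us; alpha_us: attenuation, dB cm^-1 MHz^-1.5.
    """

    speed_of_sound: float = DEFAULT_SOS
    alpha_us: float = BREAST_ALPHA_US

    def __post_init__(self) -> None:
        if self.speed_of_sound <= 0:
            raise ValueError("speed of sound must be positive")
        if self.alpha_us < 0:
            raise ValueError("alpha_us must be nonnegative")


def breast_background(wavelength_nm: float) -> OpticalProperties:
    """Average breast-tissue bulk optics at one of the two laser lines.

    Only 757 and 1064 nm are defined; other wavelengths raise (the bulk
    values are empirical means, not a spectrum to interpolate).
    """
    wl = float(wavelength_nm)
    if wl not in BREAST_MU_A:
        raise KeyError(f"breast bulk optics defined only at 757/1064 nm, got {wl}")
    return OpticalProperties(
        mu_a={wl: BREAST_MU_A[wl]},
        mu_s_prime={wl: BREAST_MU_S_PRIME[wl]},
    )


def _breast_optics_both() -> OpticalProperties:
    return OpticalProperties(mu_a=dict(BREAST_MU_A), mu_s_prime=dict(BREAST_MU_S_PRIME))


def aqueous_background_acoustics() -> AcousticProperties:
    """Water-tank medium: essentially lossless acoustically."""
    return AcousticProperties(speed_of_sound=DEFAULT_SOS, alpha_us=0.0022)


@dataclass(frozen=True)
class Inclusion:
    """One scene object: tube (cross-section), sphere, or ellipse.

    center_mm: (x, z) in the imaging plane, z positive into tissue.
    size_mm: tube/sphere -> diameter; ellipse -> (lateral, axial) diameters.
    Exactly one of ``blood`` or ``optics`` must be set.
    """

    shape: str
    center_mm: tuple[float, float]
    size_mm: tuple[float, ...]
    blood: BloodState | None = None
    optics: OpticalProperties | None = None

    def __post_init__(self) -> None:
        if self.shape not in ("tube", "sphere", "ellipse"):
            raise ValueError(f"unknown inclusion shape {self.shape!r}")
        if (self.blood is None) == (self.optics is None):
            raise ValueError("inclusion needs exactly one of blood / optics")
        if any(s <= 0 for s in self.size_mm):
            raise ValueError("inclusion size must be positive")

    @property
    def radii_mm(self) -> tuple[float, float]:
        """(lateral, axial) semi-axes of the in-plane cross-section."""
        if self.shape == "ellipse":
            a, b = self.size_mm[0] / 2.0, self.size_mm[-1] / 2.0
            return a, b
        r = self.size_mm[0] / 2.0
        return r, r

    def mu_a_at(self, wavelength_nm: float, table: ChromophoreTable = HEMOGLOBIN_TABLE) -> float:
        if self.blood is not None:
            return blood_mu_a(self.blood, wavelength_nm, table)
        assert self.optics is not None
        return self.optics.mu_a_at(wavelength_nm)


@dataclass(frozen=True)
class DigitalPhantom:
    """Voxelized 2D scene: background plus inclusions.

    The grid spans lateral x in [-extent/2, extent/2] and depth z in
    [0, extent]; spacing is isotropic.  Default 38 x 38 mm at 0.15 mm,
    matching the clinical display extent with spacing well below the
    system's axial resolution.

    The background absorption carries a seeded multiplicative sub-resolution
    texture (microvascular/structural heterogeneity) of fractional standard
    deviation ``texture_sigma`` and correlation length ``texture_corr_mm``.
    The same spatial field scales the background at every wavelength — the
    heterogeneity is structural, so its optical contrast follows the bulk
    spectrum — which is what lets row-wise depth normalization transfer
    between wavelengths.  Set ``texture_sigma=0`` for an idealized
    homogeneous background.
    """

    extent_mm: tuple[float, float] = (38.0, 38.0)
    spacing_mm: float = 0.15
    background_optics: OpticalProperties = field(default_factory=_breast_optics_both)
    background_acoustics: AcousticProperties = field(default_factory=AcousticProperties)
    inclusions: tuple[Inclusion, ...] = ()
    skin_depth_mm: float | None = None
    medium: str = "breast"
    texture_sigma: float = 0.2
    texture_corr_mm: float = 0.3
    texture_seed: int = 0

    def __post_init__(self) -> None:
        if self.spacing_mm <= 0 or any(e <= 0 for e in self.extent_mm):
            raise ValueError("grid extent and spacing must be positive")
        half_x = self.extent_mm[0] / 2.0
        for inc in self.inclusions:
            rx, rz = inc.radii_mm
            x, z = inc.center_mm
            if inc.shape == "sphere":
                # spheres extend out of plane; in-plane footprint checked
                pass
            if abs(x) + rx > half_x or z - rz < 0 or z + rz > self.extent_mm[1]:
                raise ValueError(f"inclusion at {inc.center_mm} mm exceeds the grid")

    # -- grid geometry -----------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        """(n_depth, n_lateral) raster shape."""
        nz = int(round(self.extent_mm[1] / self.spacing_mm))
        nx = int(round(self.extent_mm[0] / self.spacing_mm))
        return nz, nx

    def axes_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """(z, x) pixel-center coordinates in mm."""
        nz, nx = self.shape
        z = (np.arange(nz) + 0.5) * self.spacing_mm
        x = (np.arange(nx) + 0.5) * self.spacing_mm - self.extent_mm[0] / 2.0
        return z, x

    def inclusion_mask(self, inc: Inclusion, shrink: float = 1.0) -> np.ndarray:
        """Boolean raster of one inclusion's in-plane cross-section.

        ``shrink`` scales the radii (<1 gives a conservative interior ROI).
        """
        z, x = self.axes_mm()
        zz, xx = np.meshgrid(z, x, indexing="ij")
        rx, rz = inc.radii_mm
        cx, cz = inc.center_mm
        return ((xx - cx) / (rx * shrink)) ** 2 + ((zz - cz) / (rz * shrink)) ** 2 <= 1.0

    def texture_field(self) -> np.ndarray:
        """Seeded unit-std, zero-mean correlated background heterogeneity."""
        from scipy import ndimage

        rng = np.random.default_rng(self.texture_seed)
        field_ = rng.standard_normal(self.shape)
        sig_px = self.texture_corr_mm / self.spacing_mm
        if sig_px > 0:
            field_ = ndimage.gaussian_filter(field_, sig_px)
        field_ -= field_.mean()
        std = field_.std()
        return field_ / std if std > 0 else field_

    def mu_a_map(self, wavelength_nm: float,
                 table: ChromophoreTable = HEMOGLOBIN_TABLE) -> np.ndarray:
        """Rasterized absorption coefficient map (cm^-1).

        The background value is modulated by the phantom's multiplicative
        heterogeneity texture (clipped to stay nonnegative); inclusion
        pixels take their own absorption, untextured.
        """
        nz, nx = self.shape
        mu_bg = self.background_optics.mu_a_at(wavelength_nm)
        if self.texture_sigma > 0 and mu_bg > 0:
            mu = mu_bg * np.clip(
                1.0 + self.texture_sigma * self.texture_field(), 0.0, None
            )
        else:
            mu = np.full((nz, nx), mu_bg)
        for inc in self.inclusions:
            mu[self.inclusion_mask(inc)] = inc.mu_a_at(wavelength_nm, table)
        return mu

    def grueneisen_map(self) -> np.ndarray:
        """Thermoacoustic efficiency map (constant by default)."""
        g = np.full(self.shape, self.background_optics.grueneisen)
        for inc in self.inclusions:
            if inc.optics is not None:
                g[self.inclusion_mask(inc)] = inc.optics.grueneisen
        return g


# -- canonical validation scenes ------------------------------------------


def make_two_tube_phantom(
    depth_mm: float = 10.0,
    diameter_mm: float = 2.4,
    so2_left: float = 1.0,
    so2_right: float = 0.5,
    hematocrit: float = 0.27,
    medium: str = "breast",
    separation_mm: float = 12.0,
    extent_mm: tuple[float, float] = (38.0, 38.0),
    spacing_mm: float = 0.15,
    skin_depth_mm: float | None = None,
) -> DigitalPhantom:
    """Two parallel blood-filled tubes at equal depth, symmetric about x=0.

    This is the bench validation scene: flowing bovine blood in thin tubes
    inside a breast-mimicking (PVCP) or aqueous (milky water) medium whose
    bulk optics replicate the average breast.  The canonical variants are
    2.4 mm tubes at 10 mm (oximetry sweep), 1.5 mm tubes at 13-32 mm
    (depth series) and 2.4 mm tubes at 20 mm (hematocrit series).
    """
    if not 5.0 <= depth_mm <= 35.0:
        raise ValueError("tube depth must lie in [5, 35] mm")
    if separation_mm <= diameter_mm:
        raise ValueError("tubes overlap: separation must exceed the diameter")
    if medium not in ("breast", "aqueous"):
        raise ValueError(f"unknown medium {medium!r}")
    acoustics = (
        AcousticProperties() if medium == "breast" else aqueous_background_acoustics()
    )
    half = separation_mm / 2.0
    tubes = tuple(
        Inclusion(
            shape="tube",
            center_mm=(x, depth_mm),
            size_mm=(diameter_mm,),
            blood=BloodState(so2=so2, hematocrit=hematocrit),
        )
        for x, so2 in ((-half, so2_left), (half, so2_right))
    )
    # phantom media (PVCP, milky water) are nearly homogeneous, unlike
    # tissue: only a trace of manufacturing heterogeneity
    return DigitalPhantom(
        extent_mm=extent_mm,
        spacing_mm=spacing_mm,
        background_acoustics=acoustics,
        inclusions=tubes,
        skin_depth_mm=skin_depth_mm,
        medium=medium,
        texture_sigma=0.02,
    )


def make_tumor_phantom(
    size_mm: float = 10.0,
    depth_mm: float = 20.0,
    contrast_fold: float | None = None,
    aspect: float = 0.7,
    extent_mm: tuple[float, float] = (38.0, 38.0),
    spacing_mm: float = 0.15,
) -> DigitalPhantom:
    """Elliptical tumor-like lesion in average breast background.

    Default absorption uses the reported malignant means (0.130 cm^-1 at
    757 nm, 0.154 cm^-1 at 1064 nm).  ``contrast_fold`` overrides both as a
    multiple of the breast background; the probe/laser design optimum is a
    ~10 mm lesion at ~20 mm depth.
    """
    if not 3.0 <= size_mm <= 20.0:
        raise ValueError("tumor size must lie in [3, 20] mm")
    if contrast_fold is None:
        mu = dict(TUMOR_MU_A)
    else:
        mu = {wl: contrast_fold * BREAST_MU_A[wl] for wl in BREAST_MU_A}
    tumor = Inclusion(
        shape="ellipse",
        center_mm=(0.0, depth_mm),
        size_mm=(size_mm, size_mm * aspect),
        optics=OpticalProperties(mu_a=mu, mu_s_prime=dict(BREAST_MU_S_PRIME)),
    )
    return DigitalPhantom(
        extent_mm=extent_mm, spacing_mm=spacing_mm, inclusions=(tumor,)
    )


# -- scene YAML I/O --------------------------------------------------------


def _optics_to_dict(o: OpticalProperties) -> dict:
    return {
        "mu_a": {float(k): float(v) for k, v in o.mu_a.items()},
        "mu_s_prime": {float(k): float(v) for k, v in o.mu_s_prime.items()},
        "grueneisen": float(o.grueneisen),
    }


def _optics_from_dict(d: dict) -> OpticalProperties:
    return OpticalProperties(
        mu_a={float(k): float(v) for k, v in d["mu_a"].items()},
        mu_s_prime={float(k): float(v) for k, v in d.get("mu_s_prime", {}).items()},
        grueneisen=float(d.get("grueneisen", 1.0)),
    )


def phantom_to_dict(ph: DigitalPhantom) -> dict:
    """Serializable scene description (units: mm, cm^-1)."""
    incs = []
    for inc in ph.inclusions:
        d: dict = {
            "shape": inc.shape,
            "center_mm": [float(c) for c in inc.center_mm],
            "size_mm": [float(s) for s in inc.size_mm],
        }
        if inc.blood is not None:
            d["blood"] = {"so2": float(inc.blood.so2),
                          "hematocrit": float(inc.blood.hematocrit)}
        else:
            d["optics"] = _optics_to_dict(inc.optics)  # type: ignore[arg-type]
        incs.append(d)
    return {
        "grid": {
            "extent_mm": [float(e) for e in ph.extent_mm],
            "spacing_mm": float(ph.spacing_mm),
        },
        "medium": ph.medium,
        "background": {
            "optics": _optics_to_dict(ph.background_optics),
            "acoustics": {
                "speed_of_sound": float(ph.background_acoustics.speed_of_sound),
                "alpha_us": float(ph.background_acoustics.alpha_us),
            },
        },
        "skin_depth_mm": None if ph.skin_depth_mm is None else float(ph.skin_depth_mm),
        "texture": {
            "sigma": float(ph.texture_sigma),
            "corr_mm": float(ph.texture_corr_mm),
            "seed": int(ph.texture_seed),
        },
        "inclusions": incs,
    }


def phantom_from_dict(d: dict) -> DigitalPhantom:
    incs = []
    for i in d.get("inclusions", []):
        blood = optics = None
        if "blood" in i:
            blood = BloodState(so2=float(i["blood"]["so2"]),
                               hematocrit=float(i["blood"]["hematocrit"]))
        else:
            optics = _optics_from_dict(i["optics"])
        incs.append(
            Inclusion(
                shape=i["shape"],
                center_mm=tuple(float(c) for c in i["center_mm"]),
                size_mm=tuple(float(s) for s in i["size_mm"]),
                blood=blood,
                optics=optics,
            )
        )
    bg = d["background"]
    ac = bg["acoustics"]
    skin = d.get("skin_depth_mm")
    tex = d.get("texture", {})
    return DigitalPhantom(
        texture_sigma=float(tex.get("sigma", 0.2)),
        texture_corr_mm=float(tex.get("corr_mm", 0.3)),
        texture_seed=int(tex.get("seed", 0)),
        extent_mm=tuple(float(e) for e in d["grid"]["extent_mm"]),
        spacing_mm=float(d["grid"]["spacing_mm"]),
        background_optics=_optics_from_dict(bg["optics"]),
        background_acoustics=AcousticProperties(
            speed_of_sound=float(ac["speed_of_sound"]),
            alpha_us=float(ac["alpha_us"]),
        ),
        inclusions=tuple(incs),
        skin_depth_mm=None if skin is None else float(skin),
        medium=d.get("medium", "breast"),
    )


def save_scene(ph: DigitalPhantom, path: str | Path) -> None:
    """Write a phantom to a YAML scene file."""
    Path(path).write_text(yaml.safe_dump(phantom_to_dict(ph), sort_keys=True))


def load_scene(path: str | Path) -> DigitalPhantom:
    """Read a phantom from a YAML scene file."""
    return phantom_from_dict(yaml.safe_load(Path(path).read_text()))
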