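"""Functional color rendering and dual-wavelength frame pairing.

[sO2] maps are displayed in a red/green palette anchored at the normal-
tissue oxygenation band: values below 85% render red (grading to magenta
at extreme hypoxia), values in the closed transparent band [85, 90]% show
no color so the grayscale anatomy stays visible, and values above 90%
render green (grading to cyan toward the arterial extreme).  [tHb] maps
use a yellow palette in which only the highest relative values are opaque.
Overlays are alpha-composited over the co-registered grayscale background;
in "combined" mode [sO2] color appears only where the [tHb] layer is
colored.  Dual-wavelength acquisition alternates 757/1064 nm pulses ~5 ms
apart at 10 frames per second, giving 5 co-registered pairs per second.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "PaletteSpec",
    "OverlayImage",
    "Frame",
    "FramePair",
    "classify_so2",
    "render_so2",
    "render_thb",
    "compose_overlay",
    "pair_frames",
    "save_png",
]

log = logging.getLogger(__name__)

_COLORS = {
    "red": (1.0, 0.0, 0.0),
    "magenta": (1.0, 0.0, 1.0),
    "green": (0.0, 0.8, 0.0),
    "cyan": (0.0, 0.9, 0.9),
    "yellow": (1.0, 0.9, 0.0),
}


@dataclass(frozen=True)
class PaletteSpec:
    """Display palette anchors (sO2 in percent).

    red_boundary / green_boundary delimit the transparent band (closed
    [85, 90] by convention); magenta_level and cyan_level are the extreme
    hypoxic/arterial limbs — qualitative conventions, configurable.
    opacity_ramp is the width (percent sO2) over which opacity ramps from 0
    at the band edge to 1.  thb_percentile sets the [tHb] display threshold
    ("only the highest relative values are colored").
    """

    red_boundary: float = 85.0
    green_boundary: float = 90.0
    magenta_level: float = 40.0
    cyan_level: float = 98.0
    opacity_ramp: float = 2.0
    thb_percentile: float = 90.0

    def __post_init__(self) -> None:
        if not 0 < self.red_boundary < self.green_boundary < 100:
            raise ValueError("boundaries must satisfy 0 < red < green < 100")
        if self.opacity_ramp <= 0:
            raise ValueError("opacity ramp must be positive")


@dataclass
class OverlayImage:
    """RGBA functional layer composited over a grayscale background."""

    rgba: np.ndarray
    gray: np.ndarray
    extent_mm: tuple[float, float]
    spacing_mm: float
    meta: dict = field(default_factory=dict)


@dataclass(frozen=True)
class Frame:
    """One tagged acquisition frame of the alternating-wavelength stream."""

    wavelength_nm: float
    timestamp_ms: float
    payload: object = None


@dataclass(frozen=True)
class FramePair:
    """Co-registered short/long wavelength frame pair."""

    frame757: Frame
    frame1064: Frame

    @property
    def interpulse_delay_ms(self) -> float:
        return abs(self.frame1064.timestamp_ms - self.frame757.timestamp_ms)


def classify_so2(value_percent: float, palette: PaletteSpec = PaletteSpec()) -> str:
    """Color class of one sO2 value: red/magenta/transparent/green/cyan.

    Below the red boundary the display is red, grading to magenta at
    extreme hypoxia; the closed band [red_boundary, green_boundary] is
    transparent; above it green, grading to cyan at the arterial extreme.
    """
    v = float(value_percent)
    if not 0.0 <= v <= 100.0:
        raise ValueError(f"sO2 must be in [0, 100] percent, got {v}")
    if v < palette.red_boundary:
        return "magenta" if v < palette.magenta_level else "red"
    if v <= palette.green_boundary:
        return "transparent"
    return "cyan" if v > palette.cyan_level else "green"


def _so2_rgba_scalar(v: float, palette: PaletteSpec) -> tuple[float, float, float, float]:
    cls = classify_so2(v, palette)
    if cls == "transparent":
        return (0.0, 0.0, 0.0, 0.0)
    if cls in ("red", "magenta"):
        # grade red -> magenta as v descends from the boundary to the extreme
        span = max(palette.red_boundary - palette.magenta_level, 1e-9)
        f = np.clip((palette.red_boundary - v) / span, 0.0, 1.0)
        rgb = tuple(
            (1 - f) * a + f * b for a, b in zip(_COLORS["red"], _COLORS["magenta"])
        )
        alpha = float(np.clip((palette.red_boundary - v) / palette.opacity_ramp, 0.0, 1.0))
    else:
        span = max(palette.cyan_level - palette.green_boundary, 1e-9)
        f = np.clip((v - palette.green_boundary) / span, 0.0, 1.0)
        rgb = tuple(
            (1 - f) * a + f * b for a, b in zip(_COLORS["green"], _COLORS["cyan"])
        )
        alpha = float(np.clip((v - palette.green_boundary) / palette.opacity_ramp, 0.0, 1.0))
    return (*rgb, alpha)


def render_so2(
    so2_percent: np.ndarray,
    palette: PaletteSpec = PaletteSpec(),
    valid: np.ndarray | None = None,
) -> np.ndarray:
    """RGBA layer (float in [0, 1]) for an sO2 map given in percent.

    NaN or invalid pixels are fully transparent, as is the [85, 90] band.
    """
    a = np.asarray(so2_percent, dtype=float)
    rgba = np.zeros(a.shape + (4,))
    finite = np.isfinite(a)
    if valid is not None:
        finite &= valid
    vals = np.clip(a[finite], 0.0, 100.0)
    if vals.size:
        mapped = np.array([_so2_rgba_scalar(v, palette) for v in vals])
        rgba[finite] = mapped
    return rgba


def render_thb(
    thb: np.ndarray, palette: PaletteSpec = PaletteSpec()
) -> np.ndarray:
    """Yellow RGBA layer showing only the highest relative [tHb] values.

    Pixels strictly above the ``thb_percentile`` of the map are colored
    with opacity ramping over the top decile; everything else (including a
    uniform or all-zero map) is fully transparent.
    """
    a = np.asarray(thb, dtype=float)
    rgba = np.zeros(a.shape + (4,))
    finite = np.isfinite(a)
    if not finite.any():
        return rgba
    thr = np.percentile(a[finite], palette.thb_percentile)
    top = np.percentile(a[finite], 100.0)
    hot = finite & (a > thr)
    if not hot.any():
        return rgba
    ramp = np.clip((a - thr) / max(top - thr, 1e-12), 0.0, 1.0)
    for i, cval in enumerate(_COLORS["yellow"]):
        rgba[..., i][hot] = cval
    rgba[..., 3][hot] = 0.3 + 0.7 * ramp[hot]
    return rgba


def _composite(base_rgb: np.ndarray, layer: np.ndarray) -> np.ndarray:
    alpha = layer[..., 3:4]
    return layer[..., :3] * alpha + base_rgb * (1.0 - alpha)


def compose_overlay(
    bmode_gray: np.ndarray,
    so2_layer: np.ndarray | None,
    thb_layer: np.ndarray | None,
    mode: str = "combined",
    extent_mm: tuple[float, float] = (38.0, 38.0),
    spacing_mm: float = 0.15,
) -> OverlayImage:
    """Alpha-composite functional layers over the grayscale background.

    mode "so2" or "thb" shows a single layer; "combined" shows [sO2] colors
    only on the support where the [tHb] layer is itself colored (so colored
    oxygenation readouts appear only where hemoglobin signal is strong).
    Wherever the resulting layer alpha is 0 the background is preserved
    bit-exactly.
    """
    gray = np.asarray(bmode_gray, dtype=float)
    layers = {"so2": so2_layer, "thb": thb_layer}
    for name, layer in layers.items():
        if layer is not None and layer.shape[:2] != gray.shape:
            raise ValueError(f"{name} layer grid does not match the background")
    if mode not in ("so2", "thb", "combined"):
        raise ValueError(f"unknown overlay mode {mode!r}")

    if mode == "so2":
        layer = so2_layer if so2_layer is not None else np.zeros(gray.shape + (4,))
    elif mode == "thb":
        layer = thb_layer if thb_layer is not None else np.zeros(gray.shape + (4,))
    else:
        layer = (so2_layer if so2_layer is not None else np.zeros(gray.shape + (4,))).copy()
        support = (
            thb_layer[..., 3] > 0
            if thb_layer is not None
            else np.zeros(gray.shape, dtype=bool)
        )
        layer[..., 3] = np.where(support, layer[..., 3], 0.0)

    base = np.repeat(gray[..., None], 3, axis=-1)
    rgb = _composite(base, layer)
    rgba = np.concatenate([rgb, np.ones(gray.shape + (1,))], axis=-1)
    return OverlayImage(
        rgba=rgba, gray=gray, extent_mm=extent_mm, spacing_mm=spacing_mm,
        meta={"mode": mode},
    )


def pair_frames(
    frames: list[Frame], delay_tolerance_ms: float = 10.0
) -> list[FramePair]:
    """Pair consecutive 757/1064 nm frames from an alternating stream.

    Frames of the two wavelengths arriving within the inter-pulse delay
    tolerance are paired (in either order); a frame whose partner is
    missing, or a repeated same-wavelength frame, is dropped with a log
    entry and the stream resynchronizes on the next frame.
    """
    pairs: list[FramePair] = []
    pending: Frame | None = None
    for fr in sorted(frames, key=lambda f: f.timestamp_ms):
        if fr.wavelength_nm not in (757.0, 1064.0):
            log.warning("pair_frames: dropping frame with wavelength %s", fr.wavelength_nm)
            continue
        if pending is None:
            pending = fr
            continue
        same = pending.wavelength_nm == fr.wavelength_nm
        late = fr.timestamp_ms - pending.timestamp_ms > delay_tolerance_ms
        if same or late:
            log.warning(
                "pair_frames: dropping unpaired %g nm frame at %g ms (%s)",
                pending.wavelength_nm, pending.timestamp_ms,
                "duplicate wavelength" if same else "partner timed out",
            )
            pending = fr
            continue
        if pending.wavelength_nm == 757.0:
            pairs.append(FramePair(frame757=pending, frame1064=fr))
        else:
            pairs.append(FramePair(frame757=fr, frame1064=pending))
        pending = None
    if pending is not None:
        log.warning(
            "pair_frames: dropping trailing unpaired %g nm frame",
            pending.wavelength_nm,
        )
    return pairs


def save_png(rgba: np.ndarray, path: str | Path) -> None:
    """Write a float RGBA (or grayscale) array in [0, 1] as an 8-bit PNG."""
    from PIL import Image

    arr = np.clip(np.asarray(rgba, dtype=float), 0.0, 1.0)
    if arr.ndim == 2:
        img = Image.fromarray((arr * 255).astype(np.uint8), mode="L")
    else:
        img = Image.fromarray((arr * 255).astype(np.uint8), mode="RGBA")
    img.save(str(path))
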