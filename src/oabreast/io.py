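"""Self-describing HDF5 containers for sinograms, images and maps.

Every container stores its sampling/grid metadata as HDF5 attributes so
any pipeline stage can be re-run from its inputs alone.  Free-form
provenance dictionaries are serialized as JSON in a single attribute.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .forward import Sinogram
from .funcmap import FunctionalMaps
from .recon import OAImage

__all__ = [
    "save_sinogram", "load_sinogram",
    "save_image", "load_image",
    "save_maps", "load_maps",
]


def _meta_dump(meta: dict) -> str:
    return json.dumps(meta, sort_keys=True, default=str)


def save_sinogram(sino: Sinogram, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("data", data=sino.data)
        f.create_dataset("element_x_mm", data=sino.element_x_mm)
        d.attrs["fs_MHz"] = sino.fs_mhz
        d.attrs["wavelength_nm"] = sino.wavelength_nm
        d.attrs["pulse_ns"] = sino.pulse_ns
        d.attrs["sos_mm_per_us"] = sino.speed_of_sound
        d.attrs["meta_json"] = _meta_dump(sino.meta)


def load_sinogram(path: str | Path) -> Sinogram:
    with h5py.File(path, "r") as f:
        d = f["data"]
        return Sinogram(
            data=d[()],
            fs_mhz=float(d.attrs["fs_MHz"]),
            wavelength_nm=float(d.attrs["wavelength_nm"]),
            element_x_mm=f["element_x_mm"][()],
            speed_of_sound=float(d.attrs["sos_mm_per_us"]),
            pulse_ns=float(d.attrs["pulse_ns"]),
            meta=json.loads(d.attrs["meta_json"]),
        )


def save_image(img: OAImage, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("image", data=img.data)
        d.attrs["extent_mm"] = img.extent_mm
        d.attrs["spacing_mm"] = img.spacing_mm
        d.attrs["wavelength_nm"] = -1.0 if img.wavelength_nm is None else img.wavelength_nm
        d.attrs["meta_json"] = _meta_dump(img.meta)


def load_image(path: str | Path) -> OAImage:
    with h5py.File(path, "r") as f:
        d = f["image"]
        wl = float(d.attrs["wavelength_nm"])
        return OAImage(
            data=d[()],
            extent_mm=tuple(d.attrs["extent_mm"]),
            spacing_mm=float(d.attrs["spacing_mm"]),
            wavelength_nm=None if wl < 0 else wl,
            meta=json.loads(d.attrs["meta_json"]),
        )


def save_maps(maps: FunctionalMaps, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("thb", data=maps.thb)
        f.create_dataset("so2", data=maps.so2)
        f.create_dataset("valid", data=maps.valid.astype(np.uint8))
        f.attrs["extent_mm"] = maps.extent_mm
        f.attrs["spacing_mm"] = maps.spacing_mm
        f.attrs["reference_stats_json"] = _meta_dump(maps.reference_stats)
        f.attrs["meta_json"] = _meta_dump(maps.meta)


def load_maps(path: str | Path) -> FunctionalMaps:
    with h5py.File(path, "r") as f:
        return FunctionalMaps(
            thb=f["thb"][()],
            so2=f["so2"][()],
            valid=f["valid"][()].astype(bool),
            extent_mm=tuple(f.attrs["extent_mm"]),
            spacing_mm=float(f.attrs["spacing_mm"]),
            reference_stats=json.loads(f.attrs["reference_stats_json"]),
            meta=json.loads(f.attrs["meta_json"]),
        )
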