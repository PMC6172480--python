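"""Shared fixtures: probe, canonical scenes, and cached full-chain runs.

The full dual-wavelength chain (simulate, condition, reconstruct, map) takes
a few seconds per scene, so the canonical runs are session-scoped and shared
between the unit tests and the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from oabreast import (
    ProbeModel,
    RunConfig,
    make_two_tube_phantom,
    run_pipeline,
)
from oabreast.forward import SimulationConfig, simulate_sinogram
from oabreast.funcmap import maps_from_image_pair
from oabreast.pipeline import tube_roi_stats
from oabreast.recon import ReconGrid, backproject
from oabreast.signalproc import condition


@pytest.fixture(scope="session")
def probe() -> ProbeModel:
    return ProbeModel()


@pytest.fixture(scope="session")
def two_tube_manifest() -> dict:
    """Full-chain run of the canonical depth-series scene.

    1.5 mm tubes at 20 mm depth in an aqueous medium with breast-average
    bulk optics; left tube sO2 = 100%, right tube sO2 = 50%, hematocrit
    27%, noise off.
    """
    phantom = make_two_tube_phantom(
        depth_mm=20.0, diameter_mm=1.5, so2_left=1.0, so2_right=0.5,
        hematocrit=0.27, medium="aqueous",
    )
    return run_pipeline(RunConfig(scene=phantom, noise=False, save_outputs=False))


@pytest.fixture(scope="session")
def so2_sweep_results() -> list[dict]:
    """Oximetry sweep: 2.4 mm tubes at 10 mm in breast-mimicking medium.

    Six sweep points: the left tube steps 100 -> 95.5 -> 91% while the
    right tube steps 50 -> 70 -> 85%.
    """
    results = []
    for left, right in [(1.00, 0.50), (0.955, 0.70), (0.91, 0.85)]:
        phantom = make_two_tube_phantom(
            depth_mm=10.0, diameter_mm=2.4, so2_left=left, so2_right=right,
            hematocrit=0.27, medium="breast",
        )
        manifest = run_pipeline(
            RunConfig(scene=phantom, noise=False, save_outputs=False)
        )
        results.append(manifest)
    return results


@pytest.fixture(scope="session")
def hematocrit_series(probe) -> list[dict]:
    """Hematocrit dilution series with detection noise on (fixed seed).

    2.4 mm tubes at 20 mm depth, sO2 100%/50%, hematocrit 41/27/4%.
    Returns per-level ROI stats plus a background-noise tHb SNR.
    """
    out = []
    for ht in (0.41, 0.27, 0.04):
        phantom = make_two_tube_phantom(
            depth_mm=20.0, diameter_mm=2.4, so2_left=1.0, so2_right=0.5,
            hematocrit=ht, medium="breast",
        )
        cfg = SimulationConfig(noise=True, seed=7)
        grid = ReconGrid.for_phantom(phantom)
        images = {}
        for wl in (757.0, 1064.0):
            sino = condition(simulate_sinogram(phantom, probe, wl, cfg), probe)
            images[wl] = backproject(sino, grid, probe)
        maps = maps_from_image_pair(images[757.0], images[1064.0])
        stats = tube_roi_stats(phantom, maps)
        z, x = images[757.0].axes_mm()
        background = (
            (z[:, None] >= 5.0) & (z[:, None] <= 15.0)
            & (np.abs(x[None, :]) > 14.0)
        )
        noise_std = float(maps.thb[background].std())
        out.append({
            "hematocrit": ht,
            "stats": stats,
            "thb_snr": [s["mean_thb"] / noise_std for s in stats],
        })
    return out


def color_family(color_class: str) -> str:
    """Collapse the palette limbs onto their display family."""
    return {
        "red": "red", "magenta": "red",
        "green": "green", "cyan": "green",
        "transparent": "transparent",
    }[color_class]
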