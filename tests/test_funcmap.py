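"""Segmentation, depth normalization, spectral unmixing, statistical maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oabreast.chromophores import HEMOGLOBIN_TABLE, ChromophoreTable
from oabreast.funcmap import (
    SegmentationMask,
    normalize_depth,
    segment_bright,
    statistical_map,
    unmix,
)
from oabreast.recon import OAImage


def _image(data, wavelength=None, spacing=0.15):
    nz, nx = data.shape
    return OAImage(data=data, extent_mm=(nx * spacing, nz * spacing),
                   spacing_mm=spacing, wavelength_nm=wavelength)


def _grid(nz=120, nx=120, spacing=0.15):
    z = (np.arange(nz) + 0.5) * spacing
    x = (np.arange(nx) + 0.5) * spacing - nx * spacing / 2
    return np.meshgrid(z, x, indexing="ij")


# -- segmentation ----------------------------------------------------------

def test_uniform_image_yields_empty_mask():
    img = _image(np.full((50, 60), 1.3))
    assert not segment_bright(img).mask.any()


def test_bright_tubes_are_segmented():
    zz, xx = _grid()
    rng = np.random.default_rng(0)
    data = 1.0 + 0.05 * rng.standard_normal(zz.shape)
    truth = np.zeros(zz.shape, dtype=bool)
    for cx in (-4.0, 4.0):
        disk = (xx - cx) ** 2 + (zz - 9.0) ** 2 <= 1.2**2
        data[disk] = 8.0
        truth |= disk
    mask = segment_bright(_image(data), threshold_sigma=3.0).mask
    assert mask[truth].mean() >= 0.90
    assert mask[~truth].mean() < 0.05


def test_infinite_threshold_gives_empty_mask():
    rng = np.random.default_rng(1)
    img = _image(1.0 + 0.1 * rng.standard_normal((40, 40)))
    assert not segment_bright(img, threshold_sigma=np.inf).mask.any()


# -- depth normalization ---------------------------------------------------

def test_pure_exponential_background_flattens_exactly():
    zz, _ = _grid()
    img = _image(np.exp(-0.103 * zz))
    out = normalize_depth(img)
    assert np.allclose(out.data, 1.0, atol=1e-6)


def test_uniform_image_unchanged():
    img = _image(np.full((64, 64), 4.2))
    assert np.allclose(normalize_depth(img).data, 1.0, atol=1e-12)


def test_vessel_contrast_preserved_across_depths():
    """A vessel of fixed local contrast k over the decaying background
    normalizes to the same value at every depth from 13 to 32 mm."""
    zz, xx = _grid(nz=240, nx=160)
    k = 6.0
    for depth in (13.0, 19.0, 26.0, 32.0):
        background = np.exp(-0.103 * zz)
        vessel = (xx**2 + (zz - depth) ** 2) <= 1.0
        data = background * (1.0 + (k - 1.0) * vessel)
        out = normalize_depth(_image(data), SegmentationMask(mask=vessel))
        assert out.data[vessel].mean() == pytest.approx(k, rel=0.10)


def test_fully_masked_rows_interpolated():
    zz, _ = _grid(nz=80, nx=40)
    img = _image(np.exp(-0.1 * zz))
    mask = np.zeros(img.data.shape, dtype=bool)
    mask[30:35, :] = True  # whole rows masked out
    out = normalize_depth(img, SegmentationMask(mask=mask), dilate_px=0)
    assert np.allclose(out.data, 1.0, atol=5e-3)


def test_row_reference_curve_mode():
    zz, _ = _grid(nz=60, nx=30)
    img = _image(3.0 * np.exp(-0.2 * zz))
    ref = 3.0 * np.exp(-0.2 * (np.arange(60) + 0.5) * 0.15)
    out = normalize_depth(img, row_reference=ref)
    assert np.allclose(out.data, 1.0, atol=1e-12)
    with pytest.raises(ValueError):
        normalize_depth(img, row_reference=ref[:-1])
    with pytest.raises(ValueError):
        normalize_depth(img, row_reference=-ref)


# -- spectral unmixing -----------------------------------------------------

def _mu_pair(so2, thb, table=HEMOGLOBIN_TABLE):
    e_hb_1, e_ox_1 = table.extinction(757.0)
    e_hb_2, e_ox_2 = table.extinction(1064.0)
    mu1 = thb * (so2 * e_ox_1 + (1 - so2) * e_hb_1)
    mu2 = thb * (so2 * e_ox_2 + (1 - so2) * e_hb_2)
    return mu1, mu2


@pytest.mark.parametrize("so2_true", [0.0, 0.5, 1.0])
def test_unmix_recovers_known_states(so2_true):
    mu1, mu2 = _mu_pair(so2_true, 1.0)
    maps = unmix(_image(np.full((8, 8), mu1), 757.0),
                 _image(np.full((8, 8), mu2), 1064.0))
    assert np.allclose(maps.so2, so2_true, atol=1e-12)
    assert np.allclose(maps.thb, 1.0, rtol=1e-12)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(seed=st.integers(0, 2**31 - 1))
def test_unmix_is_exact_inverse_on_random_fields(seed):
    rng = np.random.default_rng(seed)
    so2 = rng.uniform(0.0, 1.0, (12, 12))
    thb = rng.uniform(0.2, 3.0, (12, 12))
    mu1, mu2 = _mu_pair(so2, thb)
    maps = unmix(_image(mu1, 757.0), _image(mu2, 1064.0))
    assert np.allclose(maps.so2, so2, atol=1e-10)
    assert np.allclose(maps.thb, thb, rtol=1e-10)


def test_unmix_low_signal_marked_undefined():
    mu1, mu2 = _mu_pair(0.8, 1.0)
    a = np.full((10, 10), mu1)
    b = np.full((10, 10), mu2)
    a[0, 0] = b[0, 0] = 1e-9  # essentially no hemoglobin signal
    maps = unmix(_image(a, 757.0), _image(b, 1064.0))
    assert not maps.valid[0, 0]
    assert np.isnan(maps.so2[0, 0])
    assert maps.valid[5, 5]


def test_unmix_rejects_singular_table_and_grid_mismatch():
    degenerate = ChromophoreTable(
        wavelengths_nm=(757.0, 1064.0), eps_hb=(2.0, 4.0), eps_hbo2=(1.0, 2.0)
    )
    img1 = _image(np.ones((4, 4)), 757.0)
    img2 = _image(np.ones((4, 4)), 1064.0)
    with pytest.raises(ValueError):
        unmix(img1, img2, table=degenerate)
    with pytest.raises(ValueError):
        unmix(img1, _image(np.ones((5, 5)), 1064.0))


# -- statistical mapping ---------------------------------------------------

def test_statistical_map_identities():
    rng = np.random.default_rng(3)
    values = rng.normal(5.0, 2.0, (30, 30))
    ref = np.zeros(values.shape, dtype=bool)
    ref[5:15, 5:15] = True
    zmap, mean, std = statistical_map(values, ref)
    assert zmap[ref].mean() == pytest.approx(0.0, abs=1e-12)
    assert zmap[ref].std() == pytest.approx(1.0, rel=1e-12)
    probe_val = mean + 2.0 * std
    assert (probe_val - mean) / std == pytest.approx(2.0)


def test_statistical_map_degenerate_references():
    values = np.ones((10, 10))
    with pytest.raises(ValueError):
        statistical_map(values, np.zeros((10, 10), dtype=bool))
    with pytest.raises(ValueError):
        statistical_map(values, np.ones((10, 10), dtype=bool))
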