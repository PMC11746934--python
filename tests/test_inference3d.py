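"""Volume assembly, background blackening, white-matter segmentation, MIPs."""

import numpy as np
import pytest
from scipy import ndimage

from scstain import phantom as ph
from scstain.autodiff import Tensor
from scstain.inference3d import (StainVolume, blacken_background, gray, mip,
                                 stain_slice, stain_volume, white_matter_mask)


class OracleTranslator:
    """Stand-in translator: maps an equalized SC map through the phantom's
    inverse tone curve using a reference slice's latent myelin.  Lets the
    inference plumbing be tested without training."""

    def __init__(self, slc):
        self.slc = slc

    def stain(self, xq):
        m = np.clip(self.slc.myelin[:xq.shape[0], :xq.shape[1]], 0, 1)
        return ph.ps_colormap(m)

    def __call__(self, x):
        arr = np.asarray(x)
        out = self.stain(arr if arr.ndim == 2 else arr[0, 0])
        return Tensor(out.transpose(2, 0, 1)[None])


class RankTranslator:
    """Monotone-inverting translator: bright input -> dark stain.  Used
    where the output must genuinely depend on the input."""

    def stain(self, xq):
        m = np.clip(xq, 0, 1)
        return ph.ps_colormap(m)

    def __call__(self, x):
        arr = np.asarray(x)
        out = self.stain(arr if arr.ndim == 2 else arr[0, 0])
        return Tensor(out.transpose(2, 0, 1)[None])


@pytest.fixture(scope="module")
def oracle_ds(noise_free_slice_module):
    G = OracleTranslator(noise_free_slice_module)
    return stain_slice(G, noise_free_slice_module.sc, mode="wsi")


@pytest.fixture(scope="module")
def noise_free_slice_module():
    return ph.make_cortex_phantom(128, 128, seed=0,
                                  params=ph.PhantomParams(speckle_var=0.0))


class TestStainSlice:
    def test_stain_polarity(self, noise_free_slice_module, oracle_ds):
        s = noise_free_slice_module
        lum = gray(oracle_ds)
        assert lum[s.labels == ph.WM].mean() < lum[np.isin(s.labels, [1, 2, 3, 4])].mean()
        # opposite polarity to the SC input
        assert (s.sc[s.labels == ph.WM].mean()
                > s.sc[np.isin(s.labels, [1, 2, 3, 4])].mean())

    def test_modes_agree_for_translator_without_global_state(self,
                                                             noise_free_slice_module):
        G = RankTranslator()
        a = stain_slice(G, noise_free_slice_module.sc, mode="wsi")
        b = stain_slice(G, noise_free_slice_module.sc, mode="patches", patch=64)
        interior = (slice(8, -8), slice(8, -8))
        assert np.abs(a[interior] - b[interior]).mean() < 0.05

    def test_equalization_idempotent(self, noise_free_slice_module):
        from scstain.biophys import hist_equalize

        G = RankTranslator()
        x = noise_free_slice_module.sc
        once = stain_slice(G, x, mode="wsi")
        pre_equalized = hist_equalize(x)
        twice = stain_slice(G, pre_equalized, mode="wsi")
        assert np.abs(once - twice).mean() < 0.02

    def test_rejects_rgb_input(self):
        with pytest.raises(ValueError):
            stain_slice(RankTranslator(), np.zeros((32, 32, 3)))


class TestBlackenBackground:
    def test_blackens_true_background(self, noise_free_slice_module, oracle_ds):
        out = blacken_background(oracle_ds)
        bg = noise_free_slice_module.labels == ph.BACKGROUND
        black = np.all(out == 0, axis=-1)
        assert black[bg].mean() >= 0.99

    def test_foreground_bit_identical(self, oracle_ds):
        out = blacken_background(oracle_ds)
        kept = ~np.all(out == 0, axis=-1)
        np.testing.assert_array_equal(out[kept], oracle_ds[kept])

    def test_all_tissue_image_unchanged(self):
        rng = np.random.default_rng(0)
        img = np.clip(rng.normal(0.35, 0.05, size=(64, 64, 3)), 0, 1)
        np.testing.assert_array_equal(blacken_background(img), img)

    def test_bright_corner_is_background(self):
        rng = np.random.default_rng(0)
        img = np.clip(rng.normal(0.35, 0.05, size=(64, 64, 3)), 0, 1)
        img[:16, :16] = 0.98
        out = blacken_background(img)
        assert np.all(out[:12, :12] == 0)
        tissue = np.ones((64, 64), bool)
        tissue[:16, :16] = False
        np.testing.assert_array_equal(out[tissue], img[tissue])


class TestWhiteMatterMask:
    def test_two_gaussian_valley(self, rng):
        # bimodal grayscale: modes at 0.2 and 0.8 -> threshold in between
        n = 128
        vals = np.concatenate([rng.normal(0.2, 0.05, n * n // 2),
                               rng.normal(0.8, 0.05, n * n // 2)])
        img = np.clip(vals.reshape(n, n), 0, 1)[..., None] * np.ones(3)
        mask = white_matter_mask(img, foreground=np.ones((n, n), bool),
                                 smooth_radius=0)
        dark = img[..., 0] < 0.4
        bright = img[..., 0] > 0.6
        assert mask.mask[dark].mean() > 0.99
        assert mask.mask[bright].mean() < 0.01

    def test_phantom_wm_dice(self, noise_free_slice_module, oracle_ds):
        s = noise_free_slice_module
        mask = white_matter_mask(oracle_ds).mask
        truth = s.labels == ph.WM
        dice = 2 * (mask & truth).sum() / (mask.sum() + truth.sum())
        assert dice >= 0.9

    def test_wm_volume_fraction_matches_generator(self, noise_free_slice_module,
                                                  oracle_ds):
        s = noise_free_slice_module
        mask = white_matter_mask(oracle_ds).mask
        fg = s.labels != ph.BACKGROUND
        got = mask.sum() / fg.sum()
        want = (s.labels == ph.WM).sum() / fg.sum()
        assert abs(got - want) / want < 0.10

    def test_unimodal_histogram_raises(self):
        flat = np.full((64, 64, 3), 0.5)
        with pytest.raises(ValueError):
            white_matter_mask(flat, foreground=np.ones((64, 64), bool))


class TestVolumeAndMip:
    def test_volume_preserves_order_and_provenance(self, noise_free_slice_module):
        G = RankTranslator()
        vol = stain_volume(G, [noise_free_slice_module.sc] * 3,
                           provenance={"checkpoint_hash": "abc"})
        assert vol.as_array().shape == (3, 128, 128, 3)
        assert vol.provenance["inter_slice_registration"] == "none"
        assert vol.provenance["checkpoint_hash"] == "abc"

    def test_single_slice_mip_is_identity(self, oracle_ds):
        vol = StainVolume(slices=[oracle_ds])
        np.testing.assert_array_equal(mip(vol, "z"), oracle_ds)

    def test_constant_volume_constant_mip(self):
        const = np.full((16, 16, 3), 0.3)
        vol = StainVolume(slices=[const] * 4)
        for ax in ("z", "y", "x"):
            assert np.allclose(mip(vol, ax), 0.3)

    def test_invalid_axis_rejected(self, oracle_ds):
        with pytest.raises(ValueError):
            mip(StainVolume(slices=[oracle_ds]), "w")

    def test_bright_vessel_connected_in_z_mip(self):
        # vessels are near-white in the stain render; a z-continuous vessel
        # must appear as one connected bright curve in the z-MIP
        vol_slices = ph.make_volume(5, 128, 128, seed=3,
                                    params=ph.PhantomParams(speckle_var=0.0))
        G = OracleTranslator(vol_slices[0])
        rendered = []
        for s in vol_slices:
            rendered.append(ph.ps_colormap(s.myelin))
        vol = StainVolume(slices=rendered)
        proj = gray(mip(vol, "z"))
        tissue_any = np.stack([s.labels != 0 for s in vol_slices]).all(axis=0)
        bright = (proj > 0.93) & tissue_any
        lab, n = ndimage.label(bright)
        sizes = np.bincount(lab.ravel())[1:]
        assert n >= 1 and sizes.max() >= 20

    def test_empty_volume_rejected(self):
        with pytest.raises(ValueError):
            StainVolume(slices=[])
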