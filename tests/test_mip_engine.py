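import logging

import numpy as np
import pytest

from petmip.lesion_features import segment_lesions
from petmip.mip_engine import (CANVAS_SHAPE, MIPImage, ablate_tumours,
                               lesion_mask_mip, lesion_mip, make_mip,
                               normalize, project, remove_brain, to_canvas)
from petmip.phantom import PhantomSpec, generate_phantom
from petmip.volume_io import PETVolume


def vol_from(arr, spacing=(4.0, 4.0, 4.0)):
    return PETVolume(suv=np.asarray(arr, dtype=np.float32), spacing_mm=spacing)


@pytest.fixture(scope="module")
def phantom():
    spec = PhantomSpec(seed=23)
    vol, truth = generate_phantom(spec)
    seg = segment_lesions(vol, physiological_mask=truth.physiological_mask)
    return vol, truth, seg


class TestProject:
    def test_constant_volume(self):
        p = project(vol_from(np.full((5, 6, 7), 2.5)), "coronal")
        assert p.shape == (5, 7)
        assert (p == 2.5).all()

    def test_single_hot_voxel_lands_at_z_transverse_index(self):
        arr = np.ones((6, 7, 8))
        arr[2, 3, 4] = 10.0
        cor = project(vol_from(arr), "coronal")     # collapses y
        sag = project(vol_from(arr), "sagittal")    # collapses x
        assert cor[2, 4] == 10.0 and (cor == 10).sum() == 1
        assert sag[2, 3] == 10.0 and (sag == 10).sum() == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        arr = rng.random((8, 9, 10)) * 10
        vol = vol_from(arr)
        for view, axis in (("coronal", 1), ("sagittal", 2)):
            got = project(vol, view)
            expected = np.zeros_like(got)
            for z in range(arr.shape[0]):
                for t in range(got.shape[1]):
                    ray = arr[z, :, t] if view == "coronal" else arr[z, t, :]
                    expected[z, t] = max(ray)
            np.testing.assert_allclose(got, expected)

    def test_unknown_view_rejected(self):
        with pytest.raises(ValueError):
            project(vol_from(np.ones((4, 4, 4))), "axial")


class TestToCanvas:
    def test_identity_when_already_canvas_at_4mm(self):
        rng = np.random.default_rng(0)
        proj = rng.random(CANVAS_SHAPE).astype(np.float32)
        img = to_canvas(proj, (4.0, 4.0))
        np.testing.assert_array_equal(img.pixels, proj)

    def test_output_shape_always_canvas(self):
        img = to_canvas(np.ones((50, 40), dtype=np.float32), (4.0, 4.0))
        assert img.pixels.shape == CANVAS_SHAPE

    def test_2mm_source_halves_extent_and_pads_with_zeros(self):
        proj = np.ones((100, 80), dtype=np.float32)      # 200 x 160 mm at 2 mm
        img = to_canvas(proj, (2.0, 2.0))
        rows = np.flatnonzero(img.pixels.any(axis=1))
        cols = np.flatnonzero(img.pixels.any(axis=0))
        assert len(rows) == 50 and len(cols) == 40
        assert img.pixels.sum() == pytest.approx(img.pixels[np.ix_(rows, cols)].sum())

    def test_centred_placement(self):
        img = to_canvas(np.ones((51, 41), dtype=np.float32), (4.0, 4.0))
        rows = np.flatnonzero(img.pixels.any(axis=1))
        assert rows[0] == (275 - 51) // 2

    def test_oversized_projection_reports_crop(self):
        with pytest.raises(ValueError, match="crop"):
            to_canvas(np.ones((300, 100), dtype=np.float32), (4.0, 4.0))


class TestNormalize:
    def test_cap_maps_to_one_and_truncates(self):
        pix = np.zeros(CANVAS_SHAPE, dtype=np.float32)
        pix[0, 0], pix[0, 1], pix[0, 2] = 40.0, 50.0, 20.0
        img = normalize(MIPImage(pixels=pix, view="coronal"))
        assert img.pixels[0, 0] == 1.0
        assert img.pixels[0, 1] == 1.0     # values above the cap are truncated
        assert img.pixels[0, 2] == 0.5
        assert img.normalized

    def test_idempotent(self):
        img = normalize(MIPImage(pixels=np.full(CANVAS_SHAPE, 10.0), view="coronal"))
        again = normalize(img)
        np.testing.assert_array_equal(img.pixels, again.pixels)

    def test_bad_cap_rejected(self):
        img = MIPImage(pixels=np.zeros(CANVAS_SHAPE), view="coronal")
        with pytest.raises(ValueError):
            normalize(img, suv_cap=0)


class TestLesionMIPs:
    def test_no_lesions_all_zero(self):
        vol, truth = generate_phantom(PhantomSpec(n_lesions=0, seed=2))
        seg = segment_lesions(vol, physiological_mask=truth.physiological_mask)
        assert lesion_mip(vol, seg, "coronal").pixels.max() == 0.0
        assert lesion_mask_mip(vol, seg, "coronal").pixels.max() == 0.0

    def test_intensities_retained_and_bladder_absent(self):
        spec = PhantomSpec(seed=6, lesion_suv_range=(8.0, 8.0))
        vol, truth = generate_phantom(spec)
        seg = segment_lesions(vol, physiological_mask=truth.physiological_mask)
        img = lesion_mip(vol, seg, "coronal")
        nz = img.pixels[img.pixels > 0]
        assert nz.max() == pytest.approx(8.0 / 40.0)     # no bladder (45) leaking in
        assert img.pixels.max() < 45.0 / 40.0

    def test_mask_is_binary_and_covers_lesion_support(self, phantom):
        vol, truth, seg = phantom
        lm = lesion_mip(vol, seg, "sagittal")
        mk = lesion_mask_mip(vol, seg, "sagittal")
        assert set(np.unique(mk.pixels)) <= {0.0, 1.0}
        np.testing.assert_array_equal(mk.pixels > 0, lm.pixels > 0)

    def test_lesion_mip_bounded_by_full_mip(self, phantom):
        vol, truth, seg = phantom
        full = make_mip(vol, "coronal")
        lm = lesion_mip(vol, seg, "coronal")
        assert (lm.pixels <= full.pixels + 1e-6).all()


class TestRemoveBrain:
    def test_brain_zeroed_lesions_untouched(self, phantom):
        vol, truth, seg = phantom
        out = remove_brain(vol, seg.label_map)
        assert (out.suv[truth.brain_mask] == 0).all()
        lesioned = truth.label_map > 0
        np.testing.assert_array_equal(out.suv[lesioned], vol.suv[lesioned])

    def test_headless_volume_unchanged(self, caplog):
        arr = np.ones((20, 12, 12), dtype=np.float32)
        vol = vol_from(arr)
        with caplog.at_level(logging.INFO, logger="petmip.mip_engine"):
            out = remove_brain(vol)
        np.testing.assert_array_equal(out.suv, vol.suv)
        assert any("no brain" in r.message for r in caplog.records)

    def test_lesion_overlapping_brain_region_is_flagged(self, caplog):
        vol, truth = generate_phantom(PhantomSpec(n_lesions=0, seed=2))
        suv = vol.suv.copy()
        lesion_map = np.zeros_like(truth.label_map)
        zs, ys, xs = np.nonzero(truth.brain_mask)
        i = len(zs) // 2
        lesion_map[zs[i], ys[i], xs[i]] = 1           # a lesion inside the brain blob
        suv[zs[i], ys[i], xs[i]] = 12.0
        vol2 = vol_from(suv)
        with caplog.at_level(logging.WARNING, logger="petmip.mip_engine"):
            out = remove_brain(vol2, lesion_map)
        assert any("truncation risk" in r.message for r in caplog.records)
        assert (out.suv[truth.brain_mask] == 0).all()


class TestAblateTumours:
    def build(self, body_vals, lesion_vals):
        pix = np.zeros(CANVAS_SHAPE, dtype=np.float32)
        mask = np.zeros(CANVAS_SHAPE, dtype=np.float32)
        for i, v in enumerate(body_vals):
            pix[10, i] = v
        for i, v in enumerate(lesion_vals):
            pix[20, i] = v
            mask[20, i] = 1.0
        mip = MIPImage(pixels=pix / 1.0, view="coronal", normalized=True)
        mk = MIPImage(pixels=mask, view="coronal", variant="lesion_mask", normalized=True)
        return mip, mk

    def test_lesion_pixels_become_mean_body_intensity(self):
        mip, mk = self.build([0.025, 0.025, 0.05], [0.2, 0.25])
        out = ablate_tumours(mip, mk)
        fill = (0.025 + 0.025 + 0.05) / 3
        assert out.pixels[20, 0] == pytest.approx(fill, rel=1e-5)
        assert out.pixels[20, 1] == pytest.approx(fill, rel=1e-5)
        assert out.pixels[10, 0] == pytest.approx(0.025)

    def test_empty_mask_is_identity(self):
        mip, _ = self.build([0.1, 0.2], [])
        empty = MIPImage(pixels=np.zeros(CANVAS_SHAPE), view="coronal",
                         variant="lesion_mask", normalized=True)
        out = ablate_tumours(mip, empty)
        np.testing.assert_array_equal(out.pixels, mip.pixels)

    def test_idempotent(self):
        mip, mk = self.build([0.1, 0.3, 0.2], [0.8, 0.9])
        once = ablate_tumours(mip, mk)
        twice = ablate_tumours(once, mk)
        np.testing.assert_allclose(once.pixels, twice.pixels, rtol=1e-6)

    def test_ablated_max_not_above_body_max(self, phantom):
        vol, truth, seg = phantom
        mip = make_mip(vol, "coronal")
        mk = lesion_mask_mip(vol, seg, "coronal")
        out = ablate_tumours(mip, mk)
        body = (mip.pixels > 0) & (mk.pixels == 0)
        assert out.pixels[mk.pixels > 0].max() <= mip.pixels[body].max() + 1e-6

    def test_full_mask_rejected(self):
        pix = np.ones(CANVAS_SHAPE, dtype=np.float32) * 0.5
        mip = MIPImage(pixels=pix, view="coronal", normalized=True)
        mk = MIPImage(pixels=np.ones(CANVAS_SHAPE), view="coronal",
                      variant="lesion_mask", normalized=True)
        with pytest.raises(ValueError, match="reference"):
            ablate_tumours(mip, mk)

    def test_unnormalized_mip_rejected(self):
        mip = MIPImage(pixels=np.full(CANVAS_SHAPE, 5.0), view="coronal")
        mk = MIPImage(pixels=np.zeros(CANVAS_SHAPE), view="coronal",
                      variant="lesion_mask", normalized=True)
        with pytest.raises(ValueError, match="normalized"):
            ablate_tumours(mip, mk)
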