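import numpy as np
import pytest
from dataclasses import replace

from afmi.channels import ChannelTable, default_channel_table
from afmi.phantom import (
    PhantomSpec,
    PatientStack,
    generate_clean_stack,
    generate_patient,
    vignette_field,
)
from afmi.preprocess import (
    ChannelCorruptionError,
    FlatFieldFitError,
    PreprocessConfig,
    PreprocessError,
    StitchRegistrationError,
    correct_field,
    preprocess_stack,
    repair_bad_pixels,
    stitch_tiles,
)


def _stack_from(array, mask=None, table=None):
    array = np.asarray(array, dtype=float)
    if table is None:
        table = default_channel_table()
        if array.shape[0] != table.n_channels:
            # pad planes by repetition to match the 59-channel table
            array = np.repeat(array, table.n_channels, axis=0)[: table.n_channels]
    if mask is None:
        mask = np.ones(array.shape[1:], dtype=int)
    return PatientStack("T", array, mask, channel_table=table)


def _single_channel_table():
    from afmi.channels import ChannelDefinition

    return ChannelTable((ChannelDefinition(1, 340.0, 5.0, 420.0, 460.0),))


class TestRepair:
    def test_single_zero_pixel_replaced_by_neighbor_median(self):
        plane = np.full((1, 9, 9), 100.0)
        plane[0, 4, 4] = 0.0
        stack = _stack_from(plane, table=_single_channel_table())
        repaired, report = repair_bad_pixels(stack, PreprocessConfig())
        assert repaired.stack[0, 4, 4] == 100.0
        assert len(report) == 1
        assert report.entries[0][1:] == (4, 4, "dead")

    def test_no_defects_identity(self):
        stack = _stack_from(np.full((1, 8, 8), 55.0), table=_single_channel_table())
        repaired, report = repair_bad_pixels(stack, PreprocessConfig())
        assert np.array_equal(repaired.stack, stack.stack)
        assert len(report) == 0

    def test_idempotent(self):
        plane = np.full((1, 16, 16), 200.0)
        plane[0, 3, 3] = 0.0
        plane[0, 10, 12] = 70000.0
        stack = _stack_from(plane, table=_single_channel_table())
        once, _ = repair_bad_pixels(stack, PreprocessConfig())
        twice, report2 = repair_bad_pixels(once, PreprocessConfig())
        assert np.array_equal(once.stack, twice.stack)
        assert len(report2) == 0

    def test_detection_matches_truth_on_noise_free_phantom(self):
        spec = PhantomSpec(
            n_patients=1,
            image_shape=(96, 96),
            patient_scale_sd=0.0,
            patient_offset_sd=0.0,
            vignette_strength=0.0,
            background_level=40.0,
            dead_pixel_fraction=0.01,
            saturated_pixel_fraction=0.005,
            poisson=False,
            texture_sd=0.0,
            seed=0,
        )
        stack = generate_patient(spec, np.random.SeedSequence(2), "P01")
        _, report = repair_bad_pixels(stack, PreprocessConfig())
        truth_dead = {tuple(rc) for rc in stack.truth.dead_pixels}
        truth_sat = {tuple(rc) for rc in stack.truth.saturated_pixels}
        detected_dead = {
            (r, c) for ch, r, c, kind in report.entries if kind == "dead" and ch == 0
        }
        detected_sat = {
            (r, c) for ch, r, c, kind in report.entries if kind == "saturated" and ch == 0
        }
        assert detected_dead == truth_dead
        assert detected_sat == truth_sat

    def test_corrupted_channel_rejected(self):
        plane = np.zeros((1, 10, 10))
        plane[0, :3] = 100.0  # 70% zeros
        stack = _stack_from(plane, table=_single_channel_table())
        with pytest.raises(ChannelCorruptionError):
            repair_bad_pixels(stack, PreprocessConfig())

    def test_mad_outlier_mode(self):
        rng = np.random.default_rng(0)
        plane = rng.normal(1000, 5, size=(1, 32, 32))
        plane[0, 5, 5] = 5000.0
        stack = _stack_from(plane, table=_single_channel_table())
        cfg = PreprocessConfig(badpixel_detect="mad_outlier", mad_k=8)
        repaired, report = repair_bad_pixels(stack, cfg)
        assert (0, 5, 5, "saturated") in report.entries
        assert abs(repaired.stack[0, 5, 5] - 1000) < 50


class TestBackground:
    def test_exact_constant_background_removed(self):
        table = _single_channel_table()
        mask = np.zeros((20, 20), dtype=int)
        mask[5:15, 5:15] = 1
        clean = np.zeros((1, 20, 20))
        clean[0, mask == 1] = 500.0
        b = 37.0
        stack = PatientStack("T", clean + b, mask, channel_table=table)
        cfg = PreprocessConfig(flatfield_mode="none")
        out = correct_field(stack, cfg)
        assert np.allclose(out.stack[0, mask == 1], 500.0)
        assert np.allclose(out.stack[0, mask == 0], 0.0)

    def test_negative_input_rejected(self):
        stack = _stack_from(np.full((1, 8, 8), -1.0), table=_single_channel_table())
        with pytest.raises(PreprocessError):
            correct_field(stack, PreprocessConfig())


class TestFlatField:
    def test_provided_field_exact_inverse(self):
        table = _single_channel_table()
        mask = np.zeros((40, 40), dtype=int)
        mask[8:32, 8:32] = 1
        clean = np.zeros((1, 40, 40))
        clean[0, mask == 1] = 800.0
        V = vignette_field((40, 40), 0.4)
        stack = PatientStack("T", clean * V, mask, channel_table=table)
        cfg = PreprocessConfig(flatfield_mode="provided_field")
        out = correct_field(stack, cfg, illumination=V)
        assert np.allclose(out.stack[0, mask == 1], 800.0, rtol=1e-10)

    def test_polynomial_fit_reduces_cv(self):
        table = _single_channel_table()
        V = vignette_field((64, 64), 0.3)
        flat = 1000.0 * V[None]
        stack = PatientStack(
            "T", flat, np.ones((64, 64), dtype=int), channel_table=table
        )
        cv_before = flat.std() / flat.mean()
        assert cv_before >= 0.05
        cfg = PreprocessConfig(background_mode="none", flatfield_mode="polynomial_fit")
        out = correct_field(stack, cfg)
        corrected = out.stack[0]
        assert corrected.std() / corrected.mean() < 0.02

    def test_nonpositive_provided_field_rejected(self):
        table = _single_channel_table()
        stack = _stack_from(np.full((1, 8, 8), 10.0), table=table)
        cfg = PreprocessConfig(flatfield_mode="provided_field")
        with pytest.raises(FlatFieldFitError):
            correct_field(stack, cfg, illumination=np.zeros((8, 8)))


class TestFullChain:
    def test_rmse_reduced_by_half(self):
        # default camera degradations, patient affine effects off
        spec = PhantomSpec(
            n_patients=1,
            image_shape=(256, 256),
            patient_scale_sd=0.0,
            patient_offset_sd=0.0,
            seed=0,
        )
        stack = generate_patient(spec, np.random.SeedSequence(7), "P01")
        corrected, _ = preprocess_stack(stack)
        clean = stack.truth.clean
        sel = stack.mask > 0
        rmse_in = np.sqrt(np.mean((stack.stack[:, sel] - clean[:, sel]) ** 2, axis=1))
        rmse_out = np.sqrt(
            np.mean((corrected.stack[:, sel] - clean[:, sel]) ** 2, axis=1)
        )
        assert np.mean(rmse_out) <= 0.5 * np.mean(rmse_in)


class TestStitch:
    @staticmethod
    def _textured_patient():
        spec = PhantomSpec(
            n_patients=1,
            image_shape=(128, 128),
            patient_scale_sd=0.0,
            patient_offset_sd=0.0,
            vignette_strength=0.0,
            background_level=0.0,
            dead_pixel_fraction=0.0,
            saturated_pixel_fraction=0.0,
            poisson=False,
            texture_sd=0.3,
            texture_scale_px=2.0,  # fine structure for phase correlation
            seed=0,
        )
        return generate_patient(spec, np.random.SeedSequence(21), "P01")

    def test_single_tile_identity(self):
        stack = self._textured_patient()
        assert stitch_tiles([stack]) is stack

    def test_two_tile_shift_recovery_and_reconstruction(self):
        stack = self._textured_patient()
        left = PatientStack(
            "P01", stack.stack[:, :, :72].copy(), stack.mask[:, :72].copy(),
            channel_table=stack.channel_table,
        )
        right = PatientStack(
            "P01", stack.stack[:, :, 40:].copy(), stack.mask[:, 40:].copy(),
            channel_table=stack.channel_table,
        )
        # true origin of right tile is col 40; nominal is off by 3 px
        stitched = stitch_tiles(
            [left, right], origins=[(0, 0), (0, 43)], overlap_px=32
        )
        assert stitched.shape == stack.shape
        assert np.max(np.abs(stitched.stack - stack.stack)) < 1e-9
        assert np.array_equal(stitched.mask, stack.mask)

    def test_empty_input_rejected(self):
        with pytest.raises(PreprocessError):
            stitch_tiles([])

    def test_small_overlap_rejected(self):
        stack = self._textured_patient()
        with pytest.raises(PreprocessError):
            stitch_tiles([stack, stack], overlap_px=4)

    def test_excessive_shift_rejected(self, monkeypatch):
        stack = self._textured_patient()
        left = PatientStack(
            "P01", stack.stack[:, :, :72], stack.mask[:, :72],
            channel_table=stack.channel_table,
        )
        right = PatientStack(
            "P01", stack.stack[:, :, 40:], stack.mask[:, 40:],
            channel_table=stack.channel_table,
        )
        import afmi.preprocess as pp

        monkeypatch.setattr(pp, "_register_pair", lambda ref, mov: (0, 200))
        with pytest.raises(StitchRegistrationError):
            stitch_tiles([left, right], origins=[(0, 0), (0, 40)], overlap_px=32)


class TestConfigValidation:
    def test_bad_percentile(self):
        with pytest.raises(PreprocessError):
            PreprocessConfig(background_percentile=60)

    def test_bad_degree(self):
        with pytest.raises(PreprocessError):
            PreprocessConfig(poly_degree=7)

    def test_bad_mode(self):
        with pytest.raises(PreprocessError):
            PreprocessConfig(flatfield_mode="magic")


class TestDenoise:
    def test_anscombe_smoothing_reduces_noise(self):
        rng = np.random.default_rng(0)
        table = _single_channel_table()
        plane = rng.poisson(400.0, size=(1, 64, 64)).astype(float)
        stack = PatientStack(
            "T", plane, np.ones((64, 64), dtype=int), channel_table=table
        )
        cfg = PreprocessConfig(
            background_mode="none", flatfield_mode="none", denoise=True,
            denoise_sigma=1.5,
        )
        out = correct_field(stack, cfg)
        assert out.stack[0].std() < 0.6 * plane[0].std()
        assert out.stack[0].mean() == pytest.approx(400.0, rel=0.02)
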