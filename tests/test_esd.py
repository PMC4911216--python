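import numpy as np
import pytest
import scipy.ndimage as ndi

from cortexmaps import esd, synth
from cortexmaps.esd import ImagingStack


def make_stack(frames, direction=0.0, eye="L"):
    data = np.asarray(frames)[None, ...]
    return ImagingStack(data, np.array([direction]), np.array([eye]))


class TestAlign:
    def test_planted_shift_recovered(self, rng):
        base = ndi.gaussian_filter(rng.normal(size=(64, 64)), 3)
        shifted = ndi.shift(base, (3, -2), order=0, mode="constant",
                            cval=base.mean())
        st = make_stack(np.stack([base, shifted]))
        out = esd.align_frames(st, base, max_shift=5)
        # realigned frame matches the reference except refilled border pixels
        diff = np.abs(out.data[0, 1] - base)
        assert np.median(diff) == 0.0

    def test_reference_aligned_to_itself_unchanged(self, rng):
        base = rng.normal(size=(32, 32))
        out = esd.align_frames(make_stack(base[None]), base, max_shift=4)
        assert np.array_equal(out.data[0, 0], base)

    def test_noisy_planted_shifts_mostly_recovered(self, rng):
        base = ndi.gaussian_filter(rng.normal(size=(64, 64)), 3)
        base = (base - base.mean()) / base.std()
        hits = 0
        for _ in range(20):
            dr, dc = rng.integers(-5, 6, 2)
            fr = np.roll(base, (dr, dc), axis=(0, 1))
            fr = fr + rng.normal(0, 0.2, fr.shape)  # SNR 5
            out = esd.align_frames(make_stack(fr[None]), base, max_shift=8)
            back = out.data[0, 0]
            # the aligned frame should equal fr rolled back (up to fill-in)
            expect = ndi.shift(fr, (-dr, -dc), order=0, mode="constant",
                               cval=fr.mean())
            hits += np.median(np.abs(back - expect)) == 0.0
        assert hits >= 18

    def test_flat_frame_warns_and_keeps_zero_shift(self, rng):
        flat = np.zeros((16, 16))
        with pytest.warns(UserWarning):
            out = esd.align_frames(make_stack(flat[None]), rng.normal(size=(16, 16)))
        assert np.array_equal(out.data[0, 0], flat)


class TestAverageConditions:
    def _full_stack(self, value_fn, trials=1, frames=4, hw=8):
        data, dirs, eyes = [], [], []
        for d in synth.DIRECTIONS:
            for e in ("L", "R"):
                for t in range(trials):
                    data.append(np.full((frames, hw, hw), value_fn(d, e, t)))
                    dirs.append(d)
                    eyes.append(e)
        return ImagingStack(np.array(data), np.array(dirs), np.array(eyes))

    def test_opposite_trials_cancel(self):
        st = self._full_stack(lambda d, e, t: (1.0 if d < 180 else -1.0), trials=1)
        c = esd.average_conditions(st)
        assert np.allclose(c.data, 0.0)

    def test_sixteen_directions_pool_to_eight_orientations(self):
        st = self._full_stack(lambda d, e, t: d)
        c = esd.average_conditions(st)
        assert c.data.shape[:2] == (8, 2)
        # pooled mean of d and d+180 = d + 90
        assert np.allclose(c.data[:, 0, 0, 0, 0], c.orientations + 90.0)

    def test_averaging_identical_trials_idempotent(self):
        st = self._full_stack(lambda d, e, t: np.cos(np.deg2rad(d)), trials=3)
        c1 = esd.average_conditions(st)
        st_single = self._full_stack(lambda d, e, t: np.cos(np.deg2rad(d)), trials=1)
        c2 = esd.average_conditions(st_single)
        assert np.allclose(c1.data, c2.data)

    def test_missing_condition_listed(self):
        st = self._full_stack(lambda d, e, t: 1.0)
        keep = st.eyes == "L"
        broken = ImagingStack(st.data[keep], st.directions[keep], st.eyes[keep])
        with pytest.raises(ValueError, match="R"):
            esd.average_conditions(broken)


class TestPreprocess:
    def _cstack(self, frame):
        data = np.tile(frame, (8, 2, 2, 1, 1))
        return esd.ConditionStack(data)

    def test_constant_frame_maps_to_exact_zero(self):
        out = esd.preprocess_frames(self._cstack(np.full((40, 40), 7.3)))
        assert np.allclose(out.data, 0.0, atol=1e-12)

    def test_low_frequency_sinusoid_strongly_attenuated(self):
        # wavelength 384 px >> 6*hp_sigma: Gaussian transfer leaves < 10%
        x = np.arange(384)
        frame = np.sin(2 * np.pi * x / 384)[None, :] * np.ones((48, 384))
        out = esd.preprocess_frames(self._cstack(frame))
        interior = out.data[0, 0, 0, 10:-10, 60:-60]
        assert np.abs(interior).max() < 0.1 * 1.0

    def test_sign_reversal_makes_dark_spot_positive(self):
        frame = np.zeros((64, 64))
        frame[30:34, 30:34] = -1.0  # activity: reflectance decrease
        out = esd.preprocess_frames(self._cstack(frame))
        assert out.data[0, 0, 0, 31, 31] > 0

    def test_sigma_ordering_enforced(self):
        with pytest.raises(ValueError):
            esd.preprocess_frames(self._cstack(np.zeros((16, 16))),
                                  hp_sigma=2.0, lp_sigma=5.0)


class TestCompose:
    def _cstack(self, R):
        # R: (8, 2) scalars -> (8, 2, F, H, W)
        data = np.asarray(R)[..., None, None, None] * np.ones((1, 1, 3, 4, 4))
        return esd.ConditionStack(data)

    def test_equal_responses_cancel_exactly(self):
        op_r, op_i, od = esd.compose_feature_stacks(self._cstack(np.ones((8, 2))))
        assert np.allclose(op_r, 0.0, atol=1e-12)
        assert np.allclose(op_i, 0.0, atol=1e-12)
        assert np.allclose(od, 0.0, atol=1e-12)

    def test_single_horizontal_response(self):
        R = np.zeros((8, 2))
        R[0, :] = 1.0  # θ = 0° both eyes
        op_r, op_i, od = esd.compose_feature_stacks(self._cstack(R))
        assert np.allclose(op_r, 1.0)
        assert np.allclose(op_i, 0.0, atol=1e-12)

    def test_left_only_responses_give_negative_od(self):
        R = np.zeros((8, 2))
        R[:, 0] = 1.0
        _, _, od = esd.compose_feature_stacks(self._cstack(R))
        assert np.all(od < 0)

    def test_monocular_mode_uses_single_eye(self):
        R = np.zeros((8, 2))
        R[0, 0] = 2.0  # only left eye responds at 0°
        op_r, _, _ = esd.compose_feature_stacks(self._cstack(R), mode="left")
        assert np.allclose(op_r, 2.0)
        op_r_b, _, _ = esd.compose_feature_stacks(self._cstack(R))
        assert np.allclose(op_r_b, 1.0)


class TestUnmix:
    def test_single_source_recovered_up_to_sign(self, rng):
        s = ndi.gaussian_filter(rng.normal(size=(64, 64)), 4)
        stack = np.stack([c * s for c in rng.normal(size=(20,))])
        with pytest.warns(UserWarning, match="rank-deficient"):
            out = esd.esd_unmix(stack)
        assert esd.complex_correlation(out.sources[0], s) > 1 - 1e-9

    def test_whitened_sources_have_identity_covariance(self, rng):
        stack = rng.normal(size=(12, 32, 32))
        out = esd.esd_unmix(stack)
        X = out.sources.reshape(len(out.sources), -1)
        C = X @ X.T / X.shape[1]
        assert np.abs(C - np.eye(len(C))).max() < 1e-8

    def test_coefficients_reconstruct_centered_input(self, rng):
        stack = rng.normal(size=(10, 24, 24))
        out = esd.esd_unmix(stack)
        rec = np.einsum("fk,kij->fij", out.coefficients, out.sources)
        cen = stack - stack.mean(axis=(1, 2), keepdims=True)
        assert np.allclose(rec, cen, atol=1e-10)

    def test_planted_sources_recovered(self):
        rng = np.random.default_rng(42)
        s1 = ndi.gaussian_filter(rng.normal(size=(256, 256)), 10)
        s2 = ndi.gaussian_filter(rng.normal(size=(256, 256)), 5)
        s1, s2 = s1 / s1.std(), s2 / s2.std()
        M = rng.normal(size=(50, 2))
        clean = np.einsum("fk,kij->fij", M, np.stack([s1, s2]))
        with pytest.warns(UserWarning, match="rank-deficient"):
            out = esd.esd_unmix(clean)
        r_clean = [max(esd.complex_correlation(src, s) for src in out.sources)
                   for s in (s1, s2)]
        assert min(r_clean) > 0.99
        noisy = clean + rng.normal(0, 0.1 * clean.std(), clean.shape)
        out_n = esd.esd_unmix(noisy)
        r_noisy = [max(esd.complex_correlation(src, s) for src in out_n.sources)
                   for s in (s1, s2)]
        assert min(r_noisy) > 0.95

    def test_linearity_of_coefficient_source_products(self, rng):
        stack = rng.normal(size=(8, 16, 16))
        a = esd.esd_unmix(stack)
        b = esd.esd_unmix(3.0 * stack)
        rec_a = np.einsum("fk,kij->fij", a.coefficients, a.sources)
        rec_b = np.einsum("fk,kij->fij", b.coefficients, b.sources)
        assert np.allclose(rec_b, 3.0 * rec_a, atol=1e-9)

    def test_shift_larger_than_image_rejected(self, rng):
        with pytest.raises(ValueError):
            esd.esd_unmix(rng.normal(size=(5, 8, 8)), shift=(8, 8))


class TestSelection:
    def test_planted_ramp_time_course_selected(self, rng):
        n, F = 6, 50
        sources = ndi.gaussian_filter(rng.normal(size=(n, 48, 48)), (0, 3, 3))
        coeff = rng.normal(0, 0.05, (F, n))
        coeff[:, 4] += esd.response_template(F) * 3.0
        ss = esd.SourceSet(sources=sources, coefficients=coeff,
                           eigenvalues=np.ones(n))
        esd.extract_feature_map(ss, final_lp_sigma=2.0)
        assert ss.selected == 4

    def test_flat_coefficients_raise_advisory(self, rng):
        ss = esd.SourceSet(sources=rng.normal(size=(3, 16, 16)),
                           coefficients=np.zeros((50, 3)),
                           eigenvalues=np.ones(3))
        with pytest.raises(esd.SourceSelectionError):
            esd.extract_feature_map(ss)

    def test_manual_override_bypasses_threshold(self, rng):
        ss = esd.SourceSet(sources=rng.normal(size=(3, 16, 16)),
                           coefficients=rng.normal(size=(50, 3)) * 1e-3,
                           eigenvalues=np.ones(3))
        esd.extract_feature_map(ss, selection=1)
        assert ss.selected == 1


class TestRoundTrip:
    def test_noiseless_stack_recovers_planted_maps(self, parametric_truth):
        rec = synth.StackRecipe(trials_per_condition=1, vessel_count=0,
                                vessel_amplitude=0.0, drift_amplitude=0.0,
                                noise_sigma=0.0, include_blank=False)
        stack = synth.synth_stack(parametric_truth, rec, seed=5)
        c = esd.preprocess_frames(esd.average_conditions(stack))
        with pytest.warns(UserWarning, match="rank-deficient"):
            op, od = esd.extract_maps_esd(c)
        gt_op = esd.pipeline_filter_reference(parametric_truth.op.field)
        assert esd.complex_correlation(op.field, gt_op) > 0.99
        bop, _ = esd.vector_average_baseline(c)
        bf = ndi.gaussian_filter(bop.field.real, 12, mode="nearest") \
            + 1j * ndi.gaussian_filter(bop.field.imag, 12, mode="nearest")
        # without artifacts both estimators see the same planted source
        assert esd.complex_correlation(bf, op.field) > 0.9

    def test_od_sign_convention_not_flipped(self):
        # right-eye-dominant regions must come out positive (signed, not |r|)
        truth = synth.synth_maps("parametric", seed=8, size=192, wavelength=44.0)
        rec = synth.StackRecipe(trials_per_condition=1, vessel_count=0,
                                vessel_amplitude=0.0, drift_amplitude=0.0,
                                noise_sigma=0.0, include_blank=False)
        stack = synth.synth_stack(truth, rec, seed=6)
        c = esd.preprocess_frames(esd.average_conditions(stack))
        with pytest.warns(UserWarning, match="rank-deficient"):
            _, od = esd.extract_maps_esd(c)
        gt = esd.pipeline_filter_reference(np.tanh(1.5 * truth.od.field))
        r = np.corrcoef(od.field.ravel(), gt.ravel())[0, 1]
        assert r > 0.99

    def test_doubling_gain_doubles_stimulus_locked_amplitude(self, parametric_truth):
        base = dict(trials_per_condition=1, vessel_count=0, vessel_amplitude=0.0,
                    drift_amplitude=0.0, noise_sigma=0.0, include_blank=False)
        s1 = synth.synth_stack(parametric_truth, synth.StackRecipe(**base), seed=2)
        s2 = synth.synth_stack(parametric_truth,
                               synth.StackRecipe(gain=0.02, **base), seed=2)
        d1 = 1.0 - s1.data[0, 30:35].mean(axis=0)
        d2 = 1.0 - s2.data[0, 30:35].mean(axis=0)
        assert np.allclose(d2, 2.0 * d1, atol=1e-6)
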