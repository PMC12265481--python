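import numpy as np
import pytest
from numpy.fft import fft2, fftfreq, ifft2
from scipy.ndimage import gaussian_filter

from sio.bossa_sim import (
    Hyperparameters,
    PsdModel,
    criterion,
    criterion_gradient,
    estimate_hyperparameters,
    reconstruct,
)
from sio.forward_model import (
    IlluminationModel,
    OpticalModel,
    ShiftTrajectory,
    StackOperator,
    TwoLayerObject,
)
from sio.stack import FrameStack


def _small_instance(seed=2, n=4, cam=16):
    rng = np.random.default_rng(seed)
    optical = OpticalModel()
    illum = IlluminationModel(contrast_infocus=0.8, frames_per_block=1)
    q = optical.oversampling_factor
    obj_shape = (cam * q, cam * q)
    obj = TwoLayerObject(rng.random(obj_shape), rng.random(obj_shape))
    shifts = ShiftTrajectory(rng.uniform(-2, 2, (n, 2)))
    orient = np.tile([45.0, -45.0], n // 2)
    stack = FrameStack(rng.random((n, cam, cam)), orientations=orient)
    hyper = Hyperparameters(
        0.01, PsdModel(1.0, 30.0, 3.0), PsdModel(1.0, 10.0, 3.0), lam=0.3
    )
    return obj, stack, shifts, optical, illum, hyper


class TestCriterion:
    def test_zero_object_zero_data_is_zero(self):
        obj, stack, shifts, optical, illum, hyper = _small_instance()
        zero = TwoLayerObject(np.zeros(obj.shape), np.zeros(obj.shape))
        stack.frames = np.zeros_like(stack.frames)
        assert criterion(zero, stack, shifts, optical, illum, hyper) == 0.0

    def test_consistent_data_with_tiny_prior_is_tiny(self):
        obj, stack, shifts, optical, illum, hyper = _small_instance()
        op = StackOperator(
            obj.shape, optical, illum, shifts.shifts,
            orientations=stack.orientations, phases=[0.0] * len(stack),
        )
        stack.frames = op.forward_stack(obj)
        hyper = Hyperparameters(
            1.0, PsdModel(1e12, 1e3, 1.0), PsdModel(1e12, 1e3, 1.0), lam=1e-30
        )
        J = criterion(obj, stack, shifts, optical, illum, hyper)
        assert J <= 1e-12

    def test_matches_naive_evaluation(self):
        """Frame-by-frame residual sums plus an explicit FFT penalty."""
        obj, stack, shifts, optical, illum, hyper = _small_instance()
        J = criterion(obj, stack, shifts, optical, illum, hyper)
        op = StackOperator(
            obj.shape, optical, illum, shifts.shifts,
            orientations=stack.orientations, phases=[0.0] * len(stack),
        )
        npix = obj.shape[0] * obj.shape[1]
        J_naive = 0.0
        for j in range(len(stack)):
            r = stack.frames[j] - op.forward_frame(obj, j)
            for row in r:
                for v in row:
                    J_naive += 0.5 * v * v / hyper.noise_variance
        fr = np.hypot(
            fftfreq(obj.shape[0], d=optical.object_pixel_scale)[:, None],
            fftfreq(obj.shape[1], d=optical.object_pixel_scale)[None, :],
        )
        for layer, model in ((obj.o0, hyper.s_o0), (obj.od, hyper.s_od)):
            S = np.maximum(model(fr), model.k * 1e-9) * npix
            J_naive += 0.5 * hyper.lam * np.sum(np.abs(fft2(layer)) ** 2 / S)
        assert J == pytest.approx(J_naive, rel=1e-10)

    def test_zero_noise_variance_rejected(self):
        with pytest.raises(ValueError):
            Hyperparameters(0.0, PsdModel(1, 1, 1), PsdModel(1, 1, 1))


class TestGradient:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_finite_differences(self, seed):
        obj, stack, shifts, optical, illum, hyper = _small_instance(seed=seed)
        g = criterion_gradient(obj, stack, shifts, optical, illum, hyper)
        rng = np.random.default_rng(seed + 100)
        eps = 1e-6
        for _ in range(10):
            layer = rng.integers(0, 2)
            i, j = rng.integers(0, obj.shape[0], 2)
            probe = TwoLayerObject(obj.o0.copy(), obj.od.copy())
            arr = probe.o0 if layer == 0 else probe.od
            arr[i, j] += eps
            Jp = criterion(probe, stack, shifts, optical, illum, hyper)
            arr[i, j] -= 2 * eps
            Jm = criterion(probe, stack, shifts, optical, illum, hyper)
            fd = (Jp - Jm) / (2 * eps)
            an = (g.o0 if layer == 0 else g.od)[i, j]
            assert abs(fd - an) <= 1e-5 * max(abs(fd), 1.0)

    def test_regularization_gradient_closed_form(self):
        """With residuals exactly zero, the gradient reduces to
        lam * Npix * IFFT(O / S) per layer."""
        obj, stack, shifts, optical, illum, hyper = _small_instance(seed=7)
        op = StackOperator(
            obj.shape, optical, illum, shifts.shifts,
            orientations=stack.orientations, phases=[0.0] * len(stack),
        )
        stack.frames = op.forward_stack(obj)
        g = criterion_gradient(obj, stack, shifts, optical, illum, hyper)
        npix = obj.shape[0] * obj.shape[1]
        fr = np.hypot(
            fftfreq(obj.shape[0], d=optical.object_pixel_scale)[:, None],
            fftfreq(obj.shape[1], d=optical.object_pixel_scale)[None, :],
        )
        for grad, layer, model in ((g.o0, obj.o0, hyper.s_o0), (g.od, obj.od, hyper.s_od)):
            S = np.maximum(model(fr), model.k * 1e-9) * npix
            expected = hyper.lam * npix * np.real(ifft2(fft2(layer) / S))
            assert np.abs(grad - expected).max() < 1e-8 * max(np.abs(expected).max(), 1.0)

    def test_stationary_at_noise_free_minimum(self):
        obj, stack, shifts, optical, illum, _ = _small_instance(seed=8)
        op = StackOperator(
            obj.shape, optical, illum, shifts.shifts,
            orientations=stack.orientations, phases=[0.0] * len(stack),
        )
        stack.frames = op.forward_stack(obj)
        hyper = Hyperparameters(
            1.0, PsdModel(1e15, 1e4, 1.0), PsdModel(1e15, 1e4, 1.0), lam=1e-30
        )
        g = criterion_gradient(obj, stack, shifts, optical, illum, hyper)
        assert np.abs(g.o0).max() <= 1e-8
        assert np.abs(g.od).max() <= 1e-8


class TestHyperparameters:
    def test_white_noise_variance_recovered(self):
        """Plateau of the periodogram above the cutoff gives sigma^2."""
        optical = OpticalModel()
        v = 2.5
        errors = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            stack = FrameStack(rng.normal(0, np.sqrt(v), (10, 64, 64)))
            hyper = estimate_hyperparameters(stack, optical)
            errors.append(hyper.noise_variance / v - 1.0)
        assert np.abs(errors).max() < 0.05

    def test_noise_free_stack_has_negligible_variance(self):
        optical = OpticalModel()
        illum = IlluminationModel(frames_per_block=1)
        rng = np.random.default_rng(0)
        cam = 32
        obj_shape = (cam * 2, cam * 2)
        obj = TwoLayerObject(rng.random(obj_shape), np.zeros(obj_shape))
        shifts = ShiftTrajectory(rng.uniform(-1, 1, (10, 2)))
        op = StackOperator(
            obj_shape, optical, illum, shifts.shifts,
            orientations=[45.0] * 10, phases=[0.0] * 10,
        )
        stack = FrameStack(op.forward_stack(obj), orientations=np.full(10, 45.0))
        hyper = estimate_hyperparameters(stack, optical)
        assert hyper.noise_variance <= 1e-6 * stack.frames.var()

    def test_power_law_exponent_recovered(self):
        """Known power-law object + known noise: fitted p within 20%."""
        optical = OpticalModel()
        n = 128
        p_true, f0_true = 3.0, 30.0
        rng = np.random.default_rng(5)
        fr = np.hypot(
            fftfreq(n, d=optical.pixel_scale)[:, None],
            fftfreq(n, d=optical.pixel_scale)[None, :],
        )
        S = 1.0 / (1.0 + (fr / f0_true) ** p_true)
        obj = np.real(ifft2(np.sqrt(S * n * n) * fft2(rng.standard_normal((n, n)))))
        obj *= 100.0 / obj.std()
        frames = obj[None] + rng.normal(0, 1.0, (12, n, n))
        hyper = estimate_hyperparameters(FrameStack(frames), optical)
        assert hyper.s_o0.p == pytest.approx(p_true, rel=0.2)
        assert hyper.s_od.f0 < hyper.s_o0.f0  # background prior is smoother

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            estimate_hyperparameters(FrameStack(np.zeros((3, 16, 16))), OpticalModel())


class TestReconstruct:
    def test_identity_limit_recovers_single_layer(self):
        """q=1, no shifts, no fringes, near-delta PSF, noise-free: the
        in-focus layer reproduces a band-limited truth to < 1% RMS."""
        optical = OpticalModel(
            pupil_diameter_mm=6.7 * 1.45, pixel_scale=1 / 403.0, oversampling_factor=1
        )
        illum = IlluminationModel(contrast_infocus=0.0, frames_per_block=1)
        rng = np.random.default_rng(3)
        cam = 32
        truth = np.clip(gaussian_filter(rng.random((cam, cam)), 1.5), 0, None)
        fr = np.hypot(
            fftfreq(cam, d=optical.pixel_scale)[:, None],
            fftfreq(cam, d=optical.pixel_scale)[None, :],
        )
        truth = np.real(ifft2(fft2(truth) * (fr <= optical.cutoff_cpd())))
        truth = np.clip(truth, 0, None)
        truth /= truth.mean()
        obj = TwoLayerObject(truth, np.zeros_like(truth))
        shifts = ShiftTrajectory(np.zeros((8, 2)))
        op = StackOperator(
            (cam, cam), optical, illum, shifts.shifts,
            orientations=[0.0] * 8, phases=[0.0] * 8,
        )
        stack = FrameStack(op.forward_stack(obj), orientations=np.zeros(8))
        hyper = Hyperparameters(
            1e-6, PsdModel(1.0, 50.0, 2.0), PsdModel(1.0, 10.0, 2.0), lam=1e-6
        )
        res = reconstruct(
            stack, shifts, optical, illum, hyper=hyper, max_iter=400, tol=1e-15
        )
        err = np.sqrt(np.mean((res.object.o0 - truth) ** 2) / np.mean(truth**2))
        assert err < 0.01

    def test_unbalanced_orientations_rejected(self):
        obj, stack, shifts, optical, illum, hyper = _small_instance(n=4)
        stack.orientations = np.array([45.0, 45.0, 45.0, -45.0])
        with pytest.raises(ValueError):
            reconstruct(stack, shifts, optical, illum, hyper=hyper, max_iter=2)

    def test_deterministic(self):
        obj, stack, shifts, optical, illum, hyper = _small_instance(seed=9)
        kw = dict(hyper=hyper, max_iter=8, tol=1e-12)
        a = reconstruct(stack, shifts, optical, illum, **kw)
        b = reconstruct(stack, shifts, optical, illum, **kw)
        assert np.array_equal(a.object.o0, b.object.o0)
        assert np.array_equal(a.object.od, b.object.od)

    def test_criterion_trace_monotone_and_positive(self, twopoint_recon):
        res = twopoint_recon["result"]
        trace = np.array(res.criterion_trace)
        assert len(trace) > 5
        assert np.all(np.diff(trace) <= 1e-9 * np.abs(trace[:-1]))
        assert res.object.o0.min() >= 0
        assert res.object.od.min() >= 0

    def test_two_point_resolution_gain(self, twopoint_recon):
        """The pair is unresolved in the wide-field average but split into
        two distinct maxima in the reconstructed in-focus layer."""
        from scipy.signal import find_peaks

        cam = twopoint_recon["cam"]
        q = twopoint_recon["optical"].oversampling_factor
        wf = twopoint_recon["widefield"]
        o0 = twopoint_recon["result"].object.o0
        prof_wf = wf[cam // 2, cam // 2 - 6 : cam // 2 + 7]
        peaks_wf, _ = find_peaks(prof_wf, prominence=0.05 * np.ptp(prof_wf))
        c = o0.shape[0] // 2
        prof_sio = o0[c, c - 10 : c + 11]
        peaks_sio, _ = find_peaks(prof_sio, prominence=0.2 * prof_sio.max())
        assert len(peaks_wf) <= 1
        assert len(peaks_sio) == 2
        # the two maxima sit at the true separation within one object pixel
        sep = abs(peaks_sio[1] - peaks_sio[0])
        assert sep == pytest.approx(twopoint_recon["sep_obj_px"], abs=1.5)

    def test_layer_separation(self, twopoint_recon):
        """The in-focus estimate correlates with the in-focus truth and not
        with the scattering background."""
        truth = twopoint_recon["truth"]
        o0 = twopoint_recon["result"].object.o0

        def corr(a, b):
            a = a - a.mean()
            b = b - b.mean()
            return float(np.sum(a * b) / np.sqrt(np.sum(a * a) * np.sum(b * b)))

        assert corr(o0, truth.o0) > 0.9
        assert abs(corr(o0, truth.od)) < 0.2

    def test_probe_beyond_cutoff_recovered(self, probe_recon):
        """A sinusoid at fc + fm/2, invisible to the optics, is recovered
        from 7 noiseless frames per orientation via the fringe sidebands."""
        optical = probe_recon["optical"]
        f_probe = probe_recon["f_probe_cpd"]
        o0 = probe_recon["result"].object.o0
        n = o0.shape[0]
        ps = optical.object_pixel_scale
        spec = np.abs(fft2(o0)) ** 2
        fy = fftfreq(n, d=ps)
        FY, FX = fy[:, None], fy[None, :]
        t = np.deg2rad(45.0)
        py, px = f_probe * np.sin(t), f_probe * np.cos(t)
        df = 1.0 / (n * ps)
        peak = ((FY - py) / df) ** 2 + ((FX - px) / df) ** 2 <= 4.0
        ring = (np.abs(np.hypot(FY, FX) - f_probe) < 3 * df) & ~peak
        ring &= ((FY + py) / df) ** 2 + ((FX + px) / df) ** 2 > 4.0
        snr = spec[peak].max() / spec[ring].mean()
        assert snr > 10

    def test_positivity_extends_the_spectrum(self):
        """For a dark-background point object, the positivity-constrained
        solution carries more energy beyond fc + fm than the unconstrained
        quadratic solution."""
        optical = OpticalModel()
        illum = IlluminationModel(contrast_infocus=0.9, frames_per_block=1)
        cam, q = 32, optical.oversampling_factor
        obj_n = cam * q
        o0 = np.zeros((obj_n, obj_n))
        o0[obj_n // 2, obj_n // 2] = 1.0
        o0 = gaussian_filter(o0, 0.6)
        obj = TwoLayerObject(o0, np.zeros_like(o0))
        rng = np.random.default_rng(13)
        n = 14
        shifts = ShiftTrajectory(
            np.vstack([[0, 0], rng.uniform(-4, 4, (n - 1, 2))])
        )
        orient = np.array([45.0] * 7 + [-45.0] * 7)
        op = StackOperator(
            obj.shape, optical, illum, shifts.shifts,
            orientations=orient, phases=[0.0] * n,
        )
        stack = FrameStack(op.forward_stack(obj), orientations=orient)
        hyper = Hyperparameters(
            1e-8, PsdModel(1e-3, 60.0, 2.0), PsdModel(1e-3, 10.0, 2.0), lam=1e-6
        )
        kw = dict(hyper=hyper, max_iter=150, tol=1e-15)
        res_pos = reconstruct(stack, shifts, optical, illum, positivity=True, **kw)
        res_free = reconstruct(stack, shifts, optical, illum, positivity=False, **kw)
        fy = fftfreq(obj_n, d=optical.object_pixel_scale)
        fr = np.hypot(fy[:, None], fy[None, :])
        beyond = fr > optical.cutoff_cpd() + illum.modulation_frequency_cpd + 5.0
        e_pos = np.sum(np.abs(fft2(res_pos.object.o0)) ** 2 * beyond)
        e_free = np.sum(np.abs(fft2(res_free.object.o0)) ** 2 * beyond)
        assert e_pos > e_free
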