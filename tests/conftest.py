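"""Shared fixtures.

The heavier fixtures (full simulated acquisitions and MAP reconstructions)
are session-scoped so that several property tests can interrogate one run.
Problem sizes are scaled down from the instrument's native geometry (2048
camera pixels, 1000 frames) to keep the whole suite fast; the optical
constants (pupil, wavelength, pixel scale, fringe frequency) are the
instrument's.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from sio.bossa_sim import Hyperparameters, PsdModel, reconstruct
from sio.forward_model import (
    IlluminationModel,
    OpticalModel,
    ShiftTrajectory,
    StackOperator,
    TwoLayerObject,
)
from sio.frame_selection import select_frames
from sio.metrics import build_widefield
from sio.preprocessing import PreprocessConfig, preprocess_stack
from sio.shift_estimation import NotchSpec, estimate_shifts, notch_filter_stack
from sio.simulator import (
    AcquisitionSpec,
    PhantomSpec,
    generate_phantom,
    generate_stack,
    generate_trajectory,
)
from sio.stack import FrameStack


@pytest.fixture(scope="session")
def optical():
    return OpticalModel()


@pytest.fixture(scope="session")
def illum():
    return IlluminationModel()


def _acquisition(n_frames=48, blink=0.1, frame_rate=24.0, switching=1.0, drift=1.0):
    # default: scaled-down record, 2 s at 24 Hz, switching each second, with
    # per-second drift diffusion matching 0.5 px/frame at 100 Hz
    return AcquisitionSpec(
        n_frames=n_frames,
        frame_rate_hz=frame_rate,
        switching_rate_hz=switching,
        noise_sigma=0.0,
        drift_step_px=drift,
        microsaccade_rate_hz=0.5,
        microsaccade_amplitude_px=8.0,
        blink_fraction=blink,
        dark_offset=100.0,
    )


def _simulated(
    snr: float,
    cam: int = 128,
    blink: float = 0.1,
    seed: int = 1,
    acq: AcquisitionSpec | None = None,
):
    """Simulated acquisition at the given per-frame SNR, plus ground truth."""
    optical = OpticalModel()
    illum = IlluminationModel()
    if acq is None:
        acq = _acquisition(blink=blink)
    phantom = generate_phantom(
        PhantomSpec(rng_seed=seed), optical, camera_shape=(cam * 2, cam * 2)
    )
    traj = generate_trajectory(acq, rng_seed=seed + 1)
    stack, dark, truth = generate_stack(
        phantom, traj, optical, illum, acq, rng_seed=seed + 2
    )
    rng = np.random.default_rng(seed + 3)
    sigma = truth["clean_frames"].mean() / snr
    stack.frames = stack.frames + rng.normal(0.0, sigma, stack.frames.shape)
    dark.frames = dark.frames + rng.normal(0.0, sigma, dark.frames.shape)
    truth["sigma"] = sigma
    return stack, dark, truth, optical, illum


@pytest.fixture(scope="session")
def snr5_acquisition():
    """SNR-5 acquisition at the instrument's native timing: 2 s at 100 Hz,
    orientation switching at 2 Hz (50-frame blocks), 0.5 px/frame drift."""
    return _simulated(
        snr=5.0,
        acq=_acquisition(n_frames=200, frame_rate=100.0, switching=2.0, drift=0.5),
    )


@pytest.fixture(scope="session")
def default_pipeline_run(snr20_acquisition):
    """Full pipeline on the SNR-20 acquisition, through reconstruction."""
    stack, dark, truth, optical, illum = snr20_acquisition
    prep = preprocess_stack(stack, dark, PreprocessConfig())
    report = select_frames(
        prep.stack, illum.modulation_frequency_cpd, optical.pixel_scale
    )
    selected = prep.stack.subset(report.selected_indices)
    spec = NotchSpec(
        illum.modulation_frequency_cpd,
        tuple(illum.orientations),
        optical.pixel_scale,
    )
    filtered = notch_filter_stack(
        prep.cropped.subset(report.selected_indices), spec
    )
    traj = estimate_shifts(filtered)
    result = reconstruct(
        selected,
        traj,
        optical,
        illum,
        lam=0.3,
        max_iter=80,
        tol=1e-9,
        window=prep.window,
    )
    widefield = build_widefield(selected, traj)
    return {
        "stack": stack,
        "truth": truth,
        "optical": optical,
        "illum": illum,
        "prep": prep,
        "report": report,
        "selected": selected,
        "trajectory": traj,
        "result": result,
        "widefield": widefield,
    }


@pytest.fixture(scope="session")
def snr20_acquisition():
    return _simulated(snr=20.0)


def _sim_frames(obj, optical, illum, n_per_orientation, rng, shift_span=5.0):
    """Noiseless frames with random shifts, balanced +/-45 orientations."""
    n = 2 * n_per_orientation
    shifts = ShiftTrajectory(
        np.vstack([[0.0, 0.0], rng.uniform(-shift_span, shift_span, (n - 1, 2))])
    )
    orient = np.array([45.0] * n_per_orientation + [-45.0] * n_per_orientation)
    op = StackOperator(
        obj.shape, optical, illum, shifts.shifts, orientations=orient, phases=[0.0] * n
    )
    frames = op.forward_stack(obj)
    return frames, shifts, orient


@pytest.fixture(scope="session")
def twopoint_recon():
    """Two points at the diffraction-scale spacing over a strong background,
    reconstructed at SNR 20; also serves as the layer-separation fixture."""
    optical = OpticalModel()
    illum = IlluminationModel(contrast_infocus=0.9, frames_per_block=1)
    cam, q = 64, optical.oversampling_factor
    obj_n = cam * q
    sep_obj_px = (1.0 / optical.cutoff_cpd()) / optical.object_pixel_scale
    o0 = np.zeros((obj_n, obj_n))
    c = obj_n // 2
    o0[c, int(round(c - sep_obj_px / 2))] = 1.0
    o0[c, int(round(c + sep_obj_px / 2))] = 1.0
    o0 = gaussian_filter(o0, 0.7)
    rng = np.random.default_rng(11)
    bg = gaussian_filter(rng.standard_normal((obj_n, obj_n)), 20.0)
    bg = np.clip(1.0 + 0.3 * bg / bg.std(), 0.0, None)
    bg *= 2.0 * o0.mean() / bg.mean()
    obj = TwoLayerObject(o0, bg)
    frames, shifts, orient = _sim_frames(obj, optical, illum, 7, rng)
    sigma = frames.mean() / 20.0
    frames = frames + rng.normal(0.0, sigma, frames.shape)
    stack = FrameStack(frames, orientations=orient)
    hyper = Hyperparameters(
        sigma**2, PsdModel(1e-2, 60.0, 2.0), PsdModel(1e-2, 10.0, 2.0), lam=0.05
    )
    result = reconstruct(
        stack, shifts, optical, illum, hyper=hyper, max_iter=200, tol=1e-14
    )
    widefield = build_widefield(stack, shifts)
    return {
        "optical": optical,
        "illum": illum,
        "truth": obj,
        "sep_obj_px": sep_obj_px,
        "stack": stack,
        "result": result,
        "widefield": widefield,
        "cam": cam,
    }


@pytest.fixture(scope="session")
def probe_recon():
    """Cone mosaic carrying a probe sinusoid beyond the optical cutoff,
    reconstructed noiselessly from 7 frames per orientation."""
    optical = OpticalModel()
    illum = IlluminationModel(contrast_infocus=0.9, frames_per_block=1)
    fc = optical.cutoff_cpd()
    f_probe = fc + 0.5 * illum.modulation_frequency_cpd
    cam, q = 64, optical.oversampling_factor
    obj_n = cam * q
    ps = optical.object_pixel_scale
    phantom = generate_phantom(
        PhantomSpec(rng_seed=5, background_to_signal_ratio=0.0, spacing_jitter=0.05),
        optical,
        camera_shape=(cam, cam),
    )
    y = np.arange(obj_n)[:, None] * ps
    x = np.arange(obj_n)[None, :] * ps
    t = np.deg2rad(45.0)
    probe = 0.3 * phantom.o0.mean() * (
        1.0 + np.cos(2.0 * np.pi * f_probe * (x * np.cos(t) + y * np.sin(t)))
    )
    obj = TwoLayerObject(phantom.o0 + probe, np.zeros((obj_n, obj_n)))
    rng = np.random.default_rng(7)
    frames, shifts, orient = _sim_frames(obj, optical, illum, 7, rng, shift_span=6.0)
    stack = FrameStack(frames, orientations=orient)
    hyper = Hyperparameters(
        1e-8, PsdModel(1.0, 60.0, 2.0), PsdModel(1.0, 10.0, 2.0), lam=1e-8
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = reconstruct(
            stack, shifts, optical, illum, hyper=hyper, max_iter=200, tol=1e-15
        )
    return {
        "optical": optical,
        "illum": illum,
        "f_probe_cpd": f_probe,
        "truth": obj,
        "result": result,
    }
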