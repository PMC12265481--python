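"""Synthetic fringe-illuminated retinal acquisitions with ground truth.

Emulates the statistical structure of a structured-illumination
ophthalmoscope run: a cone-mosaic in-focus layer over a smooth scattering
background, static sinusoidal fringes whose orientation alternates in
frame blocks, fixational eye motion (drift random walk plus occasional
microsaccade jumps), blink-degraded frames, a camera dark offset and
additive homogeneous Gaussian noise.  Every output is a pure function of
the specs and the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .forward_model import (
    IlluminationModel,
    OpticalModel,
    ShiftTrajectory,
    StackOperator,
    TwoLayerObject,
)
from .stack import FrameStack
from .units import frames_per_block


@dataclass
class PhantomSpec:
    """Geometry and statistics of the synthetic two-layer retina.

    The in-focus layer is a jittered hexagonal lattice of Gaussian cones
    with log-normal reflectances; the defocused layer is a smooth positive
    random field scaled to ``background_to_signal_ratio`` times the mean
    in-focus intensity.
    """

    cone_spacing_um: float = 5.0
    spacing_jitter: float = 0.1
    cone_sigma_um: float = 1.2
    reflectance_cv: float = 0.2
    background_correlation_um: float = 15.0
    background_to_signal_ratio: float = 2.0
    field_of_view_deg: float | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cone_spacing_um", "cone_sigma_um", "background_correlation_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("spacing_jitter", "reflectance_cv", "background_to_signal_ratio"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.cone_sigma_um >= self.cone_spacing_um:
            raise ValueError(
                "cone_sigma >= cone_spacing produces a degenerate, unresolvable "
                "phantom"
            )


@dataclass
class AcquisitionSpec:
    """Timing, motion and noise of a synthetic acquisition."""

    n_frames: int = 200
    frame_rate_hz: float = 100.0
    switching_rate_hz: float = 2.0
    noise_sigma: float = 0.05
    drift_step_px: float = 0.5
    microsaccade_rate_hz: float = 0.5
    microsaccade_amplitude_px: float = 8.0
    blink_fraction: float = 0.05
    dark_offset: float = 100.0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        # also validates integrality of the ratio
        self.frames_per_block = frames_per_block(
            self.frame_rate_hz, self.switching_rate_hz
        )
        if not 0.0 <= self.blink_fraction < 1.0:
            raise ValueError("blink_fraction must be in [0, 1)")


def hexagonal_lattice(
    shape: tuple[int, int], spacing_px: float
) -> np.ndarray:
    """(k, 2) array of (y, x) hexagonal lattice sites covering ``shape``."""
    ny, nx = shape
    row_pitch = spacing_px * np.sqrt(3.0) / 2.0
    pts = []
    r = 0
    y = 0.0
    while y < ny:
        offset = 0.5 * spacing_px if r % 2 else 0.0
        x = offset
        while x < nx:
            pts.append((y, x))
            x += spacing_px
        r += 1
        y = r * row_pitch
    return np.array(pts)


def generate_phantom(
    spec: PhantomSpec, optical: OpticalModel, camera_shape: tuple[int, int] = (256, 256)
) -> TwoLayerObject:
    """Ground-truth two-layer object on the oversampled grid.

    Returns cone positions and amplitudes in ``phantom.o0``/``od``; the
    lattice sites actually used are attached as ``.cone_positions``
    (object-grid pixels) for detection oracles.
    """
    rng = np.random.default_rng(spec.rng_seed)
    q = optical.oversampling_factor
    if spec.field_of_view_deg is not None:
        side = int(round(spec.field_of_view_deg / optical.pixel_scale))
        camera_shape = (side, side)
    obj_shape = (camera_shape[0] * q, camera_shape[1] * q)

    um_per_px = optical.object_pixel_scale * optical.retinal_scale
    spacing_px = spec.cone_spacing_um / um_per_px
    sigma_px = spec.cone_sigma_um / um_per_px

    sites = hexagonal_lattice(obj_shape, spacing_px)
    jitter = rng.normal(0.0, spec.spacing_jitter * spacing_px, size=sites.shape)
    pos = sites + jitter
    keep = (
        (pos[:, 0] >= 0)
        & (pos[:, 0] < obj_shape[0])
        & (pos[:, 1] < obj_shape[1])
        & (pos[:, 1] >= 0)
    )
    pos = pos[keep]
    if spec.reflectance_cv > 0:
        s = np.sqrt(np.log(1.0 + spec.reflectance_cv**2))
        amps = rng.lognormal(mean=-0.5 * s**2, sigma=s, size=len(pos))
    else:
        amps = np.ones(len(pos))

    # render each cone as a Gaussian blob by splatting onto the nearest pixel
    # then blurring once; with one shared sigma this is exact up to the
    # sub-pixel quantization of the splat.
    o0 = np.zeros(obj_shape)
    iy = np.clip(np.round(pos[:, 0]).astype(int), 0, obj_shape[0] - 1)
    ix = np.clip(np.round(pos[:, 1]).astype(int), 0, obj_shape[1] - 1)
    np.add.at(o0, (iy, ix), amps)
    o0 = gaussian_filter(o0, sigma_px, mode="wrap")
    o0 = np.clip(o0, 0.0, None)

    corr_px = spec.background_correlation_um / um_per_px
    field = gaussian_filter(rng.standard_normal(obj_shape), corr_px, mode="wrap")
    if field.std() > 0:
        field = (field - field.mean()) / field.std()
    od = np.clip(1.0 + 0.3 * field, 0.0, None)
    target = spec.background_to_signal_ratio * o0.mean()
    if od.mean() > 0:
        od *= target / od.mean()

    obj = TwoLayerObject(o0, od)
    obj.cone_positions = pos  # object-grid (y, x) px
    return obj


def generate_trajectory(
    spec: AcquisitionSpec, n_frames: int | None = None, rng_seed: int = 0
) -> ShiftTrajectory:
    """Drift random walk plus Poisson-timed microsaccade jumps.

    Frame 0 is the reference with zero shift.  Frames on which a jump
    occurs are flagged in ``trajectory.jump`` so that the selection stage
    can be tested against them.
    """
    n = spec.n_frames if n_frames is None else int(n_frames)
    if n < 1:
        raise ValueError("need at least one frame")
    rng = np.random.default_rng(rng_seed)
    steps = rng.normal(0.0, spec.drift_step_px, size=(n, 2))
    steps[0] = 0.0
    p_jump = min(1.0, spec.microsaccade_rate_hz / spec.frame_rate_hz)
    jump = rng.random(n) < p_jump
    jump[0] = False
    angles = rng.uniform(0.0, 2.0 * np.pi, size=n)
    jumps = np.zeros((n, 2))
    jumps[jump, 0] = spec.microsaccade_amplitude_px * np.sin(angles[jump])
    jumps[jump, 1] = spec.microsaccade_amplitude_px * np.cos(angles[jump])
    shifts = np.cumsum(steps + jumps, axis=0)
    traj = ShiftTrajectory(shifts)
    traj.jump = jump
    return traj


def fringe_phases(
    trajectory: ShiftTrajectory,
    illum: IlluminationModel,
    pixel_scale_deg: float,
    orientation_deg: float,
) -> np.ndarray:
    """Per-frame fringe phase (rad, mod 2pi) induced by the retinal shifts.

    Shifting the retina by ``s`` under a static fringe of wavevector
    ``f_m (cos t, sin t)`` advances the fringe phase over the object by
    ``2 pi f_m (s . n)`` with the shift converted to degrees.
    """
    t = np.deg2rad(orientation_deg)
    proj = (
        trajectory.shifts[:, 1] * np.cos(t) + trajectory.shifts[:, 0] * np.sin(t)
    ) * pixel_scale_deg
    return np.mod(2.0 * np.pi * illum.modulation_frequency_cpd * proj, 2.0 * np.pi)


def generate_stack(
    phantom: TwoLayerObject,
    trajectory: ShiftTrajectory,
    optical: OpticalModel,
    illum: IlluminationModel,
    acq: AcquisitionSpec,
    rng_seed: int = 0,
    n_dark_frames: int = 100,
):
    """Render a full synthetic acquisition.

    Returns ``(stack, dark_stack, truth)`` where ``truth`` is a dict with
    the noiseless frames, the true shifts, per-frame orientations, the
    blink flags and the per-frame SNR (mean in-focus signal over sigma).
    """
    rng = np.random.default_rng(rng_seed)
    n = acq.n_frames
    fpb = acq.frames_per_block
    if len(trajectory) < n:
        raise ValueError("trajectory shorter than the requested frame count")
    orientations = np.array(
        [illum.orientations[(j // fpb) % len(illum.orientations)] for j in range(n)]
    )
    phases = np.array([illum.phase_of(j) for j in range(n)])
    op = StackOperator(
        phantom.shape,
        optical,
        illum,
        trajectory.shifts[:n],
        orientations=orientations,
        phases=phases,
    )
    clean = op.forward_stack(phantom)

    blink = np.zeros(n, dtype=bool)
    n_blink = int(round(acq.blink_fraction * n))
    if n_blink:
        blink[rng.choice(n, size=n_blink, replace=False)] = True

    frames = clean.copy()
    for j in np.nonzero(blink)[0]:
        frames[j] = 0.5 * gaussian_filter(frames[j], 3.0, mode="wrap")
    frames = frames + acq.dark_offset
    if acq.noise_sigma > 0:
        frames = frames + rng.normal(0.0, acq.noise_sigma, size=frames.shape)

    dark = acq.dark_offset + (
        rng.normal(0.0, acq.noise_sigma, size=(n_dark_frames, *clean.shape[1:]))
        if acq.noise_sigma > 0
        else np.zeros((n_dark_frames, *clean.shape[1:]))
    )

    timestamps = np.arange(n) / acq.frame_rate_hz
    stack = FrameStack(
        frames,
        orientations=orientations,
        timestamps=timestamps,
        blink=blink,
        jump=getattr(trajectory, "jump", np.zeros(n, dtype=bool))[:n],
        frame_rate=acq.frame_rate_hz,
    )
    dark_stack = FrameStack(dark, frame_rate=acq.frame_rate_hz)
    snr = (
        clean.mean(axis=(1, 2)) / acq.noise_sigma
        if acq.noise_sigma > 0
        else np.full(n, np.inf)
    )
    truth = {
        "clean_frames": clean,
        "shifts": trajectory.shifts[:n].copy(),
        "orientations": orientations,
        "phases": phases,
        "blink": blink,
        "snr": snr,
        "phantom": phantom,
    }
    return stack, dark_stack, truth
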