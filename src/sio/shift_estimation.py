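"""Inter-frame retinal shift estimation.

The fringe frequencies are first removed with a Fourier notch mask so the
frames look like ordinary flood-illumination images, then subpixel shifts
relative to a reference frame are estimated by phase correlation with
upsampled-DFT refinement.  The shifts are *not* applied to the frames:
they parameterize the shift operator inside the reconstruction model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.fft import fft2, fftfreq, ifft2
from scipy.signal.windows import tukey
from skimage.registration import phase_cross_correlation

from .forward_model import ShiftTrajectory, apply_shift
from .frame_selection import gradient_energy
from .stack import FrameStack


@dataclass
class NotchSpec:
    """Fourier notch mask geometry for one or more fringe orientations."""

    f_m_cpd: float
    orientations_deg: tuple[float, ...]
    pixel_scale_deg: float
    radius_bins: float = 3.0

    def __post_init__(self) -> None:
        if self.radius_bins < 1:
            raise ValueError("notch radius must be at least one bin")

    def centers_cpd(self) -> list[tuple[float, float]]:
        out = []
        for theta in self.orientations_deg:
            t = np.deg2rad(theta)
            fy = self.f_m_cpd * np.sin(t)
            fx = self.f_m_cpd * np.cos(t)
            out.extend([(fy, fx), (-fy, -fx)])
        return out

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        ny, nx = shape
        fy = fftfreq(ny, d=self.pixel_scale_deg)
        fx = fftfreq(nx, d=self.pixel_scale_deg)
        dfy = 1.0 / (ny * self.pixel_scale_deg)
        dfx = 1.0 / (nx * self.pixel_scale_deg)
        m = np.ones(shape, dtype=bool)
        for cy, cx in self.centers_cpd():
            hit = ((fy[:, None] - cy) / dfy) ** 2 + (
                (fx[None, :] - cx) / dfx
            ) ** 2 <= self.radius_bins**2
            m &= ~hit
        if not m[0, 0]:
            raise ValueError("notch mask may not cover the DC bin")
        return m


def notch_filter(frame: np.ndarray, spec: NotchSpec) -> np.ndarray:
    """Zero the fringe frequencies; real output, DC preserved."""
    mask = spec.mask(frame.shape)
    return np.real(ifft2(fft2(frame) * mask))


def notch_filter_stack(stack: FrameStack, spec: NotchSpec) -> FrameStack:
    out = stack.subset(np.arange(len(stack)))
    out.frames = np.stack([notch_filter(f, spec) for f in stack.frames])
    return out


def _register(
    ref: np.ndarray,
    moving: np.ndarray,
    upsample_factor: int,
    overlap_taper: float = 0.25,
    iters: int = 2,
) -> np.ndarray:
    """Shift of ``moving`` content relative to ``ref`` (positive = moved by +s).

    Integer phase correlation first; then the subpixel part is re-estimated
    on the integer-aligned overlap of the two frames, mean-removed and
    cosine-tapered.  Aligning before tapering removes the bias that a
    static window exerts on a moving scene, and restricting to the overlap
    removes the bias from content entering/leaving the field.
    """
    reg, _, _ = phase_cross_correlation(
        ref, moving, upsample_factor=1, normalization=None
    )
    # `reg` registers `moving` onto `ref`: the moving content sits at -reg
    s = -np.asarray(reg, dtype=float)
    H, W = ref.shape
    for _ in range(iters):
        dy, dx = int(round(s[0])), int(round(s[1]))
        if abs(dy) >= H - 2 or abs(dx) >= W - 2:
            break
        mov_ov = moving[max(dy, 0) : H + min(dy, 0), max(dx, 0) : W + min(dx, 0)]
        ref_ov = ref[max(-dy, 0) : H + min(-dy, 0), max(-dx, 0) : W + min(-dx, 0)]
        w = np.outer(
            tukey(mov_ov.shape[0], overlap_taper),
            tukey(mov_ov.shape[1], overlap_taper),
        )
        a = (ref_ov - ref_ov.mean()) * w
        b = (mov_ov - mov_ov.mean()) * w
        r, _, _ = phase_cross_correlation(
            a, b, upsample_factor=upsample_factor, normalization=None
        )
        s = np.array([dy, dx], dtype=float) - r
    return s


def estimate_shifts(
    stack: FrameStack,
    reference_index: int | None = None,
    upsample_factor: int = 50,
    min_correlation: float = 0.05,
    refine_passes: int = 2,
) -> ShiftTrajectory:
    """Per-frame (dy, dx) of the retina relative to the reference frame.

    Phase correlation with local DFT upsampling; the convention is that
    ``frame_j ~ apply_shift(reference, shift_j)``.  After the first pass,
    each frame is re-registered against the counter-shifted temporal mean,
    which has higher SNR than any single frame and averages out the
    boundary bias of the finite field; the final shifts are re-zeroed at
    the reference frame.  Frames whose registered correlation with the
    reference falls below ``min_correlation`` (e.g. featureless frames)
    are flagged invalid rather than raising.
    """
    if len(stack) < 1:
        raise ValueError("empty stack")
    frames = stack.frames
    if reference_index is None:
        reference_index = int(
            np.argmax([gradient_energy(f) for f in frames])
        )
    ref = frames[reference_index]
    n = len(frames)
    shifts = np.zeros((n, 2))
    valid = np.ones(n, dtype=bool)
    for j in range(n):
        if j == reference_index:
            continue
        if frames[j].std() == 0 or ref.std() == 0:
            valid[j] = False
            continue
        shifts[j] = _register(ref, frames[j], upsample_factor)

    for _ in range(max(refine_passes, 0)):
        if valid.sum() < 2:
            break
        mean = np.zeros_like(ref)
        for j in np.nonzero(valid)[0]:
            mean += apply_shift(frames[j], tuple(-shifts[j]))
        mean /= valid.sum()
        for j in range(n):
            if not valid[j] and j != reference_index:
                continue
            shifts[j] = _register(mean, frames[j], upsample_factor)
        shifts -= shifts[reference_index]

    ref_c = ref - ref.mean()
    ref_norm = np.sqrt(np.sum(ref_c**2))
    if ref_norm > 0:
        for j in range(n):
            if j == reference_index or not valid[j]:
                continue
            back = apply_shift(frames[j], tuple(-shifts[j]))
            b = back - back.mean()
            denom = ref_norm * np.sqrt(np.sum(b**2))
            corr = float(np.sum(ref_c * b) / denom) if denom > 0 else 0.0
            if corr < min_correlation:
                valid[j] = False
                shifts[j] = 0.0
    return ShiftTrajectory(shifts, valid=valid, reference_index=reference_index)
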