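"""Three-step frame selection.

1. keep the sharpest frames by gradient energy (rejects blinks,
   microsaccade smears and poor wavefront-correction episodes);
2. within the survivors, keep the contiguous time window with the highest
   mean fringe-contrast energy (a deterministic surrogate for picking the
   high-contrast stretch by eye);
3. balance the per-orientation frame counts by dropping the
   lowest-contrast frames of the over-represented orientation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from numpy.fft import fft2, fftfreq

from .stack import FrameStack


class SelectionError(RuntimeError):
    def __init__(self, step: str, message: str) -> None:
        super().__init__(f"frame selection failed at {step}: {message}")
        self.step = step


@dataclass
class SelectionReport:
    gradient_energy: np.ndarray
    fringe_contrast_energy: np.ndarray
    retained_step1: np.ndarray
    retained_step2: np.ndarray
    retained_step3: np.ndarray
    orientation_counts: dict[float, int]

    @property
    def selected_indices(self) -> np.ndarray:
        return np.nonzero(self.retained_step3)[0]

    def to_json(self, path) -> None:
        payload = {
            "gradient_energy": self.gradient_energy.tolist(),
            "fringe_contrast_energy": self.fringe_contrast_energy.tolist(),
            "retained_step1": self.retained_step1.tolist(),
            "retained_step2": self.retained_step2.tolist(),
            "retained_step3": self.retained_step3.tolist(),
            "orientation_counts": {str(k): v for k, v in self.orientation_counts.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def gradient_energy(frame: np.ndarray) -> float:
    """Sum of squared forward differences along x and y.

    A sharpness metric: blurring removes high-frequency content and lowers
    it; it scales quadratically with a global intensity scale, so rankings
    are scale-invariant.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or min(frame.shape) < 2:
        raise ValueError("frame must be 2-D and at least 2x2")
    dx = np.diff(frame, axis=1)
    dy = np.diff(frame, axis=0)
    return float(np.sum(dx**2) + np.sum(dy**2))


def fringe_contrast_energy(
    frame: np.ndarray,
    f_m_cpd: float,
    orientation_deg: float,
    pixel_scale_deg: float,
    tolerance_bins: int = 3,
) -> float:
    """Fraction of non-DC spectral energy within the fringe peaks.

    Sums ``|FFT|^2`` over discs of radius ``tolerance_bins`` around the two
    conjugate fringe frequencies and normalizes by the total non-DC energy;
    lies in [0, 1].
    """
    frame = np.asarray(frame, dtype=float)
    ny, nx = frame.shape
    nyquist = 0.5 / pixel_scale_deg
    if f_m_cpd >= nyquist:
        raise ValueError(f"f_m {f_m_cpd} cpd at or above Nyquist {nyquist} cpd")
    spec = np.abs(fft2(frame)) ** 2
    total = spec.sum() - spec[0, 0]
    if total <= 0:
        return 0.0
    t = np.deg2rad(orientation_deg)
    fy0 = f_m_cpd * np.sin(t)
    fx0 = f_m_cpd * np.cos(t)
    fy = fftfreq(ny, d=pixel_scale_deg)
    fx = fftfreq(nx, d=pixel_scale_deg)
    dfy = 1.0 / (ny * pixel_scale_deg)
    dfx = 1.0 / (nx * pixel_scale_deg)
    energy = 0.0
    for sy, sx in ((fy0, fx0), (-fy0, -fx0)):
        mask = ((fy[:, None] - sy) / dfy) ** 2 + (
            (fx[None, :] - sx) / dfx
        ) ** 2 <= tolerance_bins**2
        mask[0, 0] = False
        energy += spec[mask].sum()
    return float(min(energy / total, 1.0))


def select_frames(
    stack: FrameStack,
    f_m_cpd: float,
    pixel_scale_deg: float,
    window_seconds: float = 2.0,
    quality_quantile: float = 0.5,
    tolerance_bins: int = 3,
) -> SelectionReport:
    """Run the three selection steps and report per-frame decisions.

    Ties in the quality ranking are broken in favour of earlier frames.
    The final per-orientation counts are exactly equal.
    """
    n = len(stack)
    if n == 0:
        raise SelectionError("step 1", "empty stack")
    grad = np.array([gradient_energy(f) for f in stack.frames])
    contrast = np.array(
        [
            fringe_contrast_energy(
                f, f_m_cpd, theta, pixel_scale_deg, tolerance_bins
            )
            for f, theta in zip(stack.frames, stack.orientations)
        ]
    )

    # step 1: top quality_quantile by gradient energy, earlier frame wins ties
    n_keep = int(np.floor(quality_quantile * n + 1e-9))
    if n_keep < 1:
        raise SelectionError("step 1", "quality quantile keeps no frames")
    order = np.lexsort((np.arange(n), -grad))
    step1 = np.zeros(n, dtype=bool)
    step1[order[:n_keep]] = True

    # step 2: contiguous window of length window_seconds maximizing mean
    # fringe-contrast energy among step-1 survivors
    surv = np.nonzero(step1)[0]
    t = stack.timestamps[surv]
    # candidate starts are clipped so every window spans the full
    # window_seconds inside the acquisition (otherwise maximizing the mean
    # would favour degenerate slivers at the end of the record)
    latest_start = max(t.max() - window_seconds, t.min())
    starts = np.unique(np.minimum(t, latest_start))
    best_mask = None
    best_mean = -np.inf
    for start in starts:
        inside = (t >= start) & (t < start + window_seconds)
        if not inside.any():
            continue
        m = contrast[surv[inside]].mean()
        if m > best_mean + 1e-15:
            best_mean = m
            best_mask = inside
    if best_mask is None:
        raise SelectionError("step 2", "no window contains surviving frames")
    step2 = np.zeros(n, dtype=bool)
    step2[surv[best_mask]] = True

    # step 3: balance orientation counts, dropping lowest-contrast frames
    # from over-represented orientations
    step3 = step2.copy()
    idx2 = np.nonzero(step2)[0]
    if len(idx2) == 0:
        raise SelectionError("step 3", "no frames left to balance")
    thetas = np.unique(stack.orientations[idx2])
    counts = {th: int(np.sum(stack.orientations[idx2] == th)) for th in thetas}
    n_min = min(counts.values())
    if n_min == 0:
        raise SelectionError("step 3", "an orientation has no surviving frames")
    for th in thetas:
        members = idx2[stack.orientations[idx2] == th]
        excess = len(members) - n_min
        if excess > 0:
            # drop lowest contrast first; ties: later frame dropped first
            drop_order = members[np.lexsort((-members, contrast[members]))]
            step3[drop_order[:excess]] = False

    final_idx = np.nonzero(step3)[0]
    final_counts = {
        float(th): int(np.sum(stack.orientations[final_idx] == th)) for th in thetas
    }
    return SelectionReport(
        gradient_energy=grad,
        fringe_contrast_energy=contrast,
        retained_step1=step1,
        retained_step2=step2,
        retained_step3=step3,
        orientation_counts=final_counts,
    )
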