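"""Raw-frame conditioning: dark subtraction, center crop, apodization.

The stages run in this fixed order.  Dark-subtracted values are kept
signed — clipping at zero would bias the noise statistics that the
unsupervised hyperparameter estimation relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import tukey

from .stack import FrameStack


@dataclass
class PreprocessConfig:
    crop_size: int | None = None  # default: half the frame side
    taper_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.taper_fraction <= 1.0:
            raise ValueError("taper_fraction must lie in [0, 1]")


def subtract_dark(stack: FrameStack, dark_stack: FrameStack) -> FrameStack:
    """Subtract the pixel-wise temporal mean of the dark stack from every frame."""
    if dark_stack.frame_shape != stack.frame_shape:
        raise ValueError("dark frames do not match the data frames")
    dark = dark_stack.frames.mean(axis=0)
    out = stack.subset(np.arange(len(stack)))
    out.frames = stack.frames - dark[None]
    return out


def crop_center(frame: np.ndarray, crop_size: int) -> np.ndarray:
    """Central ``crop_size`` x ``crop_size`` window (floor origin for odd margins)."""
    ny, nx = frame.shape
    if crop_size > min(ny, nx):
        raise ValueError(f"crop {crop_size} larger than frame {frame.shape}")
    oy = (ny - crop_size) // 2
    ox = (nx - crop_size) // 2
    return frame[oy : oy + crop_size, ox : ox + crop_size]


def tukey_window_2d(shape: tuple[int, int], alpha: float) -> np.ndarray:
    """Separable cosine-tapered (Tukey) window, 1 on the plateau, 0 at edges."""
    return np.outer(tukey(shape[0], alpha), tukey(shape[1], alpha))


def apodize(frame: np.ndarray, alpha: float) -> np.ndarray:
    """Multiply by a 2-D Tukey window to suppress FFT edge ringing."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    return frame * tukey_window_2d(frame.shape, alpha)


@dataclass
class PreprocessResult:
    """Tapered frames for selection/reconstruction, untapered for registration.

    The apodization window is static in the instrument frame while the
    retina moves, so it biases correlation-based shift estimation toward
    zero on small fields; registration therefore uses the cropped,
    untapered frames while the taper (returned in ``window``) is folded
    into the imaging model of the reconstruction.
    """

    stack: FrameStack
    cropped: FrameStack
    window: np.ndarray


def preprocess_stack(
    stack: FrameStack,
    dark_stack: FrameStack | None,
    config: PreprocessConfig | None = None,
) -> PreprocessResult:
    """dark -> crop -> apodize, applied to every frame."""
    config = config or PreprocessConfig()
    out = subtract_dark(stack, dark_stack) if dark_stack is not None else stack
    side = min(out.frame_shape)
    crop = config.crop_size if config.crop_size is not None else side // 2
    frames = np.stack([crop_center(f, crop) for f in out.frames])
    window = tukey_window_2d(frames.shape[1:], config.taper_fraction)
    cropped = out.subset(np.arange(len(out)))
    cropped.frames = frames
    tapered = out.subset(np.arange(len(out)))
    tapered.frames = frames * window[None]
    return PreprocessResult(stack=tapered, cropped=cropped, window=window)
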