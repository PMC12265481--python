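"""Ordered container for acquired or simulated frame sequences."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class FrameStack:
    """A sequence of 2-D intensity frames with per-frame metadata.

    Attributes
    ----------
    frames : (n, H, W) float array of intensities.
    orientations : (n,) fringe orientation label of each frame, degrees.
    timestamps : (n,) acquisition time of each frame, seconds.
    blink : (n,) bool, True for degraded (blink-surrogate) frames.
    jump : (n,) bool, True for frames acquired during a microsaccade jump.
    frame_rate : camera frame rate in Hz, if known.
    """

    frames: np.ndarray
    orientations: np.ndarray = None
    timestamps: np.ndarray = None
    blink: np.ndarray = None
    jump: np.ndarray = None
    frame_rate: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, H, W) array")
        n = len(self.frames)
        if self.orientations is None:
            self.orientations = np.zeros(n)
        self.orientations = np.asarray(self.orientations, dtype=float)
        if self.timestamps is None:
            dt = 1.0 / self.frame_rate if self.frame_rate else 1.0
            self.timestamps = np.arange(n) * dt
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.blink is None:
            self.blink = np.zeros(n, dtype=bool)
        if self.jump is None:
            self.jump = np.zeros(n, dtype=bool)
        self.blink = np.asarray(self.blink, dtype=bool)
        self.jump = np.asarray(self.jump, dtype=bool)
        for arr in (self.orientations, self.timestamps, self.blink, self.jump):
            if len(arr) != n:
                raise ValueError("per-frame metadata length mismatch")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def subset(self, indices) -> "FrameStack":
        """New stack restricted to ``indices`` (order preserved)."""
        idx = np.asarray(indices)
        return FrameStack(
            frames=self.frames[idx],
            orientations=self.orientations[idx],
            timestamps=self.timestamps[idx],
            blink=self.blink[idx],
            jump=self.jump[idx],
            frame_rate=self.frame_rate,
        )

    def orientation_counts(self) -> dict[float, int]:
        vals, counts = np.unique(self.orientations, return_counts=True)
        return {float(v): int(c) for v, c in zip(vals, counts)}
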