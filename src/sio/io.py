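"""Multi-page TIFF stack I/O with a JSON metadata sidecar.

Float stacks round-trip losslessly; 16-bit stacks record the scale factor
applied at write time so intensities are recovered up to half a
quantization step.  Orientation labels travel in the sidecar, or are
inferred from the frame-rate / switching-rate block structure when the
sidecar is absent.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .stack import FrameStack
from .units import frames_per_block


class StackFormatError(RuntimeError):
    pass


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(path: str | Path, stack: FrameStack, dtype: str = "float32") -> None:
    """Write a stack as multi-page TIFF plus JSON sidecar.

    ``dtype='uint16'`` scales intensities to the full 16-bit range and
    records the scale in the sidecar; any float dtype is stored verbatim.
    """
    path = Path(path)
    meta = {
        "orientations": stack.orientations.tolist(),
        "timestamps": stack.timestamps.tolist(),
        "blink": stack.blink.tolist(),
        "jump": stack.jump.tolist(),
        "frame_rate": stack.frame_rate,
        "scale": None,
    }
    frames = stack.frames
    if dtype == "uint16":
        lo = float(frames.min())
        hi = float(frames.max())
        span = hi - lo if hi > lo else 1.0
        scale = span / 65535.0
        data = np.round((frames - lo) / scale).astype(np.uint16)
        meta["scale"] = scale
        meta["offset"] = lo
    else:
        data = frames.astype(dtype)
    tifffile.imwrite(path, data, photometric="minisblack")
    with open(_sidecar(path), "w") as fh:
        json.dump(meta, fh)


def read_stack(
    path: str | Path,
    frame_rate_hz: float | None = None,
    switching_rate_hz: float | None = None,
    orientations: tuple[float, ...] = (45.0, -45.0),
) -> FrameStack:
    """Read a multi-page TIFF stack, using the sidecar when present.

    Without a sidecar, per-frame orientation labels are inferred from the
    block structure ``frames_per_block = frame_rate / switching_rate`` when
    those rates are given.
    """
    path = Path(path)
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # pragma: no cover
        raise StackFormatError(f"cannot read {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise StackFormatError(f"expected a 2-D frame stack, got shape {data.shape}")
    data = np.asarray(data)

    side = _sidecar(path)
    if side.exists():
        with open(side) as fh:
            meta = json.load(fh)
        frames = data.astype(float)
        if meta.get("scale") is not None:
            frames = frames * meta["scale"] + meta.get("offset", 0.0)
        return FrameStack(
            frames,
            orientations=np.asarray(meta["orientations"]),
            timestamps=np.asarray(meta["timestamps"]),
            blink=np.asarray(meta["blink"], dtype=bool),
            jump=np.asarray(meta["jump"], dtype=bool),
            frame_rate=meta.get("frame_rate"),
        )

    n = len(data)
    orient = None
    frame_rate = frame_rate_hz
    if frame_rate_hz is not None and switching_rate_hz is not None:
        fpb = frames_per_block(frame_rate_hz, switching_rate_hz)
        orient = np.array(
            [orientations[(j // fpb) % len(orientations)] for j in range(n)]
        )
    return FrameStack(data.astype(float), orientations=orient, frame_rate=frame_rate)


def write_image(path: str | Path, image: np.ndarray) -> None:
    tifffile.imwrite(Path(path), np.asarray(image, dtype=np.float32), photometric="minisblack")


def read_image(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(Path(path)), dtype=float)
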