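"""Movement index from grayscale video frame stacks.

Standard frame-differencing motion measure: the index at frame t is the
number of pixels whose absolute intensity change from frame t-1 exceeds a
per-pixel cutoff.  Frame 0, having no predecessor, is assigned index 0.
The output is in arbitrary units (pixel counts); only its relative
behavior is meaningful, and the per-pixel cutoff should be chosen so that
typical traces straddle the freezing classifier's 40 a.u. threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .freezing import MovementTrace

__all__ = ["FrameStack", "MotionParams", "compute_motion_index", "load_frame_stack"]


@dataclass
class FrameStack:
    """An ordered stack of equally sized 2-D grayscale frames."""

    frames: np.ndarray  # (n_frames, height, width), 8-bit intensity range
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, h, w) array")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass(frozen=True)
class MotionParams:
    """pixel_cutoff: per-pixel |intensity change| that counts as motion;
    smoothing: optional centered moving-average window, in frames."""

    pixel_cutoff: float = 10.0
    smoothing: int | None = None

    def __post_init__(self) -> None:
        if self.pixel_cutoff < 0:
            raise ValueError("pixel_cutoff must be >= 0")
        if self.smoothing is not None and self.smoothing < 1:
            raise ValueError("smoothing window must be >= 1 frame")


def compute_motion_index(
    stack: FrameStack, params: MotionParams = MotionParams()
) -> MovementTrace:
    """Frame-differencing movement index of a frame stack.

    index[t] = #{pixels with |frame[t] - frame[t-1]| > pixel_cutoff} for
    t >= 1; index[0] = 0.  Output length equals the stack length.
    """
    if stack.n_frames < 2:
        raise ValueError("need at least two frames to compute a motion index")
    diffs = np.abs(np.diff(stack.frames.astype(np.int32), axis=0))
    index = np.concatenate(
        ([0.0], (diffs > params.pixel_cutoff).sum(axis=(1, 2)).astype(float))
    )
    if params.smoothing:
        kernel = np.ones(params.smoothing) / params.smoothing
        index = np.convolve(index, kernel, mode="same")
    return MovementTrace(index, sample_rate=stack.frame_rate)


def load_frame_stack(path, frame_rate: float = 30.0) -> FrameStack:
    """Read a multi-page TIFF or a directory of PNG frames (sorted by name)."""
    p = Path(path)
    if p.is_dir():
        import imageio.v3 as iio

        files = sorted(p.glob("*.png"))
        if not files:
            raise FileNotFoundError(f"no PNG frames in {p}")
        frames = np.stack([np.asarray(iio.imread(f)) for f in files])
    else:
        import tifffile

        frames = tifffile.imread(p)
    if frames.ndim == 2:
        frames = frames[None]
    return FrameStack(frames, frame_rate)
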