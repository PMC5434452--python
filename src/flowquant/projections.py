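"""Temporal projections of a time-lapse stack.

Three derived images drive the whole quantification:

* **snapshot** — a single frame; shows every in-focus cell, adherent or
  rolling, because both touch the substrate and are in the focal plane;
* **minimum projection** — per-pixel temporal minimum; a bright cell
  survives only where its footprint covers the pixel in *every* frame,
  so only cells stationary for the whole window remain;
* **maximum projection** — per-pixel temporal maximum; a moving bright
  cell paints an elongated blur whose length encodes the distance it
  travelled.

Projections act on raw intensities; denoising and background handling
are the detector's concern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ConfigError
from .synth import FrameStack

SNAPSHOT = "snapshot"
MIN = "min"
MAX = "max"


@dataclass(frozen=True)
class ProjectionImage:
    raster: np.ndarray
    kind: str                 # snapshot | min | max
    source_frame_count: int
    duration_s: float
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in (SNAPSHOT, MIN, MAX):
            raise ConfigError(f"unknown projection kind {self.kind!r}")


def _check_stack(stack: FrameStack) -> None:
    if stack.n_frames < 1:
        raise ConfigError("stack has no frames")


def snapshot(stack: FrameStack, frame_index: int = 0) -> ProjectionImage:
    """Return one frame unmodified, tagged as the snapshot image.

    Defaults to frame 0 of the window.
    """
    _check_stack(stack)
    if not 0 <= frame_index < stack.n_frames:
        raise ConfigError(
            f"frame_index {frame_index} out of range [0, {stack.n_frames})"
        )
    return ProjectionImage(
        raster=stack.frames[frame_index].copy(),
        kind=SNAPSHOT,
        source_frame_count=1,
        duration_s=1.0 / stack.config.frame_rate,
        pixel_size_um=stack.config.pixel_size_um,
    )


def temporal_min(stack: FrameStack) -> ProjectionImage:
    """Per-pixel minimum over all frames: the firm-adhesion image."""
    _check_stack(stack)
    return ProjectionImage(
        raster=stack.frames.min(axis=0),
        kind=MIN,
        source_frame_count=stack.n_frames,
        duration_s=stack.n_frames / stack.config.frame_rate,
        pixel_size_um=stack.config.pixel_size_um,
    )


def temporal_max(stack: FrameStack) -> ProjectionImage:
    """Per-pixel maximum over all frames: the rolling-blur image."""
    _check_stack(stack)
    return ProjectionImage(
        raster=stack.frames.max(axis=0),
        kind=MAX,
        source_frame_count=stack.n_frames,
        duration_s=stack.n_frames / stack.config.frame_rate,
        pixel_size_um=stack.config.pixel_size_um,
    )
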