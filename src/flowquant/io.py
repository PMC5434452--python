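"""Reading and writing stacks, projections and tabular results.

Stacks travel as multi-page grayscale TIFF (8-bit default, 16-bit
optional), ground truth as one-row-per-cell CSV with a JSON sidecar for
the acquisition config and seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .config import AcquisitionConfig
from .projections import ProjectionImage
from .synth import CellSpec, FrameStack, GroundTruth


class FormatError(ValueError):
    """Raised when an input file does not match the expected layout."""


def write_stack(stack: FrameStack, path: str | Path) -> Path:
    """Write a stack as a multi-page grayscale TIFF."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames, photometric="minisblack")
    return path


def read_stack(path: str | Path, config: AcquisitionConfig) -> FrameStack:
    """Read a multi-page TIFF and validate it against the acquisition.

    The frame count must equal frame_rate × duration and every frame
    must match the configured raster shape; anything else is a format
    error naming the expectation.
    """
    path = Path(path)
    try:
        frames = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot read TIFF stack {path}: {exc}") from exc
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise FormatError(
            f"{path}: expected a (T, H, W) grayscale stack, got shape "
            f"{frames.shape}"
        )
    if frames.shape[0] != config.n_frames:
        raise FormatError(
            f"{path}: expected {config.n_frames} frames "
            f"({config.frame_rate} frames/s x {config.duration_s}s), got "
            f"{frames.shape[0]}"
        )
    if frames.shape[1:] != config.shape:
        raise FormatError(
            f"{path}: expected frame shape {config.shape}, got "
            f"{frames.shape[1:]}"
        )
    return FrameStack(frames=frames, config=config)


def write_projection(image: ProjectionImage, path: str | Path) -> Path:
    """Write a projection as single-page TIFF, tagging the kind in the name."""
    path = Path(path)
    out = path.with_name(f"{path.stem}_{image.kind}{path.suffix or '.tif'}")
    tifffile.imwrite(out, image.raster, photometric="minisblack")
    return out


def ground_truth_frame(truth: GroundTruth) -> pd.DataFrame:
    rows = []
    for c in truth.cells:
        rows.append({
            "class": c.class_label,
            "x_um": c.start_position[0],
            "y_um": c.start_position[1],
            "radius_um": c.radius_um,
            "velocity_um_s": c.velocity_um_s,
            "peak_intensity": c.peak_intensity,
        })
    return pd.DataFrame(rows)


def write_ground_truth(
    truth: GroundTruth,
    config: AcquisitionConfig,
    csv_path: str | Path,
) -> Path:
    """One row per cell as CSV plus a JSON sidecar with config and seed."""
    csv_path = Path(csv_path)
    ground_truth_frame(truth).to_csv(csv_path, index=False)
    sidecar = {
        "config": dataclasses.asdict(config),
        "seed": truth.seed,
        "n_adherent": truth.n_adherent,
        "n_rolling": truth.n_rolling,
        "overlap_warning": truth.overlap_warning,
    }
    csv_path.with_suffix(".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True)
    )
    return csv_path


def read_donor_csv(path: str | Path) -> pd.DataFrame:
    """Read a donor-level table (schema of DonorRecord)."""
    df = pd.read_csv(path)
    required = {"donor_id", "age_group", "treatment", "adherent_density_mm2",
                "rolling_density_mm2"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(
            f"{path}: donor table missing columns {sorted(missing)}"
        )
    return df
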