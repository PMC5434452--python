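"""Acquisition, detector and run configuration.

Physical conventions used throughout the package:

* positions are (x, y) in micrometres; ``x`` runs across the field
  (the non-flow axis), ``y`` runs along the flow axis;
* rasters are indexed ``[row, col]`` with row ~ y and col ~ x, origin at
  the top-left pixel;
* the flow axis is the shorter (446 μm) field axis, so that the longest
  streak a cell can paint during one acquisition window corresponds to a
  maximum measurable velocity of ≈112 μm/s (446 μm / 4 s).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field


class ConfigError(ValueError):
    """Raised when a configuration value is invalid."""


@dataclass(frozen=True)
class AcquisitionConfig:
    """Geometry and timing of one flow-chamber acquisition.

    Defaults mirror a standard parallel-plate assay: 4 s of imaging at
    30 frames/s from 594 × 446 μm fields under 0.6 dyn/cm² laminar shear,
    six fields per chamber.  Pixel size defaults to 1 μm/px; the camera
    calibration is a free parameter, never hard-coded elsewhere.
    """

    frame_rate: float = 30.0          # frames per second
    duration_s: float = 4.0           # seconds of acquisition
    field_width_um: float = 594.0     # non-flow axis (x)
    field_height_um: float = 446.0    # flow axis (y)
    pixel_size_um: float = 1.0
    shear_stress_dyn_cm2: float = 0.6
    n_fields_per_chamber: int = 6
    max_gray: int = 255               # intensity ceiling (8-bit default)

    def __post_init__(self) -> None:
        if self.frame_rate <= 0 or self.duration_s <= 0:
            raise ConfigError("frame_rate and duration_s must be positive")
        n = self.frame_rate * self.duration_s
        if abs(n - round(n)) > 1e-9 or round(n) < 1:
            raise ConfigError(
                f"frame_rate x duration must be a positive integer frame "
                f"count, got {n}"
            )
        if self.field_width_um <= 0 or self.field_height_um <= 0:
            raise ConfigError("field dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ConfigError("pixel_size_um must be positive")
        if self.shape[0] < 16 or self.shape[1] < 16:
            raise ConfigError("raster must be at least 16 px on each axis")

    @property
    def n_frames(self) -> int:
        """Total frame count (120 at defaults)."""
        return round(self.frame_rate * self.duration_s)

    @property
    def shape(self) -> tuple[int, int]:
        """Raster shape (rows, cols) = (flow axis, non-flow axis)."""
        return (
            round(self.field_height_um / self.pixel_size_um),
            round(self.field_width_um / self.pixel_size_um),
        )

    @property
    def shear_stress_pa(self) -> float:
        # division by 10 (not *0.1) keeps 0.6 dyn/cm2 -> 0.06 Pa exact
        return self.shear_stress_dyn_cm2 / 10.0

    @property
    def field_area_mm2(self) -> float:
        return (self.field_width_um / 1000.0) * (self.field_height_um / 1000.0)

    @property
    def max_velocity_um_s(self) -> float:
        """Geometric cap on measurable rolling velocity.

        A blur is only usable when its start and end both lie inside the
        field, so the longest measurable path equals the field extent along
        the flow axis, giving field_height / duration (111.5 μm/s ≈ 112 at
        defaults).
        """
        return self.field_height_um / self.duration_s

    def describe(self) -> dict:
        """Validator echo: derived quantities a user should sanity-check."""
        return {
            "n_frames": self.n_frames,
            "raster_shape": list(self.shape),
            "shear_stress_pa": self.shear_stress_pa,
            "field_area_mm2": self.field_area_mm2,
            "max_velocity_um_s": float(f"{self.max_velocity_um_s:.3g}"),
        }


@dataclass(frozen=True)
class DetectorConfig:
    """Segmentation gates for cell detection in snapshot/minimum images.

    Threshold = max(Otsu, background + 3*noise_sigma).  Area bounds admit
    discs of roughly 6-22 μm diameter; the circularity gate rejects
    elongated debris and partial streaks.
    """

    background: float | None = None   # None -> estimated as image median
    noise_sigma: float = 2.0          # grayscale units, for the threshold floor
    min_area_um2: float = 25.0
    max_area_um2: float = 400.0
    min_circularity: float = 0.6
    watershed_split_factor: float = 2.0   # split components > factor*max_area

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be non-negative")
        if not 0 < self.min_area_um2 < self.max_area_um2:
            raise ConfigError("need 0 < min_area_um2 < max_area_um2")


@dataclass(frozen=True)
class StreakConfig:
    """Gates and conventions for blur (streak) velocimetry."""

    min_elongation: float = 2.0       # major/minor extent ratio for a streak
    cell_diameter_um: float = 10.0    # fallback width in corrected mode
    corrected_length: bool = True     # False -> raw blur length / time
    use_measured_width: bool = True   # subtract the streak's own width
    orientation_gate_deg: float | None = None  # e.g. 15.0 to enforce alignment
    background: float | None = None
    noise_sigma: float = 2.0
    min_area_um2: float = 50.0        # smallest credible blur footprint

    def __post_init__(self) -> None:
        if self.min_elongation < 1:
            raise ConfigError("min_elongation must be >= 1")
        if self.cell_diameter_um < 0:
            raise ConfigError("cell_diameter_um must be non-negative")


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable description of one end-to-end experiment run."""

    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    streaks: StreakConfig = field(default_factory=StreakConfig)
    presets: tuple[str, ...] = (
        "young_control", "young_LPS", "old_control", "old_LPS",
    )
    n_donors: dict[str, int] = field(
        default_factory=lambda: {"young": 16, "old": 14}
    )
    n_fields: int = 6
    noise_sigma: float = 2.0
    seed: int = 0
    output_dir: str = "flowquant_run"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["presets"] = list(self.presets)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, sub in (
            ("acquisition", AcquisitionConfig),
            ("detector", DetectorConfig),
            ("streaks", StreakConfig),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        if "presets" in d:
            d["presets"] = tuple(d["presets"])
        return cls(**d)
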