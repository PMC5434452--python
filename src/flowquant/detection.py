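"""Cell detection and adherent-vs-rolling classification.

The classifier is projection-based, not a tracker: the snapshot counts
every in-focus cell (adherent + rolling), the 4-second minimum
projection counts only the firmly adherent ones (a cell must sit on the
same pixels in every frame to survive the per-pixel minimum), and the
rolling count is the difference.  Free-stream cells are defocused and
low-contrast, so they fall below the segmentation threshold and are
never counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.segmentation import watershed

from .config import AcquisitionConfig, ConfigError, DetectorConfig
from .projections import MAX, MIN, SNAPSHOT, ProjectionImage, snapshot, temporal_min
from .synth import FrameStack


@dataclass(frozen=True)
class Detection:
    """One segmented cell in a snapshot or minimum image."""

    centroid_um: tuple[float, float]   # (x, y)
    area_um2: float
    equivalent_diameter_um: float
    circularity: float                 # 4*pi*A/P^2, clamped to (0, 1]
    mean_intensity: float


@dataclass(frozen=True)
class FieldQuantification:
    """Per-field counts and densities."""

    total_count: int
    adherent_count: int
    rolling_count: int
    field_area_mm2: float
    adherent_density_mm2: float
    rolling_density_mm2: float
    clamped: bool = False              # True when adherent > total was clamped


def segmentation_threshold(
    raster: np.ndarray, config: DetectorConfig
) -> float:
    """Global threshold: Otsu with a floor at background + 3*noise_sigma.

    The floor guards against Otsu splitting the background when no bright
    object is present; background defaults to the image median.
    """
    bg = config.background if config.background is not None else float(
        np.median(raster)
    )
    floor = bg + 3.0 * config.noise_sigma
    flat = np.asarray(raster, dtype=np.float64)
    if flat.max() == flat.min():
        return max(float(flat.max()), floor)
    return max(float(threshold_otsu(flat)), floor)


def _circularity(prop) -> float:
    p = prop.perimeter
    if p <= 0:
        return 1.0
    return min(4.0 * np.pi * prop.area / (p * p), 1.0)


def segment_cells(
    image: ProjectionImage, config: DetectorConfig | None = None
) -> list[Detection]:
    """Threshold + connected components + area/circularity gates.

    Components more than ``watershed_split_factor`` times the maximum
    single-cell area are split once by watershed on the distance
    transform; split pieces are gated by area only (their perimeters are
    segmentation artefacts, not cell shapes).
    """
    config = config or DetectorConfig()
    if image.kind == MAX:
        raise ConfigError(
            "segment_cells expects a snapshot or min image; streaks in a "
            "max image are not cells"
        )
    px = image.pixel_size_um
    px_area = px * px
    thr = segmentation_threshold(image.raster, config)
    binary = np.asarray(image.raster, dtype=np.float64) > thr
    labels = label(binary)
    detections: list[Detection] = []
    split_limit = config.watershed_split_factor * config.max_area_um2
    for prop in regionprops(labels, intensity_image=image.raster):
        area_um2 = prop.area * px_area
        if area_um2 > split_limit:
            detections.extend(
                _split_component(labels == prop.label, image, config)
            )
            continue
        if not config.min_area_um2 <= area_um2 <= config.max_area_um2:
            continue
        if _circularity(prop) < config.min_circularity:
            continue
        cy, cx = prop.centroid
        detections.append(Detection(
            centroid_um=(cx * px, cy * px),
            area_um2=area_um2,
            equivalent_diameter_um=prop.equivalent_diameter_area * px,
            circularity=_circularity(prop),
            mean_intensity=float(prop.intensity_mean),
        ))
    return detections


def _split_component(
    mask: np.ndarray, image: ProjectionImage, config: DetectorConfig
) -> list[Detection]:
    """One round of distance-transform watershed on an oversized blob."""
    px = image.pixel_size_um
    px_area = px * px
    dist = ndi.distance_transform_edt(mask)
    # seed one marker per local distance maximum at least a radius apart
    min_dist = max(int(np.sqrt(config.min_area_um2 / np.pi) / px), 3)
    footprint = np.ones((2 * min_dist + 1, 2 * min_dist + 1))
    local_max = (dist == ndi.maximum_filter(dist, footprint=footprint)) & mask
    markers, _ = ndi.label(local_max)
    pieces = watershed(-dist, markers, mask=mask)
    out: list[Detection] = []
    for prop in regionprops(pieces, intensity_image=image.raster):
        area_um2 = prop.area * px_area
        if not config.min_area_um2 <= area_um2 <= config.max_area_um2:
            continue
        cy, cx = prop.centroid
        out.append(Detection(
            centroid_um=(cx * px, cy * px),
            area_um2=area_um2,
            equivalent_diameter_um=prop.equivalent_diameter_area * px,
            circularity=_circularity(prop),
            mean_intensity=float(prop.intensity_mean),
        ))
    return out


def density_per_mm2(count: int, config: AcquisitionConfig) -> float:
    """Convert a per-field count to cells per mm² of substrate."""
    if count < 0:
        raise ConfigError("count must be non-negative")
    area = config.field_area_mm2
    if area <= 0:
        raise ConfigError("field area must be positive")
    return count / area


def classify_field(
    stack: FrameStack,
    config: DetectorConfig | None = None,
    snapshot_index: int = 0,
    min_window_s: float = 4.0,
) -> FieldQuantification:
    """Quantify one field: total, firmly adherent, rolling, densities.

    Firm adhesion means stationary for at least ``min_window_s`` seconds,
    so the stack must span at least that window; the minimum projection
    is taken over exactly that window (the first 4 s at defaults).
    Rolling = total - adherent, clamped at zero with a quality flag if
    segmentation noise ever inverts the counts.
    """
    config = config or DetectorConfig()
    acq = stack.config
    duration = stack.n_frames / acq.frame_rate
    if duration < min_window_s - 1e-9:
        raise ConfigError(
            f"stack spans {duration:.2f}s but firm adhesion requires at "
            f"least {min_window_s}s of observation"
        )
    n_window = round(min_window_s * acq.frame_rate)
    window = FrameStack(frames=stack.frames[:n_window], config=acq)

    total = len(segment_cells(snapshot(stack, snapshot_index), config))
    adherent = len(segment_cells(temporal_min(window), config))
    rolling = total - adherent
    clamped = rolling < 0
    if clamped:
        rolling = 0
    area = acq.field_area_mm2
    return FieldQuantification(
        total_count=total,
        adherent_count=adherent,
        rolling_count=rolling,
        field_area_mm2=area,
        adherent_density_mm2=adherent / area,
        rolling_density_mm2=rolling / area,
        clamped=clamped,
    )
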