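"""Synthetic flow-chamber time-lapse generator with ground truth.

Emulates what the microscope sees in a parallel-plate adhesion assay:
phase-bright in-focus monocytes on a dark background — some firmly
adherent (stationary for the whole window), some rolling along the flow
axis at constant velocity — plus dim, strongly defocused free-stream
cells that pass by without touching the substrate, and additive Gaussian
camera noise.  Velocities are imposed, not emergent: there is no
hydrodynamics or bond-kinetics model here.

Every stack carries a :class:`GroundTruth` with the per-cell
specification and the true adherent/rolling counts, defined at frame 0
(cells that enter the field later are not counted, mirroring the
snapshot convention of the assay).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .config import AcquisitionConfig, ConfigError

ADHERENT = "adherent"
ROLLING = "rolling"
FREESTREAM = "freestream"

#: soft-edge width of the rendered disc profile, μm
EDGE_SIGMA_UM = 1.0
#: default rendering intensities on an 8-bit scale
BACKGROUND = 30.0
INFOCUS_PEAK = 120.0
FREESTREAM_PEAK = 15.0
FREESTREAM_BLUR_UM = 8.0
#: minimum centre-to-centre / lane separation used by the scene sampler, μm
MIN_SEPARATION_UM = 25.0


@dataclass(frozen=True)
class CellSpec:
    """One simulated cell: class, kinematics and appearance."""

    class_label: str                    # adherent | rolling | freestream
    start_position: tuple[float, float]  # (x, y) μm at frame 0
    radius_um: float = 5.0
    peak_intensity: float = INFOCUS_PEAK  # above background
    velocity_um_s: float = 0.0          # along the flow (y) axis
    focus_blur_sigma_um: float = 0.0    # 0 = in focus

    def __post_init__(self) -> None:
        if self.class_label not in (ADHERENT, ROLLING, FREESTREAM):
            raise ConfigError(f"unknown class_label {self.class_label!r}")
        if self.class_label == ADHERENT and self.velocity_um_s != 0:
            raise ConfigError("adherent cells must have zero velocity")
        if self.class_label == ROLLING and self.velocity_um_s <= 0:
            raise ConfigError("rolling cells need positive velocity")
        if self.class_label == FREESTREAM and self.focus_blur_sigma_um <= 0:
            raise ConfigError("freestream cells must be defocused")

    @property
    def in_focus(self) -> bool:
        return self.class_label in (ADHERENT, ROLLING)

    def position_at(self, t: float) -> tuple[float, float]:
        x, y = self.start_position
        return (x, y + self.velocity_um_s * t)


@dataclass(frozen=True)
class GroundTruth:
    """True per-field composition, evaluated at frame 0."""

    cells: tuple[CellSpec, ...]
    n_adherent: int
    n_rolling: int
    rolling_velocities: tuple[float, ...]
    seed: int | None = None
    overlap_warning: bool = False

    @property
    def n_in_focus(self) -> int:
        return self.n_adherent + self.n_rolling


@dataclass
class FrameStack:
    """A time-ordered stack of equal-sized grayscale frames.

    ``frames`` is a (T, H, W) array; H spans the flow axis (y), W the
    non-flow axis (x).
    """

    frames: np.ndarray
    config: AcquisitionConfig

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ConfigError("frames must be a (T, H, W) array")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


def _in_field(cell: CellSpec, config: AcquisitionConfig) -> bool:
    x, y = cell.start_position
    return (0 <= x < config.field_width_um) and (0 <= y < config.field_height_um)


def scene_ground_truth(
    scene: list[CellSpec],
    config: AcquisitionConfig,
    seed: int | None = None,
) -> GroundTruth:
    """Derive the true counts from a cell list without rendering anything.

    Counts are a frame-0 snapshot: only in-focus cells whose centre lies
    inside the field at t=0 contribute.  Adherent cells closer than one
    diameter raise the overlap warning flag (counts may then disagree
    with what a segmenter can resolve).
    """
    counted = [c for c in scene if c.in_focus and _in_field(c, config)]
    n_adh = sum(c.class_label == ADHERENT for c in counted)
    rolling = [c for c in counted if c.class_label == ROLLING]
    adherent = [c for c in counted if c.class_label == ADHERENT]
    overlap = False
    for i in range(len(adherent)):
        for j in range(i + 1, len(adherent)):
            a, b = adherent[i], adherent[j]
            d = np.hypot(
                a.start_position[0] - b.start_position[0],
                a.start_position[1] - b.start_position[1],
            )
            if d < a.radius_um + b.radius_um:
                overlap = True
    return GroundTruth(
        cells=tuple(scene),
        n_adherent=n_adh,
        n_rolling=len(rolling),
        rolling_velocities=tuple(c.velocity_um_s for c in rolling),
        seed=seed,
        overlap_warning=overlap,
    )


def _render_cell(frame: np.ndarray, cell: CellSpec, t: float,
                 config: AcquisitionConfig) -> None:
    """Additively paint one cell onto a float frame (in place)."""
    px = config.pixel_size_um
    x_um, y_um = cell.position_at(t)
    if cell.in_focus:
        extent = cell.radius_um + 4.0 * EDGE_SIGMA_UM
    else:
        extent = 3.5 * cell.focus_blur_sigma_um
    h, w = frame.shape
    r0 = max(int((y_um - extent) / px), 0)
    r1 = min(int((y_um + extent) / px) + 2, h)
    c0 = max(int((x_um - extent) / px), 0)
    c1 = min(int((x_um + extent) / px) + 2, w)
    if r0 >= r1 or c0 >= c1:
        return
    rows = (np.arange(r0, r1) + 0.5) * px
    cols = (np.arange(c0, c1) + 0.5) * px
    d = np.hypot(cols[None, :] - x_um, rows[:, None] - y_um)
    if cell.in_focus:
        # flat-topped disc with a Gaussian shoulder outside the radius
        over = np.clip(d - cell.radius_um, 0.0, None)
        profile = np.exp(-(over ** 2) / (2.0 * EDGE_SIGMA_UM ** 2))
    else:
        profile = np.exp(-(d ** 2) / (2.0 * cell.focus_blur_sigma_um ** 2))
    frame[r0:r1, c0:c1] += cell.peak_intensity * profile


def generate_field_stack(
    scene: list[CellSpec],
    config: AcquisitionConfig | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    background: float = BACKGROUND,
) -> tuple[FrameStack, GroundTruth]:
    """Render a scene into a time-lapse stack with known ground truth.

    Deterministic for a fixed ``seed``.  Rolling cells translate along
    the flow (y) axis at constant velocity; noise is additive Gaussian,
    clipped to [0, max_gray]; output is 8-bit for max_gray <= 255, else
    16-bit.
    """
    config = config or AcquisitionConfig()
    if noise_sigma < 0:
        raise ConfigError("noise_sigma must be non-negative")
    rng = np.random.default_rng(seed)
    h, w = config.shape
    dtype = np.uint8 if config.max_gray <= 255 else np.uint16
    frames = np.empty((config.n_frames, h, w), dtype=dtype)
    for i in range(config.n_frames):
        t = i / config.frame_rate
        frame = np.full((h, w), background, dtype=np.float64)
        for cell in scene:
            _render_cell(frame, cell, t, config)
        if noise_sigma > 0:
            frame += rng.normal(0.0, noise_sigma, size=frame.shape)
        np.clip(frame, 0, config.max_gray, out=frame)
        frames[i] = np.round(frame).astype(dtype)
    truth = scene_ground_truth(scene, config, seed=seed)
    return FrameStack(frames=frames, config=config), truth


# ---------------------------------------------------------------------------
# scene sampling

def draw_scene(
    n_adherent: int,
    n_rolling: int,
    config: AcquisitionConfig,
    rng: np.random.Generator,
    velocities: list[float] | None = None,
    n_freestream: int = 4,
    radius_um: float = 5.0,
    min_separation_um: float = MIN_SEPARATION_UM,
) -> list[CellSpec]:
    """Place cells at random, keeping in-focus objects resolvable.

    Rolling cells sweep a vertical corridor, so their x lanes are kept at
    least ``min_separation_um`` from every other in-focus cell; adherent
    cells keep the same centre-to-centre distance from each other.  If a
    position cannot be found in 200 draws it is placed anyway (the
    ground-truth overlap flag then reports the risk).
    """
    w, hgt = config.field_width_um, config.field_height_um
    margin = radius_um + 2.0
    cells: list[CellSpec] = []
    lanes: list[float] = []       # x of every placed in-focus cell
    points: list[tuple[float, float]] = []

    if velocities is None:
        velocities = list(rng.uniform(10.0, 60.0, size=n_rolling))
    if len(velocities) != n_rolling:
        raise ConfigError("velocities length must equal n_rolling")

    def lane_ok(x: float) -> bool:
        return all(abs(x - lx) >= min_separation_um for lx in lanes)

    def point_ok(x: float, y: float) -> bool:
        return lane_ok(x) and all(
            np.hypot(x - px, y - py) >= min_separation_um for px, py in points
        )

    for v in velocities:
        for _ in range(200):
            x = rng.uniform(margin, w - margin)
            y = rng.uniform(margin, hgt - margin)
            if lane_ok(x):
                break
        cells.append(CellSpec(ROLLING, (x, y), radius_um=radius_um,
                              velocity_um_s=float(v)))
        lanes.append(x)
        points.append((x, y))
    for _ in range(n_adherent):
        for _ in range(200):
            x = rng.uniform(margin, w - margin)
            y = rng.uniform(margin, hgt - margin)
            if point_ok(x, y):
                break
        cells.append(CellSpec(ADHERENT, (x, y), radius_um=radius_um))
        lanes.append(x)
        points.append((x, y))
    for _ in range(n_freestream):
        x = rng.uniform(0, w)
        y = rng.uniform(0, hgt)
        cells.append(CellSpec(
            FREESTREAM, (x, y), radius_um=radius_um,
            peak_intensity=FREESTREAM_PEAK,
            velocity_um_s=float(rng.uniform(150.0, 400.0)),
            focus_blur_sigma_um=FREESTREAM_BLUR_UM,
        ))
    return cells


def figure_example_scene(
    config: AcquisitionConfig | None = None,
    seed: int = 0,
) -> list[CellSpec]:
    """The worked single-field example: 10 in-focus cells, 6 stationary.

    Four cells roll at 20-60 μm/s; a few defocused free-stream cells pass
    through without appearing in the snapshot.
    """
    config = config or AcquisitionConfig()
    rng = np.random.default_rng(seed)
    velocities = list(rng.uniform(20.0, 60.0, size=4))
    return draw_scene(6, 4, config, rng, velocities=velocities,
                      n_freestream=3)


# ---------------------------------------------------------------------------
# cohort presets

@dataclass(frozen=True)
class GroupPreset:
    """Printed group-level summary statistics used to parameterize donors.

    ``*_sem`` are standard errors of the mean; the donor-level SD is
    reconstructed as SEM * sqrt(n_group), and the cell-level velocity SD
    as SEM * sqrt(n_cells) because velocity summaries pool individual
    rolling cells (150-207 per condition) rather than donors.
    """

    adherent_mean: float
    adherent_sem: float
    rolling_mean: float
    rolling_sem: float
    velocity_mean: float
    velocity_sem: float
    n_group: int
    n_velocity_cells: int = 178


PRESETS: dict[str, GroupPreset] = {
    "young_control": GroupPreset(15.0, 2.0, 15.0, 1.0, 28.7, 0.5, 16),
    "old_control": GroupPreset(19.0, 2.0, 16.0, 2.0, 27.0, 0.5, 14),
    "young_LPS": GroupPreset(19.0, 2.0, 15.0, 2.0, 30.3, 0.6, 16),
    "old_LPS": GroupPreset(26.0, 1.0, 14.0, 2.0, 27.0, 0.6, 14),
    # scenario labels without printed means; see docs/methods.md
    "young_uncoated": GroupPreset(0.5, 0.3, 3.0, 1.0, 30.0, 1.0, 16),
    "old_uncoated": GroupPreset(0.5, 0.3, 3.0, 1.0, 30.0, 1.0, 14),
    "young_antiCD11c": GroupPreset(6.0, 2.0, 15.0, 1.0, 28.7, 0.5, 4),
    "old_antiCD11c": GroupPreset(8.0, 2.0, 16.0, 2.0, 27.0, 0.5, 5),
    "young_Mg2plus": GroupPreset(19.0, 2.0, 15.0, 1.0, 28.7, 0.5, 4),
    "old_Mg2plus": GroupPreset(19.0, 2.0, 16.0, 2.0, 27.0, 0.5, 5),
}


@dataclass
class DonorScenes:
    """One simulated donor: metadata, expectations and per-field scenes."""

    donor_id: str
    age_group: str
    gender: str
    treatment: str
    expected_adherent_mm2: float
    expected_rolling_mm2: float
    field_scenes: list[list[CellSpec]]
    field_seeds: list[int]

    def ground_truths(self, config: AcquisitionConfig) -> list[GroundTruth]:
        return [
            scene_ground_truth(s, config, seed=seed)
            for s, seed in zip(self.field_scenes, self.field_seeds)
        ]


def _split_preset(name: str) -> tuple[str, str]:
    age, _, treatment = name.partition("_")
    if name not in PRESETS:
        raise ConfigError(
            f"unknown preset {name!r}; known: {sorted(PRESETS)}"
        )
    return age, treatment


def cohort_preset(
    group: str,
    n_donors: int,
    seed: int = 0,
    config: AcquisitionConfig | None = None,
    n_fields: int | None = None,
) -> list[DonorScenes]:
    """Draw a synthetic donor cohort for one age x treatment scenario.

    Per-donor expected densities are Normal around the group mean with
    SD = SEM * sqrt(n_group), truncated at zero; per-field counts are
    Poisson around donor expectation x field area; rolling velocities are
    Normal around the group velocity mean with the reconstructed
    cell-level SD, truncated to (0.5, geometric cap).

    Seeds: each donor gets an independent stream from
    ``SeedSequence([seed, donor_index])``; each field derives its render
    seed from ``(donor stream, field_index)`` so any single field is
    reproducible on its own.
    """
    age, treatment = _split_preset(group)
    preset = PRESETS[group]
    config = config or AcquisitionConfig()
    if n_fields is None:
        n_fields = config.n_fields_per_chamber
    area = config.field_area_mm2
    cap = config.max_velocity_um_s
    vel_sd = preset.velocity_sem * np.sqrt(preset.n_velocity_cells)
    donor_sd_adh = preset.adherent_sem * np.sqrt(preset.n_group)
    donor_sd_roll = preset.rolling_sem * np.sqrt(preset.n_group)

    donors: list[DonorScenes] = []
    for d in range(n_donors):
        ss = np.random.SeedSequence([seed, d])
        rng = np.random.default_rng(ss)
        exp_adh = max(float(rng.normal(preset.adherent_mean, donor_sd_adh)), 0.0)
        exp_roll = max(float(rng.normal(preset.rolling_mean, donor_sd_roll)), 0.0)
        gender = "female" if rng.random() < 0.5 else "male"
        scenes, seeds = [], []
        for f in range(n_fields):
            field_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
            frng = np.random.default_rng(field_seed)
            n_adh = int(frng.poisson(exp_adh * area))
            n_roll = int(frng.poisson(exp_roll * area))
            vels = []
            while len(vels) < n_roll:
                v = frng.normal(preset.velocity_mean, vel_sd)
                if 0.5 < v < cap:
                    vels.append(float(v))
            scenes.append(draw_scene(n_adh, n_roll, config, frng,
                                     velocities=vels))
            seeds.append(field_seed)
        donors.append(DonorScenes(
            donor_id=f"{group}_d{d:03d}",
            age_group=age,
            gender=gender,
            treatment=treatment,
            expected_adherent_mm2=exp_adh,
            expected_rolling_mm2=exp_roll,
            field_scenes=scenes,
            field_seeds=seeds,
        ))
    return donors
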