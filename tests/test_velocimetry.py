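"""Streak segmentation, completeness filtering and velocity arithmetic."""

import numpy as np
import pytest

from flowquant import (
    CellSpec,
    ConfigError,
    Streak,
    StreakConfig,
    filter_complete_streaks,
    generate_field_stack,
    measure_field_velocities,
    segment_streaks,
    snapshot,
    streak_velocity,
    summarize_velocities,
    temporal_max,
)


def make_streak(major, minor=10.0, border=False, ambiguous=False):
    return Streak(major_length_um=major, minor_width_um=minor,
                  touches_border=border, orientation_deg=0.0,
                  ambiguous=ambiguous)


def test_stationary_disc_is_not_a_streak(config):
    scene = [CellSpec("adherent", (200.0, 200.0))]
    stack, _ = generate_field_stack(scene, config, noise_sigma=0, seed=0)
    assert segment_streaks(temporal_max(stack)) == []


def test_single_roller_blur_geometry(config):
    """27 um/s for the painted span leaves a blur of path + diameter."""
    cell = CellSpec("rolling", (300.0, 150.0), radius_um=5.0,
                    velocity_um_s=27.0)
    stack, _ = generate_field_stack([cell], config, noise_sigma=0, seed=0)
    streaks = segment_streaks(temporal_max(stack))
    assert len(streaks) == 1
    s = streaks[0]
    span = (stack.n_frames - 1) / config.frame_rate
    expected = 27.0 * span + 2 * 5.0
    assert s.major_length_um == pytest.approx(expected, abs=3.0)
    assert not s.touches_border
    assert abs(s.orientation_deg) < 5.0


def test_streak_leaving_field_touches_border(config):
    cell = CellSpec("rolling", (300.0, 350.0), velocity_um_s=60.0)  # exits
    stack, _ = generate_field_stack([cell], config, noise_sigma=0, seed=0)
    streaks = segment_streaks(temporal_max(stack))
    assert len(streaks) == 1
    assert streaks[0].touches_border
    assert filter_complete_streaks(streaks) == []


def test_non_max_image_rejected(config):
    cell = CellSpec("rolling", (300.0, 100.0), velocity_um_s=30.0)
    stack, _ = generate_field_stack([cell], config, noise_sigma=0, seed=0)
    with pytest.raises(ConfigError):
        segment_streaks(snapshot(stack))


def test_completeness_filter_is_a_pure_predicate():
    interior = [make_streak(100), make_streak(80), make_streak(60)]
    border = [make_streak(120, border=True)]
    mixed = [interior[0], border[0], interior[1], interior[2]]
    assert filter_complete_streaks(interior) == interior
    assert filter_complete_streaks(border) == []
    kept = filter_complete_streaks(mixed)
    assert kept == [interior[0], interior[1], interior[2]]  # order preserved
    assert filter_complete_streaks(kept) == kept             # idempotent


def test_velocity_arithmetic():
    # corrected blur length of 120 um over 4 s -> 30 um/s
    m = streak_velocity(make_streak(130.0, minor=10.0), 4.0)
    assert m.velocity_um_s == pytest.approx(30.0)
    raw = streak_velocity(make_streak(130.0), 4.0, corrected=False)
    assert raw.velocity_um_s == pytest.approx(32.5)
    fixed = streak_velocity(make_streak(130.0, minor=12.0), 4.0,
                            cell_diameter_um=10.0, use_measured_width=False)
    assert fixed.velocity_um_s == pytest.approx(30.0)


def test_velocity_floor_and_cap():
    tiny = streak_velocity(make_streak(8.0, minor=10.0), 4.0)
    assert tiny.velocity_um_s == 0.0
    over = streak_velocity(make_streak(500.0, minor=10.0), 4.0,
                           cap_um_s=111.5)
    assert over.exceeds_cap
    with pytest.raises(ConfigError):
        streak_velocity(make_streak(100.0), 0.0)


def test_roller_velocities_recovered(config):
    rng = np.random.default_rng(8)
    vels = [15.0, 30.0, 45.0, 60.0, 75.0, 90.0]
    xs = np.linspace(40, 550, len(vels))
    scene = []
    for x, v in zip(xs, vels):
        y0 = rng.uniform(8, config.field_height_um - v * 4 - 8)
        scene.append(CellSpec("rolling", (float(x), float(y0)),
                              velocity_um_s=v))
    stack, truth = generate_field_stack(scene, config, noise_sigma=0, seed=0)
    measured = sorted(m.velocity_um_s
                      for m in measure_field_velocities(stack))
    tol = 2 * config.pixel_size_um / config.duration_s
    for m, t in zip(measured, sorted(truth.rolling_velocities)):
        assert abs(m - t) <= tol


def test_no_measurement_exceeds_geometric_cap(config):
    rng = np.random.default_rng(9)
    scene = []
    for x in np.linspace(40, 550, 8):
        v = float(rng.uniform(20, 105))
        y0 = float(rng.uniform(2, config.field_height_um - 12))
        scene.append(CellSpec("rolling", (x, y0), velocity_um_s=v))
    stack, _ = generate_field_stack(scene, config, noise_sigma=0, seed=4)
    cap = config.max_velocity_um_s
    for m in measure_field_velocities(stack):
        assert m.velocity_um_s <= cap


def test_crossing_blur_flagged_ambiguous(config):
    """A roller clipping a laterally offset adherent cell merges into one
    component with a bulged width profile; it must be excluded, not
    mis-measured.  (A cell perfectly centred in the lane is swallowed by
    the blur and is invisible to any width-based check.)"""
    roller = CellSpec("rolling", (300.0, 60.0), velocity_um_s=40.0)
    parked = CellSpec("adherent", (310.0, 150.0))  # half-overlaps the lane
    stack, _ = generate_field_stack([roller, parked], config,
                                    noise_sigma=0, seed=0)
    streaks = segment_streaks(temporal_max(stack))
    assert any(s.ambiguous for s in streaks)
    assert measure_field_velocities(stack) == []


def test_summarize_velocities():
    one = summarize_velocities([streak_velocity(make_streak(50), 4.0)])
    assert one.n == 1 and one.sem == 0.0
    vals = [10.0, 20.0, 30.0]
    ms = [streak_velocity(make_streak(v * 4 + 10), 4.0) for v in vals]
    s = summarize_velocities(ms)
    assert s.n == 3
    assert s.mean == pytest.approx(20.0)
    assert s.sem == pytest.approx(10.0 / np.sqrt(3), abs=1e-4)
    empty = summarize_velocities([])
    assert empty.n == 0 and np.isnan(empty.mean)


def test_over_cap_excluded_from_summary():
    good = streak_velocity(make_streak(90.0), 4.0)
    bad = streak_velocity(make_streak(500.0), 4.0, cap_um_s=111.5)
    s = summarize_velocities([good, bad])
    assert s.n == 1
    assert s.mean == pytest.approx(good.velocity_um_s)
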