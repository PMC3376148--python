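"""Gel densitometry: background, band detection, calibration, sizing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fragmatch as fm
from fragmatch.sim import _migration


def _profile(intensities, meta=""):
    return fm.LaneProfile(np.arange(len(intensities), dtype=float), intensities, meta)


def test_background_of_constant_profile_is_zero():
    prof = _profile(np.full(100, 7.5))
    out = fm.subtract_background(prof, window=10)
    assert np.allclose(out.intensities, 0.0)


def test_background_preserves_isolated_peak():
    x = np.arange(200, dtype=float)
    peak = 100 * np.exp(-0.5 * ((x - 90) / 4) ** 2)
    out = fm.subtract_background(_profile(peak), window=40)
    assert out.intensities[90] == pytest.approx(peak[90], rel=0.01)


def test_background_removes_linear_ramp_under_peak():
    x = np.arange(300, dtype=float)
    ramp = 0.2 * x
    peak = 150 * np.exp(-0.5 * ((x - 140) / 5) ** 2)
    out = fm.subtract_background(_profile(ramp + peak), window=60)
    assert int(np.argmax(out.intensities)) == 140
    # residual baseline far from the peak is small relative to the apex
    far = np.concatenate([out.intensities[:100], out.intensities[180:]])
    assert far.max() < 0.05 * out.intensities[140]


def test_background_window_must_fit():
    with pytest.raises(fm.DomainError):
        fm.subtract_background(_profile(np.ones(50)), window=100)


def test_background_idempotent():
    x = np.arange(250, dtype=float)
    signal = 80 * np.exp(-0.5 * ((x - 60) / 3) ** 2) + 50 * np.exp(
        -0.5 * ((x - 180) / 4) ** 2
    )
    once = fm.subtract_background(_profile(signal), window=60)
    twice = fm.subtract_background(once, window=60)
    assert np.allclose(once.intensities, twice.intensities)


def test_detect_ladder_bands_recovers_rendered_band_centers():
    render = fm.simulate_gel_lane(400, seed=5)
    true_d = _migration(
        np.asarray(render.ladder.band_sizes_bp), render.migration_a, render.migration_b
    )
    found = fm.detect_ladder_bands(render.ladder_profile, expected_n=len(render.ladder))
    assert len(found) == len(true_d)
    assert np.all(np.abs(found - np.sort(true_d)) <= 1.0)


def test_detect_ladder_bands_flat_lane_errors():
    with pytest.raises(fm.BandDetectionError):
        fm.detect_ladder_bands(_profile(np.zeros(100)), expected_n=3)


def test_detect_ladder_bands_reports_merged_bands():
    """Two bands rendered too close to resolve -> error naming the count."""
    x = np.arange(400, dtype=float)
    centers = np.linspace(40, 360, 12)
    centers[5] = centers[4] + 1.0  # merge bands 5 and 6
    trace = np.zeros_like(x)
    for c in centers:
        trace += 500 * np.exp(-0.5 * ((x - c) / 2.0) ** 2)
    with pytest.raises(fm.BandDetectionError) as err:
        fm.detect_ladder_bands(_profile(trace), expected_n=12)
    assert len(err.value.found_positions) == 11


def test_calibration_inverts_log_linear_migration():
    ladder = fm.LadderSpec()
    sizes = np.asarray(ladder.band_sizes_bp)  # descending bp
    positions = 600 - 250 * np.log10(sizes)  # increasing migration
    cal = fm.calibrate(positions, ladder)
    d350 = 600 - 250 * np.log10(350)
    assert cal.bp_at(d350) == pytest.approx(350, rel=0.005)
    # anchors map back exactly
    for pos, bp in zip(positions, sizes):
        assert cal.bp_at(pos) == pytest.approx(bp, rel=1e-12)


def test_calibration_extrapolates_and_flags_beyond_anchors():
    ladder = fm.LadderSpec((100, 300, 1000))
    positions = 600 - 250 * np.log10(np.asarray(ladder.band_sizes_bp))
    cal = fm.calibrate(positions, ladder)
    beyond = positions[-1] + 10.0
    assert not cal.in_range(beyond)
    # end-segment slope extended: still the generating law here
    assert cal.bp_at(beyond) == pytest.approx(10 ** ((600 - beyond) / 250), rel=1e-9)
    with pytest.raises(fm.DomainError):
        cal.bp_at(beyond, extrapolate=False)


def test_calibrate_rejects_count_mismatch_and_disorder():
    ladder = fm.LadderSpec((100, 300, 1000))
    with pytest.raises(fm.DomainError):
        fm.calibrate([10.0, 20.0], ladder)
    with pytest.raises(fm.DomainError):
        fm.calibrate([10.0, 30.0, 20.0], ladder)


@settings(max_examples=50, derandomize=True)
@given(
    a=st.floats(500, 900),
    b=st.floats(100, 300),
    seed=st.integers(0, 10_000),
)
def test_calibration_monotone_decreasing(a, b, seed):
    rng = np.random.default_rng(seed)
    sizes = np.sort(rng.uniform(80, 2000, size=6))[::-1]
    sizes = np.unique(sizes)[::-1]
    if len(sizes) < 3:
        return
    positions = a - b * np.log10(sizes)
    cal = fm.calibrate(positions, fm.LadderSpec(tuple(sizes)))
    grid = np.linspace(positions[0], positions[-1], 200)
    assert np.all(np.diff(cal.bp_at(grid)) < 0)


def test_mode_size_at_calibrated_anchor():
    ladder = fm.LadderSpec()
    positions = 850 - 250 * np.log10(np.asarray(ladder.band_sizes_bp))
    cal = fm.calibrate(positions, ladder)
    x = np.arange(420, dtype=float)
    d500 = 850 - 250 * np.log10(500)
    lane = _profile(1000 * np.exp(-0.5 * ((x - d500) / 10) ** 2))
    assert fm.mode_fragment_size(lane, cal) == pytest.approx(500, abs=1.0)


def test_mode_size_zero_lane_errors():
    ladder = fm.LadderSpec((100, 300, 1000))
    cal = fm.calibrate([100.0, 200.0, 300.0], ladder)
    with pytest.raises(fm.NoSmearError):
        fm.mode_fragment_size(_profile(np.zeros(350)), cal)


def test_mode_size_reports_prominence_and_range_flag():
    render = fm.simulate_gel_lane(400, seed=9)
    bands = fm.detect_ladder_bands(render.ladder_profile, len(render.ladder))
    cal = fm.calibrate(bands, render.ladder)
    bp, details = fm.mode_fragment_size(render.sample_profile, cal, full_output=True)
    assert details["prominence"] > 0
    assert details["in_calibration_range"]


def test_extract_lane_profile_isolates_each_lane():
    render = fm.simulate_gel_lane(315, seed=3)
    ladder = fm.extract_lane_profile(render.image, render.ladder_bounds)
    sample = fm.extract_lane_profile(render.image, render.sample_bounds)
    assert np.allclose(ladder.intensities, render.ladder_profile.intensities)
    assert np.allclose(sample.intensities, render.sample_profile.intensities)


def test_extract_lane_profile_bounds_checked():
    img = np.zeros((50, 10))
    with pytest.raises(fm.DomainError):
        fm.extract_lane_profile(img, (8, 20))
    with pytest.raises(fm.DomainError):
        fm.extract_lane_profile(img, (5, 5))


def test_end_to_end_sizing_error_small():
    """Simulated lanes across the usable range size back within a few %."""
    rng = np.random.default_rng(17)
    errs = []
    for _ in range(25):
        mode = rng.uniform(120, 900)
        render = fm.simulate_gel_lane(mode, seed=int(rng.integers(2**31)))
        bands = fm.detect_ladder_bands(render.ladder_profile, len(render.ladder))
        cal = fm.calibrate(bands, render.ladder)
        bp = fm.mode_fragment_size(render.sample_profile, cal)
        errs.append(abs(bp - mode) / mode)
    assert np.median(errs) <= 0.03
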