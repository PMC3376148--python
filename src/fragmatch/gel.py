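"""Gel densitometry: lane profiles, ladder calibration, mode fragment size.

Converts a 1-D gel lane intensity trace into a mode fragment size (bp) the
way an ImageJ gel analysis does: detect the ladder bands, build a monotone
migration -> size calibration, and read the sample smear's maximum-intensity
position through it.  Migration physics is assumed only to be monotone; the
calibration interpolates piecewise-linearly in log10(bp) versus migration
distance, which is exact under the classic log-linear mobility law
d = A - B*log10(bp) and robust to deviations from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import minimum_filter1d, uniform_filter1d
from scipy.signal import find_peaks, peak_prominences

from .errors import BandDetectionError, DomainError, NoSmearError

__all__ = [
    "LaneProfile",
    "LadderSpec",
    "SizeCalibration",
    "DEFAULT_LADDER_BP",
    "subtract_background",
    "detect_ladder_bands",
    "calibrate",
    "mode_fragment_size",
    "extract_lane_profile",
]

#: Default 100 bp ladder band sizes (bp).  The cited commercial ladder's
#: sizes are vendor-derived and configurable, not hard physics.
DEFAULT_LADDER_BP = (100, 200, 300, 400, 500, 600, 700, 800, 900, 1000, 1200, 1517)

_MIN_PROFILE_SAMPLES = 16


@dataclass(frozen=True)
class LaneProfile:
    """A 1-D gel intensity trace along the migration axis."""

    positions: np.ndarray
    intensities: np.ndarray
    meta: str = ""

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "intensities", inten)
        if pos.ndim != 1 or inten.ndim != 1 or len(pos) != len(inten):
            raise DomainError("positions and intensities must be equal-length 1-D")
        if len(pos) < _MIN_PROFILE_SAMPLES:
            raise DomainError(
                f"lane profile needs >= {_MIN_PROFILE_SAMPLES} samples, got {len(pos)}"
            )
        if np.any(np.diff(pos) <= 0):
            raise DomainError("positions must be strictly increasing")
        if np.any(inten < 0):
            raise DomainError("intensities must be non-negative")

    @property
    def span(self) -> float:
        return float(self.positions[-1] - self.positions[0])

    def smoothed(self, width: int = 5) -> "LaneProfile":
        """Moving-average smoothed copy (off by default in the pipeline)."""
        if width < 1:
            raise DomainError("smoothing width must be >= 1")
        return LaneProfile(
            self.positions,
            uniform_filter1d(self.intensities, size=int(width), mode="nearest"),
            self.meta,
        )


@dataclass(frozen=True)
class LadderSpec:
    """Known band sizes of a molecular-weight ladder.

    Stored in decreasing bp order, i.e. in order of increasing migration
    distance (small fragments travel farthest).
    """

    band_sizes_bp: tuple = DEFAULT_LADDER_BP

    def __post_init__(self):
        sizes = tuple(float(s) for s in self.band_sizes_bp)
        if len(sizes) < 3:
            raise DomainError("ladder needs >= 3 bands")
        if len(set(sizes)) != len(sizes):
            raise DomainError("ladder band sizes must be distinct")
        if any(s <= 0 for s in sizes):
            raise DomainError("ladder band sizes must be positive")
        object.__setattr__(self, "band_sizes_bp", tuple(sorted(sizes, reverse=True)))

    def __len__(self) -> int:
        return len(self.band_sizes_bp)


@dataclass(frozen=True)
class SizeCalibration:
    """Monotone migration-distance -> fragment-size mapping.

    Piecewise-linear in (migration, log10 bp) through the ladder anchors;
    linear extrapolation of the end segments in log-size beyond the anchor
    range, flagged via :meth:`in_range`.
    """

    anchor_positions: np.ndarray
    anchor_bp: np.ndarray
    interpolation: str = "piecewise-linear-log10"

    def __post_init__(self):
        pos = np.asarray(self.anchor_positions, dtype=float)
        bp = np.asarray(self.anchor_bp, dtype=float)
        object.__setattr__(self, "anchor_positions", pos)
        object.__setattr__(self, "anchor_bp", bp)
        if len(pos) != len(bp) or len(pos) < 2:
            raise DomainError("need >= 2 matching anchors")
        if np.any(np.diff(pos) <= 0):
            raise DomainError("anchor positions must be strictly increasing")
        if np.any(np.diff(bp) >= 0):
            raise DomainError("bp must strictly decrease with migration")

    def in_range(self, position) -> np.ndarray:
        """True where ``position`` lies within the anchor range."""
        p = np.asarray(position, dtype=float)
        return (p >= self.anchor_positions[0]) & (p <= self.anchor_positions[-1])

    def bp_at(self, position, extrapolate: bool = True):
        """Fragment size (bp) at a migration position.

        Outside the anchor range the end-segment slope is extended in
        log10(bp); callers should check :meth:`in_range` and treat
        extrapolated values as flagged.
        """
        p = np.atleast_1d(np.asarray(position, dtype=float))
        if not extrapolate and not np.all(self.in_range(p)):
            raise DomainError("position outside calibration range")
        x = self.anchor_positions
        logy = np.log10(self.anchor_bp)
        out = np.interp(p, x, logy)
        # np.interp clamps; extend end segments linearly instead.
        left = p < x[0]
        right = p > x[-1]
        if np.any(left):
            slope = (logy[1] - logy[0]) / (x[1] - x[0])
            out[left] = logy[0] + slope * (p[left] - x[0])
        if np.any(right):
            slope = (logy[-1] - logy[-2]) / (x[-1] - x[-2])
            out[right] = logy[-1] + slope * (p[right] - x[-1])
        bp = 10.0**out
        return float(bp[0]) if np.isscalar(position) or np.ndim(position) == 0 else bp

    def __call__(self, position, extrapolate: bool = True):
        return self.bp_at(position, extrapolate=extrapolate)


def subtract_background(profile: LaneProfile, window: float) -> LaneProfile:
    """Remove a rolling-minimum baseline from a lane profile.

    ``window`` is a length in position units; the baseline at each point is
    the minimum intensity within +/- window/2, and the result is clipped at
    zero.  A constant profile maps to all zeros.
    """
    if window <= 0:
        raise DomainError("window must be positive")
    if window >= profile.span:
        raise DomainError(
            f"window ({window:g}) must be shorter than the profile span "
            f"({profile.span:g})"
        )
    spacing = float(np.median(np.diff(profile.positions)))
    size = max(int(round(window / spacing)), 2)
    baseline = minimum_filter1d(profile.intensities, size=size, mode="nearest")
    corrected = np.clip(profile.intensities - baseline, 0.0, None)
    return LaneProfile(profile.positions, corrected, profile.meta)


def _parabolic_apex(positions: np.ndarray, intensities: np.ndarray, idx: int):
    """3-point parabolic refinement of a discrete peak apex.

    Returns (refined_position, refined_intensity); falls back to the grid
    point at profile edges or degenerate curvature.
    """
    if idx <= 0 or idx >= len(intensities) - 1:
        return float(positions[idx]), float(intensities[idx])
    y0, y1, y2 = intensities[idx - 1], intensities[idx], intensities[idx + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0 or not np.isfinite(denom):
        return float(positions[idx]), float(y1)
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    # local spacing; grids may be non-uniform
    if delta >= 0:
        step = positions[idx + 1] - positions[idx]
    else:
        step = positions[idx] - positions[idx - 1]
    pos = float(positions[idx] + delta * step)
    height = float(y1 - 0.25 * (y0 - y2) * delta)
    return pos, height


def detect_ladder_bands(
    profile: LaneProfile,
    expected_n: int,
    min_prominence_frac: float = 0.02,
) -> np.ndarray:
    """Locate ladder band apices in a background-subtracted ladder lane.

    Finds local maxima with prominence >= ``min_prominence_frac`` of the
    profile maximum, keeps the ``expected_n`` most prominent, and refines
    each apex parabolically.  Raises :class:`BandDetectionError` listing the
    found peaks when fewer than ``expected_n`` resolve.
    """
    if expected_n < 1:
        raise DomainError("expected_n must be >= 1")
    inten = profile.intensities
    peak_floor = float(np.max(inten)) * min_prominence_frac if np.max(inten) > 0 else 0.0
    if peak_floor <= 0:
        raise BandDetectionError(
            f"no resolvable bands (flat lane); expected {expected_n}", []
        )
    idx, props = find_peaks(inten, prominence=peak_floor)
    if len(idx) < expected_n:
        found = [
            _parabolic_apex(profile.positions, inten, i)[0] for i in idx
        ]
        raise BandDetectionError(
            f"found {len(idx)} resolvable bands, expected {expected_n}", found
        )
    order = np.argsort(props["prominences"])[::-1][:expected_n]
    chosen = np.sort(idx[order])
    refined = np.array(
        [_parabolic_apex(profile.positions, inten, i)[0] for i in chosen]
    )
    return refined


def calibrate(band_positions, ladder: LadderSpec) -> SizeCalibration:
    """Pair detected band positions with ladder sizes into a calibration.

    ``band_positions`` must be strictly increasing and match the ladder band
    count; the first (least-migrated) position is paired with the largest
    band size.
    """
    pos = np.asarray(band_positions, dtype=float)
    if len(pos) != len(ladder):
        raise DomainError(
            f"{len(pos)} band positions but ladder has {len(ladder)} bands"
        )
    if np.any(np.diff(pos) <= 0):
        raise DomainError("band positions must be strictly increasing")
    return SizeCalibration(
        anchor_positions=pos, anchor_bp=np.asarray(ladder.band_sizes_bp, dtype=float)
    )


def mode_fragment_size(
    profile: LaneProfile,
    calibration: SizeCalibration,
    smear_region: tuple[float, float] | None = None,
    min_prominence: float = 1e-6,
    full_output: bool = False,
):
    """Mode fragment size (bp): the smear's maximum-intensity position sized
    through the ladder calibration.

    The apex is refined parabolically; its prominence is reported with
    ``full_output=True`` and must exceed ``min_prominence`` (absolute
    intensity units) or a :class:`NoSmearError` is raised.
    """
    pos, inten = profile.positions, profile.intensities
    if smear_region is not None:
        lo, hi = smear_region
        mask = (pos >= lo) & (pos <= hi)
        if not np.any(mask):
            raise DomainError("smear_region selects no samples")
        sel = np.flatnonzero(mask)
    else:
        sel = np.arange(len(pos))
    local = inten[sel]
    i_local = int(np.argmax(local))
    idx = int(sel[i_local])
    prominence = float(peak_prominences(inten, [idx])[0][0]) if 0 < idx < len(inten) - 1 else float(inten[idx])
    if inten[idx] <= 0 or prominence < min_prominence:
        raise NoSmearError(
            f"no smear detected: apex prominence {prominence:g} below floor "
            f"{min_prominence:g}"
        )
    apex_pos, _ = _parabolic_apex(pos, inten, idx)
    bp = calibration.bp_at(apex_pos)
    if full_output:
        return bp, {
            "apex_position": apex_pos,
            "prominence": prominence,
            "in_calibration_range": bool(calibration.in_range(apex_pos)),
        }
    return bp


def extract_lane_profile(image: np.ndarray, lane_bounds: tuple[int, int], meta: str = "") -> LaneProfile:
    """Row-wise mean intensity across a lane's columns of a grayscale image."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise DomainError("image must be a 2-D grayscale array")
    c0, c1 = int(lane_bounds[0]), int(lane_bounds[1])
    if not (0 <= c0 < c1 <= img.shape[1]):
        raise DomainError(
            f"lane bounds [{c0}, {c1}) outside image with {img.shape[1]} columns"
        )
    return LaneProfile(
        positions=np.arange(img.shape[0], dtype=float),
        intensities=img[:, c0:c1].mean(axis=1),
        meta=meta,
    )
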