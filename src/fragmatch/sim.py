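"""Seeded synthetic-data generators for every pipeline input.

Three generators, all bit-reproducible for a fixed seed:

* ``simulate_hybridization`` — probe-level self/test hybridization tables
  whose noise scale depends on the mode fragment sizes of the test and
  reference aliquots.  The size effect enters as a multiplicative Gaussian
  noise scale (no per-fragment simulation): hybridization efficiency
  depends on fragment length, so mismatched or very short fragment
  distributions inflate the per-probe log2-ratio spread.  With the default
  constants the matched 225/225 pairing passes the 0.3 dLRsd gate while
  the 525/225, 525/140 and 225/140 mismatches fail it, matched sweeps stay
  under 0.3 at every size, and quality is flat above the ~400 bp optimum.
* ``simulate_decay_series`` — decay-series observations from known theta
  with Gaussian size noise, for model-recovery tests.
* ``simulate_gel_lane`` — a rendered gel with a ladder lane and a sample
  smear lane under the log-linear mobility law d = A - B*log10(bp), with
  known ground-truth mode.

The noise constants (sigma0 = 0.16, a = 0.8, b = 0.35, Lstar = 400) are a
synthetic calibration — chosen so the simulator reproduces the observed
pass/fail phenomenology — not measured quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .decay import DecayModel, DecayObservation, fragment_size
from .errors import DomainError
from .gel import DEFAULT_LADDER_BP, LadderSpec, LaneProfile

__all__ = [
    "NoiseConstants",
    "HybridizationConfig",
    "DecaySimConfig",
    "GelLaneRender",
    "noise_sigma",
    "simulate_hybridization",
    "simulate_decay_series",
    "simulate_gel_lane",
    "DEFAULT_MIGRATION_A",
    "DEFAULT_MIGRATION_B",
]

#: Default migration law d = A - B*log10(bp) for rendered gels; A chosen so
#: the whole default ladder lands inside a 420-row image.
DEFAULT_MIGRATION_A = 850.0
DEFAULT_MIGRATION_B = 250.0


@dataclass(frozen=True)
class NoiseConstants:
    """Size-dependent noise model constants (synthetic calibration)."""

    sigma0: float = 0.16  # baseline log2-ratio noise sd for matched, long DNA
    a: float = 0.8        # penalty per unit relative size mismatch
    b: float = 0.35       # penalty for sizes below lstar
    lstar: float = 400.0  # bp; optimum size, no small-size penalty above it

    def __post_init__(self):
        if self.sigma0 < 0 or self.a < 0 or self.b < 0 or self.lstar <= 0:
            raise DomainError("noise constants must be non-negative, lstar > 0")


def noise_sigma(
    mode_test_bp: float,
    mode_ref_bp: float,
    constants: NoiseConstants = NoiseConstants(),
) -> float:
    """Per-probe log2-ratio noise sd for a test/reference size pairing.

    sigma = sigma0 * (1 + a*Delta) * (1 + b*max(0, Lstar/min(mt, mr) - 1))
    with Delta the relative size mismatch |mt - mr| / mean(mt, mr).
    Symmetric in the two sizes; >= sigma0; equal to sigma0 for matched
    sizes at or above Lstar.
    """
    mt, mr = float(mode_test_bp), float(mode_ref_bp)
    if mt <= 0 or mr <= 0:
        raise DomainError("mode fragment sizes must be positive")
    delta = abs(mt - mr) / ((mt + mr) / 2.0)
    small = max(0.0, constants.lstar / min(mt, mr) - 1.0)
    return constants.sigma0 * (1.0 + constants.a * delta) * (1.0 + constants.b * small)


@dataclass(frozen=True)
class HybridizationConfig:
    """Settings for one simulated (self-)hybridization.

    ``chrom_layout`` lists (chromosome, probe count); by default all
    ``n_probes`` sit on chr1.  ``cn_profile`` lists (chromosome,
    (first_probe, last_probe_exclusive), true log2 shift) in per-chromosome
    probe indices.  Probes tile each chromosome contiguously at
    ``probe_spacing_bp`` (2.1 kb by default, the median spacing of the 1 M
    feature array this emulates).
    """

    mode_test_bp: float
    mode_ref_bp: float
    n_probes: int = 50_000
    chrom_layout: tuple[tuple[str, int], ...] | None = None
    cn_profile: tuple[tuple[str, tuple[int, int], float], ...] = ()
    constants: NoiseConstants = field(default_factory=NoiseConstants)
    gc_effect: float | None = None
    probe_spacing_bp: int = 2100
    probe_length_bp: int = 60
    seed: int = 0

    def __post_init__(self):
        if self.mode_test_bp <= 0 or self.mode_ref_bp <= 0:
            raise DomainError("mode fragment sizes must be positive")
        if self.n_probes < 1:
            raise DomainError("n_probes must be >= 1")

    def layout(self) -> list[tuple[str, int]]:
        if self.chrom_layout is not None:
            return [(str(c), int(n)) for c, n in self.chrom_layout]
        return [("chr1", int(self.n_probes))]


def simulate_hybridization(config: HybridizationConfig) -> pd.DataFrame:
    """Generate a probe table for a simulated hybridization.

    log2ratio_i = true_shift(i) + gc_effect*(gc_i - mean(gc)) + eps_i with
    eps_i iid Gaussian of sd ``noise_sigma(mode_test, mode_ref)``; gc_i is
    uniform in [0.3, 0.7].  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    layout = config.layout()
    counts = {c: n for c, n in layout}
    for chrom, (i0, i1), _shift in config.cn_profile:
        if chrom not in counts:
            raise DomainError(f"cn_profile chromosome {chrom!r} not in layout")
        if not (0 <= i0 < i1 <= counts[chrom]):
            raise DomainError(
                f"cn_profile probe range [{i0}, {i1}) outside chromosome "
                f"{chrom!r} with {counts[chrom]} probes"
            )
    sigma = noise_sigma(config.mode_test_bp, config.mode_ref_bp, config.constants)
    frames = []
    for chrom, n in layout:
        starts = np.arange(n, dtype=np.int64) * config.probe_spacing_bp
        shift = np.zeros(n)
        for c, (i0, i1), s in config.cn_profile:
            if c == chrom:
                shift[i0:i1] += s
        gc = rng.uniform(0.3, 0.7, size=n)
        eps = rng.normal(0.0, sigma, size=n) if sigma > 0 else np.zeros(n)
        vals = shift + eps
        if config.gc_effect is not None:
            vals = vals + config.gc_effect * (gc - gc.mean())
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + config.probe_length_bp,
                    "probe_id": [f"{chrom}_p{i}" for i in range(n)],
                    "log2ratio": vals,
                    "gc": gc,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class DecaySimConfig:
    """Ground-truth decay model plus sampling scheme for synthetic series."""

    theta1: float
    theta2: float
    theta3: float
    theta4: float
    time_grid: tuple[float, ...]
    noise_sd_bp: float = 0.0
    seed: int = 0
    sample_id: str = "sim"

    def __post_init__(self):
        # reuse DecayModel validation for the theta bounds
        DecayModel(self.theta1, self.theta2, self.theta3, self.theta4)
        if self.noise_sd_bp < 0:
            raise DomainError("noise sd must be >= 0")
        if len(self.time_grid) < 1:
            raise DomainError("time grid must be non-empty")
        if any(t < 0 for t in self.time_grid):
            raise DomainError("heat times must be >= 0")

    @property
    def model(self) -> DecayModel:
        return DecayModel(self.theta1, self.theta2, self.theta3, self.theta4)


def simulate_decay_series(config: DecaySimConfig) -> list[DecayObservation]:
    """Noisy decay-series observations from a known model.

    mode_bp = f(t; theta) + N(0, noise_sd), truncated at >= 30 bp so sizes
    stay physical.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    times = np.asarray(config.time_grid, dtype=float)
    clean = fragment_size(
        times, config.theta1, config.theta2, config.theta3, config.theta4
    )
    noise = (
        rng.normal(0.0, config.noise_sd_bp, size=len(times))
        if config.noise_sd_bp > 0
        else np.zeros(len(times))
    )
    sizes = np.maximum(clean + noise, 30.0)
    return [
        DecayObservation(config.sample_id, float(t), float(s))
        for t, s in zip(times, sizes)
    ]


@dataclass(frozen=True)
class GelLaneRender:
    """A rendered two-lane gel (ladder + sample) with ground truth."""

    sample_profile: LaneProfile
    ladder_profile: LaneProfile
    image: np.ndarray
    true_mode_bp: float
    migration_a: float
    migration_b: float
    ladder: LadderSpec
    ladder_bounds: tuple[int, int]
    sample_bounds: tuple[int, int]


def _migration(bp, a: float, b: float):
    return a - b * np.log10(np.asarray(bp, dtype=float))


def simulate_gel_lane(
    mode_bp: float,
    spread_log10: float = 0.12,
    ladder: LadderSpec | None = None,
    migration_a: float = DEFAULT_MIGRATION_A,
    migration_b: float = DEFAULT_MIGRATION_B,
    seed: int = 0,
    n_rows: int = 420,
    band_sd_px: float = 2.0,
    sensor_noise: float = 1.5,
    lane_width_px: int = 18,
) -> GelLaneRender:
    """Render a gel: one ladder lane and one sample smear lane.

    The sample's fragment-size density is log-normal with its mode at
    ``mode_bp`` and spread ``spread_log10`` decades; mapped through the
    mobility law d = A - B*log10(bp) this is a Gaussian intensity bump in
    migration coordinate centered at d(mode_bp) with sd B*spread_log10, so
    the rendered smear's apex sits exactly at the ground-truth mode.
    Ladder bands are narrow Gaussians at d(band).  Additive sensor noise is
    seeded and clipped at zero; the two lanes are tiled into a grayscale
    image with a gap column block between them.
    """
    if mode_bp <= 0:
        raise DomainError("mode_bp must be positive")
    if spread_log10 < 0:
        raise DomainError("spread_log10 must be >= 0")
    ladder = ladder or LadderSpec(DEFAULT_LADDER_BP)
    margin = 8.0
    d_mode = float(_migration(mode_bp, migration_a, migration_b))
    band_d = _migration(np.asarray(ladder.band_sizes_bp), migration_a, migration_b)
    if not (margin <= d_mode <= n_rows - margin):
        raise DomainError(
            f"mode {mode_bp:g} bp maps to row {d_mode:.1f}, outside the "
            f"renderable range [{margin:g}, {n_rows - margin:g}]"
        )
    if np.any(band_d < 0) or np.any(band_d > n_rows - 1):
        raise DomainError("ladder bands fall outside the rendered image")

    rng = np.random.default_rng(seed)
    rows = np.arange(n_rows, dtype=float)

    smear_sd = max(migration_b * spread_log10, 0.5)
    sample = 1000.0 * np.exp(-0.5 * ((rows - d_mode) / smear_sd) ** 2)

    ladder_trace = np.zeros(n_rows)
    # heavier staining of larger bands, deterministic
    amps = 600.0 + 300.0 * np.linspace(1.0, 0.4, len(ladder))
    for amp, d in zip(amps, band_d):
        ladder_trace += amp * np.exp(-0.5 * ((rows - d) / band_sd_px) ** 2)

    if sensor_noise > 0:
        sample = sample + rng.normal(0.0, sensor_noise, size=n_rows)
        ladder_trace = ladder_trace + rng.normal(0.0, sensor_noise, size=n_rows)
    sample = np.clip(sample, 0.0, None)
    ladder_trace = np.clip(ladder_trace, 0.0, None)

    gap = 6
    ladder_bounds = (0, lane_width_px)
    sample_bounds = (lane_width_px + gap, 2 * lane_width_px + gap)
    image = np.zeros((n_rows, 2 * lane_width_px + gap))
    image[:, ladder_bounds[0] : ladder_bounds[1]] = ladder_trace[:, None]
    image[:, sample_bounds[0] : sample_bounds[1]] = sample[:, None]

    return GelLaneRender(
        sample_profile=LaneProfile(rows, sample, meta=f"sample(mode={mode_bp:g}bp)"),
        ladder_profile=LaneProfile(rows, ladder_trace, meta="ladder"),
        image=image,
        true_mode_bp=float(mode_bp),
        migration_a=migration_a,
        migration_b=migration_b,
        ladder=ladder,
        ladder_bounds=ladder_bounds,
        sample_bounds=sample_bounds,
    )
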