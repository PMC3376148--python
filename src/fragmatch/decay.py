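"""Per-sample DNA thermodegradation model (Fragmentation Simulation Method).

A small decay series — the mode fragment size of a DNA sample measured after a
few heat-fragmentation times at 95 °C — is fit with a four-parameter shifted
inverse power law

    f(t) = theta1 + theta2 * (t + theta3) ** (-theta4)

where ``f(t)`` is the mode fragment size in base pairs immediately prior to
hybridization and ``t`` is heat time in minutes.  ``theta1`` is the asymptotic
minimum fragment size (bp), ``theta2`` a decay amplitude (bp·min^theta4),
``theta3`` a time offset (min) that keeps f finite at t = 0, and ``theta4`` the
dimensionless decay exponent.  The fitted curve is then inverted in closed form
to prescribe the heat time that brings the sample to a target mode size
(typically 400 bp, the size at and above which matched-size hybridizations
give optimal array quality).

Samples differ substantially and unpredictably in their thermodegradation
rates, which is why the four parameters are refit per sample from at least
four time points rather than taken from a fixed protocol.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import DomainError, FitFailureError, InsufficientDataError

__all__ = [
    "DecayObservation",
    "DecayModel",
    "FragmentationRecommendation",
    "fragment_size",
    "predict_size",
    "fit_decay_model",
    "predict_time",
    "default_time_grid",
    "DEFAULT_TARGET_BP",
    "MAX_RECOMMENDED_TIME_MIN",
]

#: Optimal mode fragment size target (bp): matched sizes >= 400 bp give the
#: best array quality, so workflows default to this.
DEFAULT_TARGET_BP = 400.0

#: Recommendations longer than this (minutes) are clipped and flagged.
MAX_RECOMMENDED_TIME_MIN = 15.0

# Parameter bounds keeping f physical and the inversion well-posed:
# theta1 in [0, min(mode_bp)], theta2 in (0, 10*max(mode_bp)],
# theta3 in (1e-3, 30], theta4 in (0.05, 5].
_THETA3_LO, _THETA3_HI = 1e-3, 30.0
_THETA4_LO, _THETA4_HI = 0.05, 5.0


@dataclass(frozen=True)
class DecayObservation:
    """One point of a decay series: mode size after ``time_min`` of heat."""

    sample_id: str
    time_min: float
    mode_bp: float

    def __post_init__(self):
        if self.time_min < 0:
            raise DomainError(f"time_min must be >= 0, got {self.time_min}")
        if self.mode_bp <= 0:
            raise DomainError(f"mode_bp must be > 0, got {self.mode_bp}")


@dataclass(frozen=True)
class DecayModel:
    """Fitted thermodegradation parameters plus fit diagnostics."""

    theta1: float
    theta2: float
    theta3: float
    theta4: float
    rss: float = 0.0
    n_obs: int = 0

    def __post_init__(self):
        if self.theta1 < 0:
            raise DomainError(f"theta1 must be >= 0, got {self.theta1}")
        if self.theta2 <= 0 or self.theta3 <= 0 or self.theta4 <= 0:
            raise DomainError(
                "theta2, theta3, theta4 must be > 0, got "
                f"({self.theta2}, {self.theta3}, {self.theta4})"
            )
        if self.rss < 0:
            raise DomainError("rss must be >= 0")

    @property
    def size_at_zero(self) -> float:
        """Mode fragment size at t = 0 (no heat beyond labeling exposure)."""
        return fragment_size(0.0, self.theta1, self.theta2, self.theta3, self.theta4)

    def to_dict(self) -> dict:
        return {
            "theta1": self.theta1,
            "theta2": self.theta2,
            "theta3": self.theta3,
            "theta4": self.theta4,
            "rss": self.rss,
            "n_obs": self.n_obs,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DecayModel":
        return cls(
            theta1=float(d["theta1"]),
            theta2=float(d["theta2"]),
            theta3=float(d["theta3"]),
            theta4=float(d["theta4"]),
            rss=float(d.get("rss", 0.0)),
            n_obs=int(d.get("n_obs", 0)),
        )


@dataclass(frozen=True)
class FragmentationRecommendation:
    """Prescribed heat-fragmentation time for a target mode size."""

    time_min: float
    target_bp: float
    feasible: bool
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "time_min": self.time_min,
            "target_bp": self.target_bp,
            "feasible": self.feasible,
            "note": self.note,
        }


def fragment_size(t, theta1, theta2, theta3, theta4):
    """Forward model f(t) = theta1 + theta2 * (t + theta3) ** (-theta4).

    The single place the functional form lives; alternates can be swapped
    here.  Vectorized over ``t``.
    """
    t = np.asarray(t, dtype=float)
    return theta1 + theta2 * np.power(t + theta3, -theta4)


def predict_size(model: DecayModel, t: float) -> float:
    """Mode fragment size (bp) after ``t`` minutes of heat fragmentation.

    Strictly decreasing in t; always > theta1.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise DomainError(f"heat time must be >= 0 minutes, got {t}")
    out = fragment_size(t_arr, model.theta1, model.theta2, model.theta3, model.theta4)
    return float(out) if out.ndim == 0 else out


def _default_bounds(mode_bp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lo = np.array([0.0, 1e-9, _THETA3_LO, _THETA4_LO])
    hi = np.array(
        [float(np.min(mode_bp)), 10.0 * float(np.max(mode_bp)), _THETA3_HI, _THETA4_HI]
    )
    return lo, hi


def _starting_points(t, y, lo, hi, fixed_theta4):
    """Five deterministic multi-starts spanning plausible decay shapes."""
    y_min, y_max = float(np.min(y)), float(np.max(y))
    starts = []
    for th4, th3 in ((1.0, 0.5), (0.5, 0.5), (0.3, 1.0), (2.0, 0.5), (1.0, 2.0)):
        if fixed_theta4 is not None:
            th4 = fixed_theta4
        th1 = 0.5 * y_min
        # theta2 from solving f(0) = max(mode_bp)
        th2 = max((y_max - th1) * th3**th4, 1e-6)
        x0 = np.clip(np.array([th1, th2, th3, th4]), lo, hi)
        starts.append(x0)
    return starts


def fit_decay_model(
    observations: Sequence[DecayObservation],
    fixed_theta4: float | None = None,
    bounds: tuple[Sequence[float], Sequence[float]] | None = None,
) -> DecayModel:
    """Fit the inverse-power-law decay model by bounded least squares.

    Parameters
    ----------
    observations
        Decay series for one sample; >= 4 points with distinct times
        (>= 3 if ``fixed_theta4`` pins the exponent).
    fixed_theta4
        Optionally fix the decay exponent instead of fitting it.
    bounds
        Optional ``(lower, upper)`` arrays over (theta1..theta4) replacing
        the defaults.

    Returns
    -------
    DecayModel
        Parameters minimizing the residual sum of squares over the bounded
        box, from the best of five deterministic multi-starts (4 points / 4
        parameters is ill-conditioned; multi-start + bounds stabilizes it).
    """
    obs = list(observations)
    n_params = 3 if fixed_theta4 is not None else 4
    min_n = n_params
    if len(obs) < max(min_n, 3):
        raise InsufficientDataError(
            f"need >= {min_n} observations"
            f"{' (fixed exponent)' if fixed_theta4 is not None else ''}, "
            f"got {len(obs)}"
        )
    if fixed_theta4 is None and len(obs) < 4:
        raise InsufficientDataError(f"need >= 4 observations, got {len(obs)}")

    t = np.array([o.time_min for o in obs], dtype=float)
    y = np.array([o.mode_bp for o in obs], dtype=float)
    if len(np.unique(t)) != len(t):
        raise DomainError("observations must have distinct time_min values")
    if np.any(y <= 0):
        raise DomainError("all mode_bp must be > 0")
    if len(obs) == n_params:
        warnings.warn(
            "exactly-determined fit (n == n_params); >= 5 points recommended",
            stacklevel=2,
        )
    if fixed_theta4 is not None and not (_THETA4_LO <= fixed_theta4 <= _THETA4_HI):
        raise DomainError(
            f"fixed_theta4 must lie in [{_THETA4_LO}, {_THETA4_HI}]"
        )

    if bounds is not None:
        lo = np.asarray(bounds[0], dtype=float)
        hi = np.asarray(bounds[1], dtype=float)
    else:
        lo, hi = _default_bounds(y)

    if fixed_theta4 is not None:
        free = [0, 1, 2]
    else:
        free = [0, 1, 2, 3]

    def residuals(x_free):
        full = np.empty(4)
        full[free] = x_free
        if fixed_theta4 is not None:
            full[3] = fixed_theta4
        return fragment_size(t, *full) - y

    best = None
    failures = []
    for x0 in _starting_points(t, y, lo, hi, fixed_theta4):
        try:
            res = least_squares(
                residuals,
                x0[free],
                bounds=(lo[free], hi[free]),
                method="trf",
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
                max_nfev=2000,
            )
        except Exception as exc:  # pragma: no cover - scipy internal failure
            failures.append(str(exc))
            continue
        if not np.all(np.isfinite(res.x)):
            failures.append("non-finite solution")
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitFailureError(
            "nonlinear regression failed across all restarts",
            diagnostics={"failures": failures},
        )

    full = np.empty(4)
    full[free] = best.x
    if fixed_theta4 is not None:
        full[3] = fixed_theta4
    rss = float(np.sum(residuals(best.x) ** 2))
    return DecayModel(
        theta1=float(full[0]),
        theta2=float(full[1]),
        theta3=float(full[2]),
        theta4=float(full[3]),
        rss=rss,
        n_obs=len(obs),
    )


def predict_time(
    model: DecayModel,
    target_bp: float,
    max_time: float | None = MAX_RECOMMENDED_TIME_MIN,
) -> FragmentationRecommendation:
    """Invert the fitted decay curve: heat time reaching ``target_bp``.

    Closed form: t* = (theta2 / (target - theta1)) ** (1/theta4) - theta3
    when theta1 < target <= f(0).  A target at or above the sample's t = 0
    size needs no fragmentation; a target at or below the asymptotic floor
    theta1 is infeasible.  Times beyond ``max_time`` minutes are clipped and
    flagged (pass ``max_time=None`` to disable clipping).
    """
    if target_bp <= 0:
        raise DomainError(f"target_bp must be > 0, got {target_bp}")
    f0 = model.size_at_zero
    if target_bp <= model.theta1:
        return FragmentationRecommendation(
            time_min=0.0,
            target_bp=target_bp,
            feasible=False,
            note=(
                f"target {target_bp:g} bp is at or below the asymptotic "
                f"minimum fragment size theta1 = {model.theta1:g} bp"
            ),
        )
    if target_bp >= f0:
        return FragmentationRecommendation(
            time_min=0.0,
            target_bp=target_bp,
            feasible=True,
            note=(
                "no fragmentation needed: sample already at/below target "
                f"at t=0 (f(0) = {f0:g} bp)"
            ),
        )
    t_star = (model.theta2 / (target_bp - model.theta1)) ** (1.0 / model.theta4)
    t_star -= model.theta3
    t_star = max(t_star, 0.0)
    note = ""
    if max_time is not None and t_star > max_time:
        note = (
            f"predicted time {t_star:.3g} min exceeds the configured maximum; "
            f"clipped to {max_time:g} min"
        )
        t_star = float(max_time)
    return FragmentationRecommendation(
        time_min=float(t_star), target_bp=target_bp, feasible=True, note=note
    )


#: Heat-fragmentation time grids (minutes) used to build a decay series.
_TIME_GRIDS = {
    "ffpe": (0.0, 0.5, 1.0, 2.0),
    "frozen": (0.0, 2.0, 4.0, 6.0),
}


def default_time_grid(sample_class: str) -> list[float]:
    """Decay-series heat times for a sample class.

    FFPE DNA is already fragmented, so its series uses short exposures
    (0, 0.5, 1, 2 min); intact frozen tissue/cell DNA uses longer ones
    (0, 2, 4, 6 min).
    """
    try:
        return list(_TIME_GRIDS[str(sample_class).lower()])
    except KeyError:
        raise DomainError(
            f"unknown sample class {sample_class!r}; expected one of "
            f"{sorted(_TIME_GRIDS)}"
        ) from None
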