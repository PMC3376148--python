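"""File readers/writers and the end-to-end fragmentation workflow.

Formats (all plain text, chosen for diff-ability):

* decay CSV: headered ``sample_id,time_min,mode_bp``
* probe table TSV: headered ``chrom  start  end  probe_id  log2ratio  [gc]``
  (BED-style 0-based half-open coordinates; extra trailing columns are
  accepted and preserved)
* lane profile TSV: headered ``position  intensity``
* calls BED: tab-delimited, headerless, track-line free:
  ``chrom  start  end  direction  n_probes  mean_log2  score``
* fitted models and workflow reports: JSON

``run_fsm_workflow`` ties the stages together per sample: (optional) gel
sizing of each aliquot lane -> decay-model fit -> closed-form inversion to
the recommended heat time for the target mode size (default 400 bp).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .decay import (
    DEFAULT_TARGET_BP,
    DecayModel,
    DecayObservation,
    FragmentationRecommendation,
    default_time_grid,
    fit_decay_model,
    predict_time,
)
from .errors import FragmatchError, InsufficientDataError, ParseError, ValidationError
from .gel import LadderSpec, LaneProfile, SizeCalibration, calibrate, detect_ladder_bands, mode_fragment_size, subtract_background
from .qc import PROBE_COLUMNS, AberrationCall, validate_probe_table

__all__ = [
    "read_probe_table",
    "write_probe_table",
    "read_decay_csv",
    "write_decay_csv",
    "read_lane_profile",
    "write_lane_profile",
    "read_ladder_sizes",
    "read_calls_bed",
    "write_calls_bed",
    "read_model_json",
    "write_model_json",
    "SampleResult",
    "WorkflowReport",
    "run_fsm_workflow",
]


# ---------------------------------------------------------------------------
# tabular readers / writers


def read_probe_table(path) -> pd.DataFrame:
    """Read a headered probe TSV, validating invariants.

    Unsorted input is re-sorted with a warning; malformed rows raise
    :class:`ParseError` naming the line (1-based, counting the header).
    Extra trailing columns are preserved.
    """
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ParseError(f"cannot parse probe table {path}: {exc}") from exc
    missing = [c for c in PROBE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    for col in ("start", "end"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            line = int(vals.index[vals.isna()][0]) + 2
            raise ParseError(f"{path}: non-numeric {col!r} at line {line}")
        df[col] = vals.astype(np.int64)
    if (df["start"] < 0).any():
        line = int(df.index[df["start"] < 0][0]) + 2
        raise ValidationError(f"{path}: negative start coordinate at line {line}")
    bad = df["end"] <= df["start"]
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise ValidationError(f"{path}: end <= start at line {line}")
    sorted_ok = (
        df.sort_values(["chrom", "start"], kind="mergesort")
        .reset_index(drop=True)[["chrom", "start"]]
        .equals(df[["chrom", "start"]].reset_index(drop=True))
    )
    if not sorted_ok:
        warnings.warn(f"{path}: probe table not sorted; re-sorting", stacklevel=2)
    return validate_probe_table(df)


def write_probe_table(probes: pd.DataFrame, path) -> None:
    """Write a probe table TSV; round-trips bit-identically through
    :func:`read_probe_table` for canonical inputs."""
    validate_probe_table(probes).to_csv(path, sep="\t", index=False)


def read_decay_csv(path) -> pd.DataFrame:
    """Read a headered decay CSV (sample_id, time_min, mode_bp)."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"cannot parse decay CSV {path}: {exc}") from exc
    required = ["sample_id", "time_min", "mode_bp"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    for col in ("time_min", "mode_bp"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            line = int(vals.index[vals.isna()][0]) + 2
            raise ParseError(f"{path}: non-numeric {col!r} at line {line}")
        df[col] = vals
    if (df["time_min"] < 0).any():
        raise ValidationError(f"{path}: negative time_min")
    if (df["mode_bp"] <= 0).any():
        raise ValidationError(f"{path}: non-positive mode_bp")
    return df


def write_decay_csv(observations: Sequence[DecayObservation], path) -> None:
    pd.DataFrame(
        {
            "sample_id": [o.sample_id for o in observations],
            "time_min": [o.time_min for o in observations],
            "mode_bp": [o.mode_bp for o in observations],
        }
    ).to_csv(path, index=False)


def read_lane_profile(path, meta: str = "") -> LaneProfile:
    """Read a headered lane-profile TSV (position, intensity)."""
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ParseError(f"cannot parse lane profile {path}: {exc}") from exc
    missing = [c for c in ("position", "intensity") if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    return LaneProfile(
        df["position"].to_numpy(dtype=float),
        df["intensity"].to_numpy(dtype=float),
        meta=meta or str(path),
    )


def write_lane_profile(profile: LaneProfile, path) -> None:
    pd.DataFrame(
        {"position": profile.positions, "intensity": profile.intensities}
    ).to_csv(path, sep="\t", index=False)


def read_ladder_sizes(path) -> LadderSpec:
    """Read a one-column CSV of ladder band sizes (bp)."""
    sizes = pd.read_csv(path, header=None).iloc[:, 0].to_numpy(dtype=float)
    return LadderSpec(tuple(sizes))


_BED_COLUMNS = ["chrom", "start", "end", "direction", "n_probes", "mean_log2", "score"]


def write_calls_bed(calls: Sequence[AberrationCall], path) -> None:
    """Write calls as headerless BED-like TSV."""
    pd.DataFrame(
        [
            (c.chrom, c.start, c.end, c.direction, c.n_probes, c.mean_log2, c.score)
            for c in calls
        ],
        columns=_BED_COLUMNS,
    ).to_csv(path, sep="\t", index=False, header=False)


def read_calls_bed(path) -> list[AberrationCall]:
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=_BED_COLUMNS)
    except Exception as exc:
        raise ParseError(f"cannot parse calls BED {path}: {exc}") from exc
    if len(df) and df.isna().any().any():
        raise ParseError(f"{path}: malformed BED row")
    return [
        AberrationCall(
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            n_probes=int(r.n_probes),
            mean_log2=float(r.mean_log2),
            score=float(r.score),
            direction=str(r.direction),
        )
        for r in df.itertuples()
    ]


def write_model_json(model: DecayModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=2)
        fh.write("\n")


def read_model_json(path) -> DecayModel:
    with open(path) as fh:
        try:
            return DecayModel.from_dict(json.load(fh))
        except (KeyError, ValueError, TypeError) as exc:
            raise ParseError(f"{path}: not a valid decay-model JSON: {exc}") from exc


# ---------------------------------------------------------------------------
# end-to-end workflow


@dataclass(frozen=True)
class SampleResult:
    """Per-sample workflow outcome: observations, fit, recommendation."""

    sample_id: str
    observations: tuple[DecayObservation, ...]
    model: DecayModel
    recommendation: FragmentationRecommendation
    warnings: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "observations": [
                {"time_min": o.time_min, "mode_bp": o.mode_bp}
                for o in self.observations
            ],
            "model": self.model.to_dict(),
            "recommendation": self.recommendation.to_dict(),
            "warnings": list(self.warnings),
        }


@dataclass(frozen=True)
class WorkflowReport:
    """Full fragmentation-workflow report; JSON round-trips losslessly."""

    samples: tuple[SampleResult, ...]
    target_bp: float
    sample_class: str
    version: str = __version__
    seed: int | None = None
    config_hash: str = ""

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "seed": self.seed,
            "config_hash": self.config_hash,
            "target_bp": self.target_bp,
            "sample_class": self.sample_class,
            "samples": [s.to_dict() for s in self.samples],
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "WorkflowReport":
        samples = tuple(
            SampleResult(
                sample_id=s["sample_id"],
                observations=tuple(
                    DecayObservation(s["sample_id"], o["time_min"], o["mode_bp"])
                    for o in s["observations"]
                ),
                model=DecayModel.from_dict(s["model"]),
                recommendation=FragmentationRecommendation(
                    time_min=s["recommendation"]["time_min"],
                    target_bp=s["recommendation"]["target_bp"],
                    feasible=s["recommendation"]["feasible"],
                    note=s["recommendation"].get("note", ""),
                ),
                warnings=tuple(s.get("warnings", ())),
            )
            for s in d["samples"]
        )
        return cls(
            samples=samples,
            target_bp=float(d["target_bp"]),
            sample_class=d["sample_class"],
            version=d.get("version", __version__),
            seed=d.get("seed"),
            config_hash=d.get("config_hash", ""),
        )


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def size_lanes(
    lanes: Sequence[tuple[float, LaneProfile]],
    ladder_profile: LaneProfile,
    ladder: LadderSpec,
    background_window: float | None = None,
) -> list[tuple[float, float]]:
    """Size a set of (heat_time, lane profile) aliquots against one ladder
    lane; returns (heat_time, mode_bp) pairs."""
    if background_window is not None:
        ladder_profile = subtract_background(ladder_profile, background_window)
    band_pos = detect_ladder_bands(ladder_profile, expected_n=len(ladder))
    cal = calibrate(band_pos, ladder)
    sized = []
    for t, prof in lanes:
        if background_window is not None:
            prof = subtract_background(prof, background_window)
        sized.append((t, mode_fragment_size(prof, cal)))
    return sized


def run_fsm_workflow(
    decay_table: pd.DataFrame | None = None,
    lanes: dict[str, Sequence[tuple[float, LaneProfile]]] | None = None,
    ladder_profile: LaneProfile | None = None,
    ladder: LadderSpec | None = None,
    sample_class: str = "ffpe",
    target_bp: float = DEFAULT_TARGET_BP,
    seed: int | None = None,
) -> WorkflowReport:
    """Run the fragmentation workflow for one or more samples.

    Input is either a decay table (``sample_id, time_min, mode_bp``; e.g.
    from :func:`read_decay_csv`) or per-sample gel lanes plus a ladder lane
    to be sized first.  Each sample needs >= 4 sized aliquots.  Stage
    errors are re-raised annotated with the sample id and stage name.
    """
    default_time_grid(sample_class)  # validates the class early
    per_sample: dict[str, list[DecayObservation]] = {}
    if decay_table is not None:
        for sid, grp in decay_table.groupby("sample_id", sort=False):
            per_sample[str(sid)] = [
                DecayObservation(str(sid), float(r.time_min), float(r.mode_bp))
                for r in grp.itertuples()
            ]
    elif lanes is not None:
        if ladder_profile is None or ladder is None:
            raise FragmatchError(
                "gel sizing needs both a ladder lane profile and a ladder spec"
            )
        for sid, sample_lanes in lanes.items():
            try:
                sized = size_lanes(sample_lanes, ladder_profile, ladder)
            except FragmatchError as exc:
                raise type(exc)(f"[sample {sid} / stage gel-sizing] {exc}") from exc
            per_sample[str(sid)] = [
                DecayObservation(str(sid), t, bp) for t, bp in sized
            ]
    else:
        raise FragmatchError("provide either a decay table or gel lanes")

    results = []
    for sid, obs in per_sample.items():
        if len(obs) < 4:
            raise InsufficientDataError(
                f"[sample {sid} / stage fit] need >= 4 sized aliquots, got {len(obs)}"
            )
        notes: list[str] = []
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                model = fit_decay_model(obs)
            except FragmatchError as exc:
                raise type(exc)(f"[sample {sid} / stage fit] {exc}") from exc
            notes.extend(str(w.message) for w in caught)
        try:
            rec = predict_time(model, target_bp)
        except FragmatchError as exc:
            raise type(exc)(f"[sample {sid} / stage predict] {exc}") from exc
        if rec.note:
            notes.append(rec.note)
        results.append(
            SampleResult(
                sample_id=sid,
                observations=tuple(obs),
                model=model,
                recommendation=rec,
                warnings=tuple(notes),
            )
        )
    cfg = {
        "sample_class": sample_class,
        "target_bp": target_bp,
        "seed": seed,
        "samples": sorted(per_sample),
    }
    return WorkflowReport(
        samples=tuple(results),
        target_bp=target_bp,
        sample_class=sample_class,
        seed=seed,
        config_hash=_config_hash(cfg),
    )
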