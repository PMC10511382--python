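"""CSV/JSON interchange, validation, and seeded run manifests.

Trial data travel as one CSV row per trial (whole and partial report share a
schema), pupil traces as time/diameter/valid CSV, cohorts as one row per
subject, and all fitted or computed results as JSON.  A run manifest records
every stage's seed and file hashes so a pipeline run can be reproduced
byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .pupillometry import PUIResult, PupilTrace
from .tva_model import (
    FitResult,
    PartialReportDataset,
    PartialReportTrial,
    WholeReportDataset,
    WholeReportTrial,
    default_partial_report_conditions,
)

__all__ = [
    "TrialValidationError",
    "read_trials",
    "write_trials",
    "read_trace",
    "write_trace",
    "read_cohort",
    "write_cohort",
    "fit_result_to_dict",
    "pui_result_to_dict",
    "write_json",
    "RunManifest",
]

TRIAL_COLUMNS = [
    "subject_id",
    "paradigm",
    "condition_id",
    "exposure_ms",
    "masked",
    "displayed",
    "reported",
]


class TrialValidationError(ValueError):
    """A malformed trial row, reported with its (1-based) data row number."""


def write_trials(
    data: WholeReportDataset | PartialReportDataset, path: str | Path
) -> None:
    rows = []
    if isinstance(data, WholeReportDataset):
        for t in data.trials:
            rows.append(
                {
                    "subject_id": data.subject_id,
                    "paradigm": "whole",
                    "condition_id": f"{t.exposure_ms:g}_{'m' if t.masked else 'u'}",
                    "exposure_ms": t.exposure_ms,
                    "masked": int(t.masked),
                    "displayed": t.displayed,
                    "reported": t.reported,
                }
            )
    else:
        for t in data.trials:
            # role string encodes target/distractor letters: "T:AB|D:C"
            disp = f"T:{t.displayed_targets}|D:{t.displayed_distractors}"
            rows.append(
                {
                    "subject_id": data.subject_id,
                    "paradigm": "partial",
                    "condition_id": t.condition_id,
                    "exposure_ms": t.exposure_ms,
                    "masked": 1,
                    "displayed": disp,
                    "reported": t.reported,
                }
            )
    pd.DataFrame(rows, columns=TRIAL_COLUMNS).to_csv(path, index=False)


def read_trials(path: str | Path) -> WholeReportDataset | PartialReportDataset:
    """Read and validate a trial CSV (whole or partial report).

    Raises :class:`TrialValidationError` naming the offending row for
    unknown paradigms, duplicate display letters, or impossible scores.
    """
    df = pd.read_csv(
        path, dtype={"displayed": str, "reported": str}, keep_default_na=False
    )
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise TrialValidationError(f"missing columns: {sorted(missing)}")
    paradigms = set(df["paradigm"].unique())
    if not paradigms <= {"whole", "partial"}:
        raise TrialValidationError(
            f"unknown paradigm value(s): {sorted(paradigms - {'whole', 'partial'})}"
        )
    if len(paradigms) != 1:
        raise TrialValidationError("file mixes whole- and partial-report trials")
    subject = str(df["subject_id"].iloc[0]) if len(df) else "unknown"
    if paradigms == {"whole"}:
        trials = []
        for i, row in enumerate(df.itertuples(index=False), start=1):
            disp = str(row.displayed)
            if len(disp) != 6:
                raise TrialValidationError(
                    f"row {i}: whole-report display must have 6 letters, got {disp!r}"
                )
            try:
                trials.append(
                    WholeReportTrial(
                        exposure_ms=float(row.exposure_ms),
                        masked=bool(int(row.masked)),
                        displayed=disp,
                        reported=str(row.reported),
                    )
                )
            except ValueError as e:
                raise TrialValidationError(f"row {i}: {e}") from e
        return WholeReportDataset(subject_id=subject, trials=trials)
    conditions = {c.condition_id: c for c in default_partial_report_conditions()}
    trials_p = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if row.condition_id not in conditions:
            raise TrialValidationError(
                f"row {i}: unknown partial-report condition {row.condition_id!r}"
            )
        disp = str(row.displayed)
        try:
            tpart, dpart = disp.split("|")
            targets = tpart.removeprefix("T:")
            distractors = dpart.removeprefix("D:")
        except ValueError as e:
            raise TrialValidationError(
                f"row {i}: malformed partial display {disp!r}"
            ) from e
        trials_p.append(
            PartialReportTrial(
                condition_id=str(row.condition_id),
                exposure_ms=float(row.exposure_ms),
                displayed_targets=targets,
                displayed_distractors=distractors,
                reported=str(row.reported),
            )
        )
    return PartialReportDataset(subject_id=subject, conditions=conditions, trials=trials_p)


# ---------------------------------------------------------------------------
# traces and cohorts
# ---------------------------------------------------------------------------


def write_trace(trace: PupilTrace, path: str | Path) -> None:
    t = np.arange(trace.diameter_mm.size) / trace.sampling_rate_hz
    d = np.where(np.isfinite(trace.diameter_mm), trace.diameter_mm, "")
    pd.DataFrame(
        {"time_s": np.round(t, 4), "diameter_mm": d, "valid": trace.valid.astype(int)}
    ).to_csv(path, index=False)


def read_trace(path: str | Path) -> PupilTrace:
    df = pd.read_csv(path)
    for col in ("time_s", "diameter_mm", "valid"):
        if col not in df.columns:
            raise ValueError(f"trace CSV missing column {col!r}")
    dt = np.diff(df["time_s"].to_numpy(float))
    fs = 1.0 / float(np.median(dt)) if dt.size else 25.0
    return PupilTrace(
        diameter_mm=df["diameter_mm"].to_numpy(float),
        valid=df["valid"].to_numpy(int).astype(bool),
        sampling_rate_hz=round(fs, 6),
    )


def write_cohort(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "group" not in df.columns:
        raise ValueError("cohort CSV must have a 'group' column")
    bad = set(df["group"].unique()) - {"control", "patient"}
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    return df


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


def fit_result_to_dict(fit: FitResult) -> dict:
    return {
        "C": fit.params.C,
        "t0": fit.params.t0,
        "K": fit.params.K,
        "mu": fit.params.mu,
        "alpha": fit.alpha,
        "loglik": fit.loglik,
        "R2_fit": fit.R2_fit,
        "convergence": {
            "converged": fit.converged,
            "n_starts": fit.n_starts,
            "n_iterations": fit.n_iterations,
        },
    }


def pui_result_to_dict(res: PUIResult) -> dict:
    return {
        "segment_puis": [None if not np.isfinite(v) else float(v) for v in res.segment_puis],
        "total_pui": res.total_pui,
        "mean_pd": res.mean_pd,
        "n_segments_used": res.n_segments_used,
        "n_samples_interpolated": res.n_samples_interpolated,
        "flagged": res.flagged,
    }


def _jsonable(obj):
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Record of one pipeline run: config hash, seeds, inputs/outputs."""

    seed: int
    config: dict
    stages: dict = dataclasses.field(default_factory=dict)
    started_at: float = dataclasses.field(default_factory=time.time)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.config, sort_keys=True, default=_jsonable).encode()
        ).hexdigest()

    def record_stage(self, name: str, seed: int, outputs: list[str | Path]) -> None:
        self.stages[name] = {
            "seed": seed,
            "outputs": {str(p): _sha256(Path(p)) for p in outputs},
        }

    def write(self, path: str | Path) -> None:
        write_json(
            {
                "config_hash": self.config_hash,
                "seed": self.seed,
                "config": self.config,
                "stages": self.stages,
                "started_at": self.started_at,
            },
            path,
        )
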