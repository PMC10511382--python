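"""Synthetic whole/partial-report trials, pupil traces and cohort tables.

Stands in for the study's (non-deposited) patient data: report trials are
sampled from the same TVA race model the estimator fits, pupil traces mix a
slow high-amplitude oscillation with measurement noise and blink artifacts,
and the cohort generator uses a Gaussian copula so the subject-level table
reproduces the target rank-correlation structure (processing speed vs
pupillary unrest vs mental fatigue etc.) together with group mean shifts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tva_model import (
    LETTER_ALPHABET,
    AttentionalWeights,
    PartialReportCondition,
    PartialReportDataset,
    PartialReportTrial,
    TVAParameters,
    WholeReportDataset,
    WholeReportTrial,
    default_partial_report_conditions,
    effective_exposure_s,
)

__all__ = [
    "WholeReportDesign",
    "simulate_whole_report",
    "simulate_partial_report",
    "simulate_pupil_trace",
    "CohortConfig",
    "simulate_cohort",
    "default_cohort_config",
    "COHORT_VARIABLES",
]


# ---------------------------------------------------------------------------
# whole report
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WholeReportDesign:
    """Seven effective exposure conditions: five masked plus two unmasked.

    The unmasked conditions repeat the second-shortest and the longest
    masked exposure, as in the standard whole-report protocol.
    """

    masked_exposures_ms: tuple[float, ...] = (10.0, 30.0, 60.0, 110.0, 200.0)
    n_trials_per_condition: int = 20

    def conditions(self) -> list[tuple[float, bool]]:
        exps = sorted(self.masked_exposures_ms)
        if len(exps) < 2:
            raise ValueError("design needs at least two masked exposures")
        unmasked = [exps[1], exps[-1]]
        return [(e, True) for e in exps] + [(e, False) for e in unmasked]


def simulate_whole_report(
    params: TVAParameters,
    design: WholeReportDesign | None = None,
    seed: int | np.random.Generator = 0,
    subject_id: str = "sim",
) -> WholeReportDataset:
    """Sample a whole-report dataset from the TVA race model.

    Per trial, each of the six displayed letters is encoded independently
    with the condition's encoding probability; a capacity draw from the
    (K_base, K_base+1) mixture caps how many encoded letters are retained
    and reported.
    """
    design = design or WholeReportDesign()
    rng = np.random.default_rng(seed)
    letters = np.array(list(LETTER_ALPHABET))
    trials: list[WholeReportTrial] = []
    for exposure_ms, masked in design.conditions():
        a = effective_exposure_s(params, exposure_ms, masked)
        p = -math.expm1(-(params.C / 6.0) * a)
        for _ in range(design.n_trials_per_condition):
            displayed = rng.choice(letters, size=6, replace=False)
            k = params.K_base + (rng.random() < params.K_frac)
            encoded = displayed[rng.random(6) < p]
            if encoded.size > k:
                encoded = rng.choice(encoded, size=k, replace=False)
            trials.append(
                WholeReportTrial(
                    exposure_ms=exposure_ms,
                    masked=masked,
                    displayed="".join(displayed),
                    reported="".join(encoded),
                )
            )
    return WholeReportDataset(subject_id=subject_id, trials=trials)


# ---------------------------------------------------------------------------
# partial report
# ---------------------------------------------------------------------------


def simulate_partial_report(
    shared: TVAParameters,
    weights: AttentionalWeights,
    exposure_ms: float = 80.0,
    n_trials_per_condition: int = 18,
    conditions: list[PartialReportCondition] | None = None,
    seed: int | np.random.Generator = 0,
    subject_id: str = "sim",
) -> PartialReportDataset:
    """Sample partial-report trials (16 layouts x 18 trials by default).

    Items race with independent exponential finishing times at TVA rates
    ``C * w / sum(w)``; finishers before the masked deadline enter vSTM in
    finishing order up to the capacity draw, and encoded targets are
    reported (distractors are encoded but never reported).
    """
    conditions = conditions or default_partial_report_conditions()
    rng = np.random.default_rng(seed)
    letters = np.array(list(LETTER_ALPHABET))
    cond_map = {c.condition_id: c for c in conditions}
    trials: list[PartialReportTrial] = []
    for cond in conditions:
        roles = ["T"] * len(cond.target_positions) + ["D"] * len(
            cond.distractor_positions
        )
        wsum = weights.wT * roles.count("T") + weights.wD * roles.count("D")
        rates = np.array(
            [shared.C * (weights.wT if r == "T" else weights.wD) / wsum for r in roles]
        )
        a = max(0.0, exposure_ms - shared.t0) / 1000.0
        for _ in range(n_trials_per_condition):
            disp = rng.choice(letters, size=len(roles), replace=False)
            with np.errstate(divide="ignore"):
                times = np.where(
                    rates > 0, rng.exponential(1.0, size=len(roles)) / np.where(rates > 0, rates, 1.0), np.inf
                )
            finished = np.flatnonzero(times <= a)
            order = finished[np.argsort(times[finished])]
            k = shared.K_base + (rng.random() < shared.K_frac)
            selected = order[:k]
            reported = [disp[i] for i in selected if roles[i] == "T"]
            trials.append(
                PartialReportTrial(
                    condition_id=cond.condition_id,
                    exposure_ms=exposure_ms,
                    displayed_targets="".join(
                        disp[i] for i in range(len(roles)) if roles[i] == "T"
                    ),
                    displayed_distractors="".join(
                        disp[i] for i in range(len(roles)) if roles[i] == "D"
                    ),
                    reported="".join(reported),
                )
            )
    return PartialReportDataset(subject_id=subject_id, conditions=cond_map, trials=trials)


# ---------------------------------------------------------------------------
# pupil traces
# ---------------------------------------------------------------------------


def simulate_pupil_trace(
    duration_s: float = 660.0,
    base_pd_mm: float = 6.9,
    drift_mm: float = 0.3,
    oscillation_amplitude_mm: float = 0.25,
    oscillation_freq_hz: float = 0.1,
    noise_sd_mm: float = 0.02,
    blink_rate_per_min: float = 4.0,
    long_dropout_prob: float = 0.0,
    sampling_rate_hz: float = 25.0,
    seed: int | np.random.Generator = 0,
):
    """Synthesise a dark-adapted pupil recording.

    The series is a baseline with slow linear drift, a random-phase slow
    oscillation (the "fatigue wave" band, ~0.05–0.2 Hz), white measurement
    noise, and blink artifacts: masked gaps of 0.1–0.4 s at the given rate
    plus, with probability ``long_dropout_prob``, one eye closure longer
    than 3 s.  Returns a :class:`~tva_arousal.pupillometry.PupilTrace`.
    """
    from .pupillometry import PupilTrace

    if duration_s <= 82.5:
        raise ValueError("duration_s must exceed one 82.5-s segment")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sampling_rate_hz))
    t = np.arange(n) / sampling_rate_hz
    phase = rng.uniform(0, 2 * np.pi)
    d = (
        base_pd_mm
        - drift_mm * t / duration_s
        + oscillation_amplitude_mm * np.sin(2 * np.pi * oscillation_freq_hz * t + phase)
        + rng.normal(0.0, noise_sd_mm, size=n)
    )
    valid = np.ones(n, dtype=bool)
    n_blinks = rng.poisson(blink_rate_per_min * duration_s / 60.0)
    for _ in range(n_blinks):
        dur = rng.uniform(0.1, 0.4)
        start = rng.integers(0, max(1, n - int(dur * sampling_rate_hz)))
        valid[start : start + int(dur * sampling_rate_hz)] = False
    if rng.random() < long_dropout_prob:
        dur = rng.uniform(3.5, 6.0)
        start = rng.integers(0, max(1, n - int(dur * sampling_rate_hz)))
        valid[start : start + int(dur * sampling_rate_hz)] = False
    d[~valid] = np.nan
    return PupilTrace(diameter_mm=d, valid=valid, sampling_rate_hz=sampling_rate_hz)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

#: subject-level measures, in the order of the correlation matrix
COHORT_VARIABLES = [
    "C",
    "PUI",
    "fatigue_mental",
    "PD",
    "depression",
    "sleepiness",
    "days_since_infection",
    "age",
    "K",
    "t0",
    "alpha",
]

# patient-group Spearman correlations (lower triangle, COHORT_VARIABLES order)
_DEFAULT_RHO = {
    ("PUI", "C"): -0.508,
    ("fatigue_mental", "C"): -0.535,
    ("fatigue_mental", "PUI"): 0.234,
    ("PD", "C"): 0.094,
    ("PD", "PUI"): -0.447,
    ("PD", "fatigue_mental"): 0.050,
    ("depression", "C"): -0.266,
    ("depression", "PUI"): 0.097,
    ("depression", "fatigue_mental"): 0.498,
    ("depression", "PD"): -0.131,
    ("sleepiness", "C"): -0.194,
    ("sleepiness", "PUI"): 0.116,
    ("sleepiness", "fatigue_mental"): 0.318,
    ("sleepiness", "PD"): -0.163,
    ("sleepiness", "depression"): 0.345,
    ("days_since_infection", "C"): -0.115,
    ("days_since_infection", "PUI"): 0.005,
    ("days_since_infection", "fatigue_mental"): 0.133,
    ("days_since_infection", "PD"): 0.063,
    ("days_since_infection", "depression"): 0.378,
    ("days_since_infection", "sleepiness"): -0.016,
    ("age", "C"): 0.042,
    ("age", "PUI"): -0.053,
    ("age", "fatigue_mental"): 0.014,
    ("age", "PD"): -0.364,
    ("age", "depression"): 0.095,
    ("age", "sleepiness"): 0.169,
    ("age", "days_since_infection"): -0.315,
    ("K", "C"): 0.574,
    ("K", "PUI"): -0.433,
    ("K", "fatigue_mental"): -0.206,
    ("K", "PD"): 0.124,
    ("K", "depression"): -0.037,
    ("K", "sleepiness"): -0.186,
    ("K", "days_since_infection"): -0.014,
    ("K", "age"): 0.001,
    ("t0", "C"): -0.369,
    ("t0", "PUI"): 0.379,
    ("t0", "fatigue_mental"): 0.258,
    ("t0", "PD"): -0.112,
    ("t0", "depression"): 0.110,
    ("t0", "sleepiness"): 0.309,
    ("t0", "days_since_infection"): -0.419,
    ("t0", "age"): 0.093,
    ("t0", "K"): -0.258,
    ("alpha", "C"): 0.250,
    ("alpha", "PUI"): -0.247,
    ("alpha", "fatigue_mental"): -0.249,
    ("alpha", "PD"): -0.024,
    ("alpha", "depression"): -0.022,
    ("alpha", "sleepiness"): 0.124,
    ("alpha", "days_since_infection"): -0.160,
    ("alpha", "age"): 0.145,
    ("alpha", "K"): 0.175,
    ("alpha", "t0"): 0.084,
}

# group-level marginal means and SDs; patient values from the study tables,
# control pupillometry assumed (higher arousal: lower PUI, larger pupil)
_DEFAULT_MARGINALS = {
    "patient": {
        "C": (26.23, 12.26),
        "PUI": (4.39, 1.76),
        "fatigue_mental": (18.65, 4.17),
        "PD": (6.88, 0.97),
        "depression": (6.85, 3.98),
        "sleepiness": (11.24, 4.31),
        "days_since_infection": (428.0, 94.85),
        "age": (47.95, 8.44),
        "K": (3.16, 0.95),
        "t0": (15.16, 13.65),
        "alpha": (0.44, 0.25),
    },
    "control": {
        "C": (33.72, 11.92),
        "PUI": (3.0, 1.4),
        "fatigue_mental": (8.97, 2.90),
        "PD": (7.4, 0.9),
        "depression": (2.72, 4.55),
        "sleepiness": (7.30, 4.20),
        "days_since_infection": (0.0, 1e-9),
        "age": (44.05, 12.25),
        "K": (3.89, 0.71),
        "t0": (9.92, 12.19),
        "alpha": (0.50, 0.33),
    },
}

# (low, high, integer) clipping per variable
_SCALE_BOUNDS = {
    "C": (1.0, 200.0, False),
    "PUI": (0.1, 20.0, False),
    "fatigue_mental": (5, 25, True),
    "PD": (1.5, 9.0, False),
    "depression": (0, 21, True),
    "sleepiness": (0, 24, True),
    "days_since_infection": (0, 10000, True),
    "age": (18, 90, True),
    "K": (0.5, 6.0, False),
    "t0": (0.0, 100.0, False),
    "alpha": (0.0, 3.0, False),
}


@dataclass
class CohortConfig:
    """Configuration of the synthetic two-group cohort.

    ``rho`` holds target Spearman rank correlations for variable pairs
    (shared across groups); ``marginals`` maps group -> variable ->
    (mean, sd).  ``indirect_only_mediation`` replaces the K–PUI correlation
    with the product rho(K,C)*rho(C,PUI), so the pupillary-unrest effect on
    capacity runs entirely through processing speed.
    """

    n_per_group: int = 40
    rho: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(_DEFAULT_RHO)
    )
    marginals: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            g: dict(m) for g, m in _DEFAULT_MARGINALS.items()
        }
    )
    indirect_only_mediation: bool = False

    def correlation_matrix(self) -> np.ndarray:
        rho = dict(self.rho)
        if self.indirect_only_mediation:
            rho[("K", "PUI")] = rho[("K", "C")] * rho[("PUI", "C")]
        p = len(COHORT_VARIABLES)
        mat = np.eye(p)
        idx = {v: i for i, v in enumerate(COHORT_VARIABLES)}
        for (a, b), r in rho.items():
            if not -1 <= r <= 1:
                raise ValueError(f"target correlation out of range for ({a}, {b}): {r}")
            mat[idx[a], idx[b]] = mat[idx[b], idx[a]] = r
        eig = np.linalg.eigvalsh(mat)
        if eig.min() < -1e-10:
            # name the most collinear pair for the error message
            offender = max(rho.items(), key=lambda kv: abs(kv[1]))[0]
            raise ValueError(
                f"target correlation matrix is not positive semi-definite "
                f"(min eigenvalue {eig.min():.3g}); check pair {offender}"
            )
        return mat


def default_cohort_config(**overrides) -> CohortConfig:
    """The study-calibrated default cohort (40 patients, 40 controls)."""
    return CohortConfig(**overrides)


def _nearest_correlation(mat: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues and rescale to unit diagonal."""
    w, v = np.linalg.eigh(mat)
    w = np.maximum(w, 1e-8)
    m = v @ np.diag(w) @ v.T
    d = np.sqrt(np.diag(m))
    return m / np.outer(d, d)


def simulate_cohort(
    config: CohortConfig | None = None, seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """Draw a subject-level cohort table via a Gaussian copula.

    Rank-correlation targets are converted to Gaussian-copula correlations
    with ``2 sin(pi * rho_s / 6)``, latent normals are drawn per group, and
    each variable is mapped to a normal marginal at the group's mean/SD,
    then clipped (and rounded for questionnaire/integer scales) to its
    scale bounds.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(seed)
    rho_s = config.correlation_matrix()
    rho_gauss = 2.0 * np.sin(np.pi * rho_s / 6.0)
    np.fill_diagonal(rho_gauss, 1.0)
    eig = np.linalg.eigvalsh(rho_gauss)
    if eig.min() < 1e-10:
        rho_gauss = _nearest_correlation(rho_gauss)
    chol = np.linalg.cholesky(rho_gauss)
    rows = []
    for group in ("control", "patient"):
        z = rng.standard_normal((config.n_per_group, len(COHORT_VARIABLES))) @ chol.T
        for i in range(config.n_per_group):
            row: dict[str, object] = {"group": group, "subject_id": f"{group[:3]}{i:03d}"}
            for j, var in enumerate(COHORT_VARIABLES):
                mean, sd = config.marginals[group][var]
                val = mean + sd * z[i, j]
                lo, hi, integer = _SCALE_BOUNDS[var]
                val = min(max(val, lo), hi)
                row[var] = int(round(val)) if integer else float(val)
            rows.append(row)
    df = pd.DataFrame(rows)
    df.loc[df["group"] == "control", "days_since_infection"] = 0
    return df
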