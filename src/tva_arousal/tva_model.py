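"""Generative TVA whole/partial-report model and maximum-likelihood fitting.

The theory of visual attention (TVA) treats briefly exposed letters as
exponential racers: each display item is encoded with rate ``v_i`` during the
effective exposure window, and the first ``K`` finishers enter a limited
visual short-term memory (vSTM) store.  Whole-report accuracy across exposure
durations identifies the total processing rate ``C`` (letters/s), the
perceptual threshold ``t0`` (ms), vSTM capacity ``K`` and, for unmasked
displays, the iconic-persistence prolongation ``mu`` (ms).  Partial report
with target and distractor letters additionally identifies the selectivity
ratio ``alpha = wD / wT``.

Capacity is modelled as a two-point mixture on adjacent integers
``(K_base, K_base + 1)`` with mass ``K_frac`` on the larger value, so the
reported capacity ``K = K_base + K_frac`` can be fractional.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.stats import qmc

__all__ = [
    "TVAParameters",
    "AttentionalWeights",
    "WholeReportTrial",
    "WholeReportDataset",
    "PartialReportCondition",
    "PartialReportTrial",
    "PartialReportDataset",
    "ConditionPrediction",
    "FitConfig",
    "FitResult",
    "LETTER_ALPHABET",
    "UnidentifiableError",
    "default_partial_report_conditions",
    "condition_prediction",
    "partial_report_prediction",
    "whole_report_loglik",
    "partial_report_loglik",
    "fit_whole_report",
    "fit_partial_report",
    "fit_r2",
]

#: Report alphabet: A–Z without I, Q and Y.
LETTER_ALPHABET = "ABCDEFGHJKLMNOPRSTUVWXZ"

# binomial coefficients for n = 6 letters
_COMB6 = np.array([1.0, 6.0, 15.0, 20.0, 15.0, 6.0, 1.0])

#: per-trial likelihood floor guarding against log(0) under gross misfit
LIKELIHOOD_FLOOR = 1e-12


class UnidentifiableError(ValueError):
    """Raised when the requested parameters cannot be identified from the data."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TVAParameters:
    """Race-model parameter vector.

    Parameters
    ----------
    C : float
        Visual processing speed in letters/second, > 0.
    t0 : float
        Perceptual threshold in ms, >= 0.
    K_base : int
        Integer floor of vSTM capacity, in {0..6}.
    K_frac : float
        Probability mass on ``K_base + 1``; reported K = K_base + K_frac.
    mu : float
        Iconic-persistence prolongation for unmasked displays, ms, >= 0.
    """

    C: float
    t0: float
    K_base: int
    K_frac: float = 0.0
    mu: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.C, self.t0, self.K_frac, self.mu)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("TVA parameters must be finite")
        if self.C <= 0:
            raise ValueError(f"C must be > 0, got {self.C}")
        if self.t0 < 0:
            raise ValueError(f"t0 must be >= 0, got {self.t0}")
        if not 0 <= self.K_frac <= 1:
            raise ValueError(f"K_frac must be in [0, 1], got {self.K_frac}")
        if not 0 <= self.K_base + self.K_frac <= 6:
            raise ValueError("K = K_base + K_frac must lie in [0, 6]")
        if self.mu < 0:
            raise ValueError(f"mu must be >= 0, got {self.mu}")

    @property
    def K(self) -> float:
        """Expected vSTM capacity ``K_base + K_frac``."""
        return self.K_base + self.K_frac

    @classmethod
    def from_continuous(cls, C: float, t0: float, K: float, mu: float = 0.0) -> "TVAParameters":
        """Build parameters from a continuous capacity value in [0, 6]."""
        if not math.isfinite(K) or not 0 <= K <= 6:
            raise ValueError(f"K must be in [0, 6], got {K}")
        base = min(int(math.floor(K)), 6)
        frac = K - base
        if base == 6:
            base, frac = 6, 0.0
        return cls(C=C, t0=t0, K_base=base, K_frac=frac, mu=mu)


@dataclass(frozen=True)
class AttentionalWeights:
    """Target/distractor attentional weights; wT is the reference (1.0)."""

    wD: float
    wT: float = 1.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.wD) or self.wD < 0:
            raise ValueError(f"wD must be finite and >= 0, got {self.wD}")
        if self.wT <= 0:
            raise ValueError(f"wT must be > 0, got {self.wT}")

    @property
    def alpha(self) -> float:
        """Top-down control ratio wD / wT (lower = better selectivity)."""
        return self.wD / self.wT


# ---------------------------------------------------------------------------
# trial containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WholeReportTrial:
    exposure_ms: float
    masked: bool
    displayed: str
    reported: str

    def __post_init__(self) -> None:
        if len(set(self.displayed)) != len(self.displayed):
            raise ValueError(f"displayed letters must be distinct: {self.displayed!r}")
        unknown = set(self.displayed) - set(LETTER_ALPHABET)
        if unknown:
            raise ValueError(f"letters outside report alphabet: {sorted(unknown)}")

    @property
    def score(self) -> int:
        """Number of reported letters actually present in the display."""
        return len(set(self.reported) & set(self.displayed))


@dataclass
class WholeReportDataset:
    subject_id: str
    trials: list[WholeReportTrial] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.trials)

    def conditions(self) -> list[tuple[float, bool]]:
        """Distinct (exposure_ms, masked) conditions, sorted."""
        return sorted({(t.exposure_ms, t.masked) for t in self.trials})

    def score_counts(self) -> dict[tuple[float, bool], np.ndarray]:
        """Per condition, counts of trial scores 0..6."""
        table: dict[tuple[float, bool], np.ndarray] = {}
        for t in self.trials:
            key = (t.exposure_ms, t.masked)
            if key not in table:
                table[key] = np.zeros(7)
            table[key][t.score] += 1
        return table

    def condition_means(self) -> dict[tuple[float, bool], float]:
        scores = np.arange(7.0)
        return {k: float(scores @ c / c.sum()) for k, c in self.score_counts().items()}


@dataclass(frozen=True)
class PartialReportCondition:
    """One of the 16 partial-report display layouts.

    Letters occupy corners of an imaginary square (TL, TR, BL, BR);
    two-letter layouts are never diagonal.
    """

    condition_id: str
    target_positions: tuple[str, ...]
    distractor_positions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        pos = self.target_positions + self.distractor_positions
        if not 1 <= len(pos) <= 2 or len(set(pos)) != len(pos):
            raise ValueError(f"bad layout for {self.condition_id}")
        if len(self.target_positions) < 1:
            raise ValueError("at least one target required")
        if len(pos) == 2 and set(pos) in ({"TL", "BR"}, {"TR", "BL"}):
            raise ValueError("two-letter layouts are never diagonal")

    @property
    def kind(self) -> str:
        n_t, n_d = len(self.target_positions), len(self.distractor_positions)
        return {(1, 0): "T", (1, 1): "TD", (2, 0): "TT"}[(n_t, n_d)]


def default_partial_report_conditions() -> list[PartialReportCondition]:
    """The standard 16-condition layout: 4 T, 8 T-D, 4 T-T."""
    corners = ("TL", "TR", "BL", "BR")
    pairs = [("TL", "TR"), ("BL", "BR"), ("TL", "BL"), ("TR", "BR")]
    out = [PartialReportCondition(f"T_{c}", (c,)) for c in corners]
    for a, b in pairs:
        out.append(PartialReportCondition(f"TD_{a}_{b}", (a,), (b,)))
        out.append(PartialReportCondition(f"TD_{b}_{a}", (b,), (a,)))
    for a, b in pairs:
        out.append(PartialReportCondition(f"TT_{a}_{b}", (a, b)))
    return out


@dataclass(frozen=True)
class PartialReportTrial:
    condition_id: str
    exposure_ms: float
    displayed_targets: str
    displayed_distractors: str
    reported: str

    @property
    def score(self) -> int:
        """Number of reported target letters."""
        return len(set(self.reported) & set(self.displayed_targets))


@dataclass
class PartialReportDataset:
    subject_id: str
    conditions: dict[str, PartialReportCondition]
    trials: list[PartialReportTrial] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.trials)

    def score_counts(self) -> dict[str, np.ndarray]:
        """Per condition id, counts of reported-target scores 0..2."""
        table: dict[str, np.ndarray] = {}
        for t in self.trials:
            arr = table.setdefault(t.condition_id, np.zeros(3))
            arr[t.score] += 1
        return table


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConditionPrediction:
    effective_exposure_s: float
    p_encode: float
    score_pmf: np.ndarray
    expected_score: float


def _capped_binomial_pmf(n: int, p: float, k: int) -> np.ndarray:
    """PMF of min(Binomial(n, p), k) over scores 0..n."""
    s = np.arange(n + 1)
    if p <= 0:
        pmf = np.zeros(n + 1)
        pmf[0] = 1.0
    elif p >= 1:
        pmf = np.zeros(n + 1)
        pmf[n] = 1.0
    else:
        pmf = _COMB6[: n + 1] * p**s * (1 - p) ** (n - s) if n == 6 else (
            np.array([math.comb(n, int(i)) for i in s]) * p**s * (1 - p) ** (n - s)
        )
    if k < n:
        out = pmf.copy()
        out[k] = pmf[k:].sum()
        out[k + 1 :] = 0.0
        return out
    return pmf


def effective_exposure_s(params: TVAParameters, exposure_ms: float, masked: bool) -> float:
    """Effective processing time in seconds: max(0, tau + mu*[unmasked] - t0)/1000."""
    tau = exposure_ms + (0.0 if masked else params.mu)
    return max(0.0, tau - params.t0) / 1000.0


def condition_prediction(
    params: TVAParameters, exposure_ms: float, masked: bool, n_letters: int = 6
) -> ConditionPrediction:
    """Score distribution for one whole-report condition.

    Each of the ``n_letters`` equally weighted letters is encoded with
    probability ``1 - exp(-(C/n) * a)`` during the effective exposure ``a``;
    the capacity mixture caps the number retained.
    """
    if exposure_ms <= 0:
        raise ValueError("exposure_ms must be > 0")
    a = effective_exposure_s(params, exposure_ms, masked)
    v = params.C / n_letters
    p = -math.expm1(-v * a)
    pmf = (1.0 - params.K_frac) * _capped_binomial_pmf(n_letters, p, params.K_base)
    if params.K_frac > 0:
        pmf = pmf + params.K_frac * _capped_binomial_pmf(
            n_letters, p, min(params.K_base + 1, n_letters)
        )
    return ConditionPrediction(
        effective_exposure_s=a,
        p_encode=p,
        score_pmf=pmf,
        expected_score=float(np.arange(n_letters + 1) @ pmf),
    )


def whole_report_loglik(params: TVAParameters, data: WholeReportDataset) -> float:
    """Sum of log score probabilities over all trials (0 for an empty dataset)."""
    ll = 0.0
    for (exp_ms, masked), counts in data.score_counts().items():
        pmf = condition_prediction(params, exp_ms, masked).score_pmf
        ll += float(counts @ np.log(np.maximum(pmf, LIKELIHOOD_FLOOR)))
    return ll


# ---------------------------------------------------------------------------
# partial-report forward model
# ---------------------------------------------------------------------------


def _two_item_target_pmf(
    v_items: list[tuple[str, float]], a: float, k: int
) -> np.ndarray:
    """PMF of the number of reported targets for a 1- or 2-item display.

    Items race with independent exponential finishing times; the first
    ``k`` finishers before deadline ``a`` (seconds) are selected, and only
    targets count toward the score.
    """
    pmf = np.zeros(3)
    roles = [r for r, _ in v_items]
    rates = [v for _, v in v_items]
    n_targets = roles.count("T")
    if k == 0 or a <= 0:
        pmf[0] = 1.0
        return pmf
    p = [-math.expm1(-v * a) for v in rates]
    if len(v_items) == 1:
        pt = p[0] if roles[0] == "T" else 0.0
        pmf[1] = pt
        pmf[0] = 1.0 - pt
        return pmf
    if k >= 2:
        # both slots available: items are selected independently
        pr = [p[i] if roles[i] == "T" else 0.0 for i in range(2)]
        if n_targets == 2:
            pmf[2] = pr[0] * pr[1]
            pmf[1] = pr[0] * (1 - pr[1]) + (1 - pr[0]) * pr[1]
        else:
            pt = pr[0] + pr[1]  # exactly one entry nonzero
            pmf[1] = pt
        pmf[0] = 1.0 - pmf[1] - pmf[2]
        return pmf
    # k == 1: only the first finisher is selected
    vsum = rates[0] + rates[1]
    q = -math.expm1(-vsum * a)  # P(min finishing time <= a)
    if n_targets == 2:
        pmf[1] = q
        pmf[0] = 1.0 - q
    else:
        it = roles.index("T")
        pt = rates[it] / vsum * q  # P(target finishes first and before a)
        pmf[1] = pt
        pmf[0] = 1.0 - pt
    return pmf


def partial_report_prediction(
    shared: TVAParameters,
    weights: AttentionalWeights,
    condition: PartialReportCondition,
    exposure_ms: float,
) -> np.ndarray:
    """PMF over the number of reported targets (0..2) for one layout.

    Rates follow the TVA weight rule ``v_x = C * w_x / sum_z w_z`` over the
    items actually displayed; partial-report displays are always masked.
    """
    items = [("T", weights.wT) for _ in condition.target_positions] + [
        ("D", weights.wD) for _ in condition.distractor_positions
    ]
    wsum = sum(w for _, w in items)
    if wsum <= 0:
        raise ValueError("total attentional weight must be > 0")
    a = max(0.0, exposure_ms - shared.t0) / 1000.0
    v_items = [(r, shared.C * w / wsum) for r, w in items]
    pmf = (1.0 - shared.K_frac) * _two_item_target_pmf(v_items, a, shared.K_base)
    if shared.K_frac > 0:
        pmf = pmf + shared.K_frac * _two_item_target_pmf(v_items, a, shared.K_base + 1)
    return pmf


def partial_report_loglik(
    shared: TVAParameters,
    weights: AttentionalWeights,
    data: PartialReportDataset,
) -> float:
    """Multinomial log-likelihood of reported-target counts per condition."""
    ll = 0.0
    by_cond: dict[str, dict[float, np.ndarray]] = {}
    for t in data.trials:
        by_cond.setdefault(t.condition_id, {}).setdefault(t.exposure_ms, np.zeros(3))[
            t.score
        ] += 1
    for cid, per_exp in by_cond.items():
        cond = data.conditions[cid]
        for exp_ms, counts in per_exp.items():
            pmf = partial_report_prediction(shared, weights, cond, exp_ms)
            ll += float(counts @ np.log(np.maximum(pmf, LIKELIHOOD_FLOOR)))
    return ll


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class FitConfig:
    n_starts: int = 8
    seed: int = 0
    maxiter: int = 2000
    fatol: float = 1e-6
    xatol: float = 1e-4
    bounds_C: tuple[float, float] = (1.0, 200.0)
    bounds_t0: tuple[float, float] = (0.0, 100.0)
    bounds_K: tuple[float, float] = (0.5, 6.0)
    bounds_mu: tuple[float, float] = (0.0, 500.0)
    bounds_alpha: tuple[float, float] = (0.0, 3.0)


@dataclass
class FitResult:
    params: TVAParameters
    loglik: float
    R2_fit: float
    converged: bool
    n_starts: int
    n_iterations: int
    weights: AttentionalWeights | None = None

    @property
    def alpha(self) -> float | None:
        return None if self.weights is None else self.weights.alpha


def fit_r2(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Squared Pearson correlation between observed and predicted condition means.

    Returns NaN when the observations have zero variance (undefined).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("observed and predicted must be equal-length, length >= 2")
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        return float("nan")
    r = np.corrcoef(obs, pred)[0, 1]
    return float(r * r)


def _multistart_minimize(neg_ll, bounds: list[tuple[float, float]], config: FitConfig):
    """Seeded Latin-hypercube multi-start Nelder-Mead over box bounds."""
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    sampler = qmc.LatinHypercube(d=len(bounds), seed=config.seed)
    starts = lo + sampler.random(config.n_starts) * (hi - lo)
    best = None
    n_iter = 0
    any_converged = False
    for x0 in starts:
        res = optimize.minimize(
            neg_ll,
            x0,
            method="Nelder-Mead",
            bounds=bounds,
            options={
                "maxiter": config.maxiter,
                "fatol": config.fatol,
                "xatol": config.xatol,
            },
        )
        n_iter += res.nit
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    return best, any_converged, n_iter


def fit_whole_report(data: WholeReportDataset, config: FitConfig | None = None) -> FitResult:
    """Maximum-likelihood TVA fit to whole-report data.

    Optimizes (log C, t0, K, mu) by multi-start bounded simplex search; mu is
    only fitted when unmasked conditions are present.  The goodness of fit
    ``R2_fit`` is the squared correlation between observed and predicted mean
    scores across the exposure conditions.
    """
    config = config or FitConfig()
    conds = data.conditions()
    if len(conds) < 2:
        raise UnidentifiableError(
            "need >= 2 distinct effective exposure conditions to fit"
        )
    counts = data.score_counts()
    has_unmasked = any(not m for _, m in conds)
    scores = np.arange(7.0)

    cond_list = [(e, m, counts[(e, m)]) for e, m in conds]

    def neg_ll(x) -> float:
        params = TVAParameters.from_continuous(
            C=math.exp(x[0]), t0=x[1], K=x[2], mu=x[3] if has_unmasked else 0.0
        )
        ll = 0.0
        for exp_ms, masked, c in cond_list:
            pmf = condition_prediction(params, exp_ms, masked).score_pmf
            ll += float(c @ np.log(np.maximum(pmf, LIKELIHOOD_FLOOR)))
        return -ll

    bounds = [
        (math.log(config.bounds_C[0]), math.log(config.bounds_C[1])),
        config.bounds_t0,
        config.bounds_K,
    ]
    bounds.append(config.bounds_mu if has_unmasked else (0.0, 1e-9))
    best, converged, n_iter = _multistart_minimize(neg_ll, bounds, config)
    params = TVAParameters.from_continuous(
        C=math.exp(best.x[0]),
        t0=float(best.x[1]),
        K=float(best.x[2]),
        mu=float(best.x[3]) if has_unmasked else 0.0,
    )
    obs = np.array([float(scores @ c / c.sum()) for _, _, c in cond_list])
    pred = np.array(
        [condition_prediction(params, e, m).expected_score for e, m, _ in cond_list]
    )
    return FitResult(
        params=params,
        loglik=-best.fun,
        R2_fit=fit_r2(obs, pred),
        converged=converged,
        n_starts=config.n_starts,
        n_iterations=n_iter,
    )


def fit_partial_report(
    data: PartialReportDataset,
    config: FitConfig | None = None,
    shared: TVAParameters | None = None,
) -> FitResult:
    """Maximum-likelihood fit of the selectivity ratio alpha from partial report.

    When ``shared`` is given only alpha is estimated; otherwise C and t0 for
    the partial-report display are estimated jointly (capacity fixed at the
    shared default K = 4 when not supplied, since 1–2 item displays carry no
    capacity information).
    """
    config = config or FitConfig()
    td_trials = [
        t for t in data.trials if data.conditions[t.condition_id].kind == "TD"
    ]
    if not td_trials:
        raise UnidentifiableError("alpha unidentifiable: no target-distractor trials")

    if shared is not None:

        def neg_ll(x) -> float:
            return -partial_report_loglik(shared, AttentionalWeights(wD=x[0]), data)

        best, converged, n_iter = _multistart_minimize(
            neg_ll, [config.bounds_alpha], config
        )
        params = shared
        weights = AttentionalWeights(wD=float(best.x[0]))
    else:

        def neg_ll(x) -> float:
            p = TVAParameters.from_continuous(C=math.exp(x[0]), t0=x[1], K=4.0)
            return -partial_report_loglik(p, AttentionalWeights(wD=x[2]), data)

        bounds = [
            (math.log(config.bounds_C[0]), math.log(config.bounds_C[1])),
            config.bounds_t0,
            config.bounds_alpha,
        ]
        best, converged, n_iter = _multistart_minimize(neg_ll, bounds, config)
        params = TVAParameters.from_continuous(
            C=math.exp(best.x[0]), t0=float(best.x[1]), K=4.0
        )
        weights = AttentionalWeights(wD=float(best.x[2]))

    obs_means, pred_means = [], []
    by_cond: dict[str, list[PartialReportTrial]] = {}
    for t in data.trials:
        by_cond.setdefault(t.condition_id, []).append(t)
    for cid, trials in sorted(by_cond.items()):
        obs_means.append(float(np.mean([t.score for t in trials])))
        exp_ms = trials[0].exposure_ms
        pmf = partial_report_prediction(params, weights, data.conditions[cid], exp_ms)
        pred_means.append(float(np.arange(3.0) @ pmf))
    r2 = fit_r2(np.array(obs_means), np.array(pred_means)) if len(obs_means) >= 2 else float("nan")
    return FitResult(
        params=params,
        loglik=-best.fun,
        R2_fit=r2,
        converged=converged,
        n_starts=config.n_starts,
        n_iterations=n_iter,
        weights=weights,
    )
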