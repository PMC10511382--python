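"""Group, correlation, regression and mediation statistics for the cohort.

Covers the full battery applied to the subject-level table: Wilcoxon
rank-sum tests with the effect size r = |z|/sqrt(N), bootstrapped
kernel-density non-overlap between group distributions, a Spearman
correlation matrix with Benjamini–Hochberg FDR control, multiple linear
regression with case-resampling bootstrap confidence intervals and Cohen's
f², an extra-sum-of-squares nested model comparison, and percentile
bootstrap mediation (indirect = a*b).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RankTestResult",
    "RegressionResult",
    "MediationResult",
    "CorrelationReport",
    "wilcoxon_rank_sum",
    "effect_size_r",
    "chi_square_independence",
    "distribution_nonoverlap",
    "spearman_matrix",
    "bh_fdr",
    "ols_regression",
    "cohens_f2",
    "nested_model_f_test",
    "mediate",
]


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------


@dataclass
class RankTestResult:
    W: float
    z: float
    p: float
    r: float
    n_total: int
    alternative: str
    degenerate: bool = False


def effect_size_r(z: float, n_total: int) -> float:
    """Rank-test effect size r = |z| / sqrt(N); medium 0.3–0.5, large > 0.5."""
    if n_total < 2:
        raise ValueError("n_total must be >= 2")
    return abs(z) / math.sqrt(n_total)


def wilcoxon_rank_sum(
    x, y, alternative: str = "two-sided", continuity: bool = True,
    method: str = "normal",
) -> RankTestResult:
    """Wilcoxon rank-sum (Mann–Whitney) test.

    Uses midranks for ties, a tie-corrected variance and an optional
    continuity correction; W is the Mann–Whitney U of the first sample
    (as printed by R's ``wilcox.test``).  With ``method="exact"`` the
    p-value comes from full permutation enumeration (small untied samples,
    as in R's default); z and r always use the normal approximation.  With
    every value tied across both samples the result is flagged degenerate
    (z = 0, r = 0, p = 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    n = n1 + n2
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    R1 = ranks[:n1].sum()
    U = R1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    _, counts = np.unique(combined, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return RankTestResult(
            W=float(U), z=0.0, p=1.0, r=0.0, n_total=n,
            alternative=alternative, degenerate=True,
        )
    diff = U - mu
    cc = 0.5 if continuity else 0.0
    if alternative == "two-sided":
        z = (diff - math.copysign(cc, diff) if diff != 0 else 0.0) / math.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(z))
    elif alternative == "greater":
        z = (diff - cc) / math.sqrt(var)
        p = stats.norm.sf(z)
    elif alternative == "less":
        z = (diff + cc) / math.sqrt(var)
        p = stats.norm.cdf(z)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = min(p, 1.0)
    if method == "exact":
        if tie_term > 0:
            raise ValueError("exact method requires untied samples")
        p = float(stats.mannwhitneyu(x, y, alternative=alternative, method="exact").pvalue)
    elif method != "normal":
        raise ValueError(f"unknown method {method!r}")
    return RankTestResult(
        W=float(U), z=float(z), p=float(p), r=effect_size_r(z, n),
        n_total=n, alternative=alternative,
    )


def chi_square_independence(table) -> tuple[float, float, int]:
    """Pearson chi-square test of independence on a contingency table.

    No continuity correction is applied (plain Pearson statistic).
    Returns (chi2, p, dof).
    """
    chi2, p, dof, _ = stats.chi2_contingency(np.asarray(table), correction=False)
    return float(chi2), float(p), int(dof)


# ---------------------------------------------------------------------------
# distribution non-overlap
# ---------------------------------------------------------------------------


def distribution_nonoverlap(
    x, y, n_boot: int = 1000, seed: int = 0, n_grid: int = 512
) -> dict:
    """Bootstrapped non-overlap of two kernel density estimates.

    Per replicate, each group is resampled with replacement, Gaussian KDEs
    with Silverman bandwidth are fitted, and the non-overlap is
    ``1 - integral of min(f, g)``; the point estimate is the mean over
    replicates, with a percentile 95% CI.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5 or y.size < 5:
        raise ValueError("need at least 5 observations per group")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance sample: KDE undefined")
    rng = np.random.default_rng(seed)
    lo = min(x.min(), y.min())
    hi = max(x.max(), y.max())
    span = hi - lo
    grid = np.linspace(lo - 0.5 * span, hi + 0.5 * span, n_grid)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        xb = rng.choice(x, size=x.size, replace=True)
        yb = rng.choice(y, size=y.size, replace=True)
        if np.ptp(xb) == 0 or np.ptp(yb) == 0:
            vals[b] = np.nan
            continue
        f = stats.gaussian_kde(xb, bw_method="silverman")(grid)
        g = stats.gaussian_kde(yb, bw_method="silverman")(grid)
        ovl = np.trapezoid(np.minimum(f, g), grid)
        vals[b] = 1.0 - min(ovl, 1.0)
    est = float(np.nanmean(vals))
    ci = np.nanpercentile(vals, [2.5, 97.5])
    return {"nonoverlap": est, "ci": (float(ci[0]), float(ci[1])), "n_boot": n_boot}


# ---------------------------------------------------------------------------
# correlations and FDR
# ---------------------------------------------------------------------------


@dataclass
class CorrelationReport:
    variables: list[str]
    rho: pd.DataFrame
    p_raw: pd.DataFrame
    p_adjusted: pd.DataFrame
    significant: pd.DataFrame


def bh_fdr(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up FDR: (adjusted p-values, rejection flags)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def spearman_matrix(
    table: pd.DataFrame, variables: list[str] | None = None, q: float = 0.05
) -> CorrelationReport:
    """Pairwise midrank Spearman correlations with BH-FDR over the matrix.

    Constant variables yield NaN correlations, flagged not-significant.
    """
    variables = variables or list(table.columns)
    k = len(variables)
    rho = np.full((k, k), np.nan)
    p_raw = np.full((k, k), np.nan)
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p_raw, 0.0)
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            sub = table[[variables[i], variables[j]]].dropna()
            if len(sub) < 4:
                raise ValueError(
                    f"fewer than 4 complete cases for ({variables[i]}, {variables[j]})"
                )
            a, b = sub.iloc[:, 0].to_numpy(float), sub.iloc[:, 1].to_numpy(float)
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                continue
            r, p = stats.spearmanr(a, b)
            rho[i, j] = rho[j, i] = r
            p_raw[i, j] = p_raw[j, i] = p
            pairs.append((i, j, p))
    p_adj_mat = np.full((k, k), np.nan)
    np.fill_diagonal(p_adj_mat, 0.0)
    sig = np.zeros((k, k), dtype=bool)
    if pairs:
        adj, rej = bh_fdr([p for _, _, p in pairs], q=q)
        for (i, j, _), pa, rj in zip(pairs, adj, rej):
            p_adj_mat[i, j] = p_adj_mat[j, i] = pa
            sig[i, j] = sig[j, i] = rj
    mk = lambda m: pd.DataFrame(m, index=variables, columns=variables)
    return CorrelationReport(
        variables=variables, rho=mk(rho), p_raw=mk(p_raw),
        p_adjusted=mk(p_adj_mat), significant=mk(sig),
    )


# ---------------------------------------------------------------------------
# regression
# ---------------------------------------------------------------------------


@dataclass
class RegressionResult:
    outcome: str
    predictors: list[str]
    b: dict[str, float]                      # unstandardized, incl. intercept
    b_ci: dict[str, tuple[float, float]]
    beta: dict[str, float]                   # standardized
    beta_ci: dict[str, tuple[float, float]]
    p_values: dict[str, float]
    R2: float
    R2_adj: float
    f2: float
    model_p: float
    r2_ci: tuple[float, float]
    n: int
    n_boot: int
    _model: object = field(repr=False, default=None)


def cohens_f2(r2_adj: float) -> float:
    """Cohen's f² = R²_adj / (1 − R²_adj)."""
    if r2_adj >= 1:
        raise ValueError("R2 must be < 1")
    return r2_adj / (1.0 - r2_adj)


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # locate a column that is linearly dependent on the preceding ones
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) <= np.linalg.matrix_rank(X[:, :j]):
                raise ValueError(f"rank-deficient design: column {names[j]!r} is collinear")
        raise ValueError("rank-deficient design matrix")


def ols_regression(
    table: pd.DataFrame,
    outcome: str,
    predictors: list[str],
    n_boot: int = 1000,
    seed: int = 0,
) -> RegressionResult:
    """OLS with standardized coefficients and percentile bootstrap CIs.

    Unstandardized coefficients come from the raw-scale fit; standardized
    betas from the same model on z-scored variables.  Confidence intervals
    are case-resampling percentile bootstrap (matching "bootstrapped (1000
    samples)" reporting); the model p-value is the overall F-test.
    """
    cols = [outcome] + predictors
    data = table[cols].dropna()
    n = len(data)
    if n < len(predictors) + 2:
        raise ValueError("too few complete cases for the requested model")
    y = data[outcome].to_numpy(float)
    X = sm.add_constant(data[predictors].to_numpy(float))
    _check_full_rank(X, ["const"] + predictors)
    fit = sm.OLS(y, X).fit()
    zdata = (data - data.mean()) / data.std(ddof=1)
    zfit = sm.OLS(
        zdata[outcome].to_numpy(float),
        sm.add_constant(zdata[predictors].to_numpy(float)),
    ).fit()

    rng = np.random.default_rng(seed)
    boots_b = np.empty((n_boot, len(predictors) + 1))
    boots_beta = np.empty((n_boot, len(predictors)))
    boots_r2 = np.empty(n_boot)
    idx_all = np.arange(n)
    for b_i in range(n_boot):
        idx = rng.choice(idx_all, size=n, replace=True)
        Xb, yb = X[idx], y[idx]
        try:
            fb = sm.OLS(yb, Xb).fit()
        except np.linalg.LinAlgError:
            boots_b[b_i] = np.nan
            boots_beta[b_i] = np.nan
            boots_r2[b_i] = np.nan
            continue
        boots_b[b_i] = fb.params
        sx = Xb[:, 1:].std(axis=0, ddof=1)
        sy = yb.std(ddof=1)
        boots_beta[b_i] = fb.params[1:] * sx / sy if sy > 0 else np.nan
        boots_r2[b_i] = fb.rsquared

    names = ["Intercept"] + predictors
    pct = lambda a: tuple(np.nanpercentile(a, [2.5, 97.5]).astype(float))
    b = dict(zip(names, fit.params.astype(float)))
    b_ci = {nm: pct(boots_b[:, i]) for i, nm in enumerate(names)}
    beta = dict(zip(predictors, zfit.params[1:].astype(float)))
    beta_ci = {nm: pct(boots_beta[:, i]) for i, nm in enumerate(predictors)}
    p_values = dict(zip(names, fit.pvalues.astype(float)))
    r2_adj = float(fit.rsquared_adj)
    # a perfect (noiseless) fit has unbounded effect size
    f2 = float("inf") if r2_adj >= 1 else cohens_f2(r2_adj)
    return RegressionResult(
        outcome=outcome,
        predictors=predictors,
        b=b,
        b_ci=b_ci,
        beta=beta,
        beta_ci=beta_ci,
        p_values=p_values,
        R2=float(fit.rsquared),
        R2_adj=r2_adj,
        f2=f2,
        model_p=float(fit.f_pvalue),
        r2_ci=pct(boots_r2),
        n=n,
        n_boot=n_boot,
        _model=fit,
    )


def nested_model_f_test(
    reduced: RegressionResult, full: RegressionResult
) -> tuple[float, tuple[int, int], float]:
    """Extra-sum-of-squares F-test comparing nested OLS models.

    Returns (F, (df_num, df_den), p).  Requires the reduced predictors to be
    a strict subset of the full model's, fitted on the same cases.
    """
    if not set(reduced.predictors) < set(full.predictors):
        raise ValueError("models are not nested (reduced ⊄ full)")
    if reduced.n != full.n or reduced.outcome != full.outcome:
        raise ValueError("models must share outcome and cases")
    rss_r = float(reduced._model.ssr)
    rss_f = float(full._model.ssr)
    df_num = len(full.predictors) - len(reduced.predictors)
    df_den = full.n - len(full.predictors) - 1
    tss = float(reduced._model.centered_tss)
    if rss_r <= 1e-12 * max(tss, 1e-300):
        # the reduced model is already a perfect fit; nothing to gain
        return 0.0, (df_num, df_den), 1.0
    F = max(((rss_r - rss_f) / df_num) / (rss_f / df_den), 0.0)
    p = float(stats.f.sf(F, df_num, df_den))
    return float(F), (df_num, df_den), p


# ---------------------------------------------------------------------------
# mediation
# ---------------------------------------------------------------------------


@dataclass
class MediationResult:
    a_path: float            # M ~ X slope
    b_path: float            # Y ~ M slope, controlling X
    direct: float            # c': Y ~ X slope, controlling M
    indirect: float          # a * b
    total: float             # Y ~ X slope
    indirect_se: float
    indirect_ci: tuple[float, float]
    direct_ci: tuple[float, float]
    full_mediation: bool
    n_boot: int
    seed: int


def _ols_slopes(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    return np.linalg.lstsq(sm.add_constant(X), y, rcond=None)[0][1:]


def mediate(
    table: pd.DataFrame,
    x: str,
    mediator: str,
    y: str,
    n_boot: int = 1000,
    seed: int = 0,
) -> MediationResult:
    """Simple-mediation analysis with percentile bootstrap CIs.

    Paths are OLS: a (M~X), b and c' (Y~M+X).  The indirect effect a*b and
    the direct effect c' are bootstrapped over case resamples; "full
    mediation" is flagged when the direct CI covers 0 while the indirect CI
    excludes 0.  On any dataset, total = direct + indirect holds exactly.
    """
    data = table[[x, mediator, y]].dropna()
    if len(data) < 10:
        raise ValueError("need at least 10 complete cases for mediation")
    xv = data[x].to_numpy(float)
    mv = data[mediator].to_numpy(float)
    yv = data[y].to_numpy(float)
    for nm, v in ((x, xv), (mediator, mv), (y, yv)):
        if np.ptp(v) == 0:
            raise ValueError(f"zero variance in {nm!r}")
    a = float(_ols_slopes(mv, xv[:, None])[0])
    bc = _ols_slopes(yv, np.column_stack([mv, xv]))
    b_path, direct = float(bc[0]), float(bc[1])
    total = float(_ols_slopes(yv, xv[:, None])[0])

    rng = np.random.default_rng(seed)
    n = len(data)
    boot_ind = np.empty(n_boot)
    boot_dir = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        xb, mb, yb = xv[idx], mv[idx], yv[idx]
        if np.ptp(xb) == 0 or np.ptp(mb) == 0:
            boot_ind[i] = boot_dir[i] = np.nan
            continue
        ab = float(_ols_slopes(mb, xb[:, None])[0])
        bcb = _ols_slopes(yb, np.column_stack([mb, xb]))
        boot_ind[i] = ab * float(bcb[0])
        boot_dir[i] = float(bcb[1])
    ind_ci = tuple(np.nanpercentile(boot_ind, [2.5, 97.5]).astype(float))
    dir_ci = tuple(np.nanpercentile(boot_dir, [2.5, 97.5]).astype(float))
    full = bool(dir_ci[0] <= 0.0 <= dir_ci[1]) and not bool(ind_ci[0] <= 0.0 <= ind_ci[1])
    return MediationResult(
        a_path=a,
        b_path=b_path,
        direct=direct,
        indirect=a * b_path,
        total=total,
        indirect_se=float(np.nanstd(boot_ind, ddof=1)),
        indirect_ci=ind_ci,
        direct_ci=dir_ci,
        full_mediation=full,
        n_boot=n_boot,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# full battery
# ---------------------------------------------------------------------------

#: one-tailed test directions: are patients expected lower than controls?
GROUP_TEST_DIRECTIONS = {
    "C": "lower",
    "K": "lower",
    "alpha": "lower",
    "t0": "higher",
    "fatigue_mental": "higher",
    "depression": "higher",
    "sleepiness": "higher",
}

CORRELATION_VARIABLES = [
    "C", "PUI", "fatigue_mental", "PD", "depression", "sleepiness",
    "days_since_infection", "age", "K", "t0", "alpha",
]


def analyze_cohort(
    table: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    nonoverlap_vars: tuple[str, ...] = ("C", "K", "t0"),
) -> dict:
    """Run the complete statistical battery on a cohort table.

    Produces analogues of the study's result tables: one-tailed group
    comparisons with effect sizes and BH-FDR (with KDE non-overlap for the
    attention parameters), the patient-group Spearman matrix, the two
    regression models for processing speed with their nested comparison,
    and the mediation of the pupillary-unrest -> capacity association by
    processing speed.
    """
    patients = table[table["group"] == "patient"]
    controls = table[table["group"] == "control"]
    out: dict = {"n_patients": len(patients), "n_controls": len(controls)}

    group_tests = {}
    pvals, keys = [], []
    for var, direction in GROUP_TEST_DIRECTIONS.items():
        # alternative refers to the first sample (controls)
        res = wilcoxon_rank_sum(
            controls[var], patients[var],
            alternative="greater" if direction == "lower" else "less",
        )
        group_tests[var] = res
        pvals.append(res.p)
        keys.append(var)
    adj, rej = bh_fdr(pvals)
    out["group_tests"] = {
        k: {
            "W": t.W, "z": t.z, "r": t.r, "p": t.p,
            "p_fdr": float(a), "significant": bool(s),
        }
        for k, t, a, s in zip(keys, group_tests.values(), adj, rej)
    }

    rng = np.random.default_rng(seed)
    out["nonoverlap"] = {
        v: distribution_nonoverlap(
            controls[v], patients[v], n_boot=n_boot,
            seed=int(rng.integers(0, 2**31 - 1)),
        )["nonoverlap"]
        for v in nonoverlap_vars
    }

    corr = spearman_matrix(patients, CORRELATION_VARIABLES)
    out["correlations"] = {
        "rho": corr.rho.round(3).to_dict(),
        "p_fdr": corr.p_adjusted.round(4).to_dict(),
        "significant": corr.significant.to_dict(),
    }

    model1 = ols_regression(
        patients, "C", ["PUI", "fatigue_mental"],
        n_boot=n_boot, seed=int(rng.integers(0, 2**31 - 1)),
    )
    model2 = ols_regression(
        patients, "C",
        ["PUI", "fatigue_mental", "depression", "sleepiness",
         "days_since_infection", "age"],
        n_boot=n_boot, seed=int(rng.integers(0, 2**31 - 1)),
    )
    F, dfs, p_nested = nested_model_f_test(model1, model2)

    def _reg(r: RegressionResult) -> dict:
        return {
            "b": r.b, "b_ci": r.b_ci, "beta": r.beta, "beta_ci": r.beta_ci,
            "p": r.p_values, "R2": r.R2, "R2_adj": r.R2_adj, "f2": r.f2,
            "model_p": r.model_p, "n": r.n,
        }

    out["regression"] = {
        "model1": _reg(model1),
        "model2": _reg(model2),
        "nested_F": {"F": F, "df": dfs, "p": p_nested},
    }

    med = mediate(
        patients, "PUI", "C", "K",
        n_boot=n_boot, seed=int(rng.integers(0, 2**31 - 1)),
    )
    out["mediation"] = {
        "a_path": med.a_path, "b_path": med.b_path,
        "direct": med.direct, "direct_ci": med.direct_ci,
        "indirect": med.indirect, "indirect_se": med.indirect_se,
        "indirect_ci": med.indirect_ci, "total": med.total,
        "full_mediation": med.full_mediation,
    }
    return out
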