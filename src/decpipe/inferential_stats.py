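"""Group and symptom-association statistics for DEC summaries.

Implements the full inferential layer: covariate-adjusted MANCOVA with
Pillai's trace for omnibus group differences across a set of
connections, Bonferroni-corrected post-hoc per-connection regressions,
effect sizes (Cohen's d from t with a normal-approximation CI; Pearson
r with Fisher-z CI), a multiple regression of symptom severity on
connection means, a medication-by-connectivity interaction model, and
the summary-statistic arithmetic (pooled two-sample t from printed
means/SDs, Yates-corrected chi-squared from 2x2 counts) that lets every
printed demographic comparison be recomputed exactly.

Conventions: pooled-variance (not Welch) t tests; chi-squared with the
Yates continuity correction; two-sided p-values throughout except the
optional one-sided sample-size calculation; gender enters design
matrices as a binary numeric covariate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats

__all__ = [
    "TTestResult",
    "Chi2Result",
    "EffectSize",
    "PearsonResult",
    "MancovaResult",
    "RegressionTerm",
    "RegressionResult",
    "pooled_t_from_summary",
    "yates_chi2",
    "cohens_d_from_t",
    "pearson_test",
    "mancova_pillai",
    "posthoc_group_regressions",
    "symptom_regression",
    "medication_interaction",
    "required_n",
    "bonferroni",
]


def bonferroni(p: float, m: int) -> float:
    """Family-wise corrected p-value, ``min(1, m * p)``."""
    return min(1.0, m * p)


# ---------------------------------------------------------------------------
# summary-statistic arithmetic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float


def pooled_t_from_summary(m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int) -> TTestResult:
    """Pooled-variance two-sample t test from group summary statistics.

    ``df = n1 + n2 - 2``; equal means with zero pooled variance give
    t = 0, unequal means with zero variance are refused (infinite t).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    if sp2 == 0:
        if m1 == m2:
            return TTestResult(0.0, df, 1.0)
        raise ValueError("zero pooled variance with unequal means: t is infinite")
    t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * spstats.t.sf(abs(t), df)
    return TTestResult(float(t), df, float(p))


@dataclass(frozen=True)
class Chi2Result:
    chi2: float
    df: int
    p: float


def yates_chi2(a: int, b: int, c: int, d: int) -> Chi2Result:
    """Continuity-corrected chi-squared for a 2x2 table ``[[a, b], [c, d]]``.

    ``chi2 = n * max(|ad - bc| - n/2, 0)^2 / (r1 r2 c1 c2)`` on 1 df.
    """
    counts = np.array([a, b, c, d], dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    n = counts.sum()
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("all table margins must be positive")
    num = n * max(abs(a * d - b * c) - n / 2.0, 0.0) ** 2
    chi2 = num / (r1 * r2 * c1 * c2)
    return Chi2Result(float(chi2), 1, float(spstats.chi2.sf(chi2, 1)))


@dataclass(frozen=True)
class EffectSize:
    d: float
    ci_low: float
    ci_high: float
    n1: int
    n2: int


def cohens_d_from_t(t: float, n1: int, n2: int) -> EffectSize:
    """Cohen's d (magnitude) from a two-sample t statistic, with 95% CI.

    ``d = |t| sqrt(1/n1 + 1/n2)``; the CI uses the standard variance
    approximation ``(n1+n2)/(n1 n2) + d^2 / (2 (n1+n2))`` with z = 1.96.
    Invariant to the sign of t.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    d = abs(t) * np.sqrt(1.0 / n1 + 1.0 / n2)
    se = np.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2.0 * (n1 + n2)))
    return EffectSize(float(d), float(d - 1.96 * se), float(d + 1.96 * se), n1, n2)


@dataclass(frozen=True)
class PearsonResult:
    r: float
    n: int
    p: float
    ci_low: float
    ci_high: float
    degenerate: bool = False


def pearson_test(r: float, n: int) -> PearsonResult:
    """Two-sided p and Fisher-z 95% CI for a correlation coefficient.

    ``t = r sqrt((n-2)/(1-r^2))`` on n-2 df; the CI is
    ``tanh(atanh(r) +/- 1.96 / sqrt(n-3))``.  ``|r| = 1`` yields p = 0
    with a degenerate CI flag.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if abs(r) > 1:
        raise ValueError("|r| must not exceed 1")
    if abs(r) == 1:
        return PearsonResult(float(r), n, 0.0, float(r), float(r), degenerate=True)
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * spstats.t.sf(abs(t), n - 2)
    half = 1.96 / np.sqrt(n - 3)
    lo, hi = np.tanh(np.arctanh(r) - half), np.tanh(np.arctanh(r) + half)
    return PearsonResult(float(r), n, float(p), float(lo), float(hi))


# ---------------------------------------------------------------------------
# design-matrix helpers
# ---------------------------------------------------------------------------

def _design(columns: dict[str, np.ndarray]) -> tuple[np.ndarray, list[str]]:
    names = ["intercept"] + list(columns)
    n = len(next(iter(columns.values())))
    X = np.column_stack([np.ones(n)] + [np.asarray(v, dtype=float) for v in columns.values()])
    return X, names

def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns from the R diagonal of a QR factorization
        diag = np.abs(np.diag(np.linalg.qr(X, mode="r")))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [names[i] for i in range(len(names)) if i < len(diag) and diag[i] <= tol]
        raise ValueError(f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
                         f"suspect columns: {bad or 'unknown'}")


def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X)


# ---------------------------------------------------------------------------
# MANCOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MancovaResult:
    pillai: float
    f: float
    df_hyp: int
    df_err: int
    p: float
    n: int


def mancova_pillai(Y, group, covariates=None) -> MancovaResult:
    """One-factor MANCOVA: Pillai's trace for the group term.

    ``Y`` is an n x q outcome matrix, ``group`` a binary (2-level)
    factor, ``covariates`` an optional n x k matrix adjusted for in both
    the full and reduced models.  The hypothesis SSCP is the difference
    between the full and group-free projections; Pillai's trace is
    ``tr(H (H + E)^{-1})``, mapped to an F approximation (for a 2-level
    factor, ``F(q, n - rank(X) - q + 1)``).
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, q = Y.shape
    g = _binary_group(group)
    cols = {"group": g}
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        for k in range(C.shape[1]):
            cols[f"cov{k}"] = C[:, k]
    X_full, names = _design(cols)
    if n <= X_full.shape[1] + q:
        raise ValueError("too few observations for the design and outcome dimension")
    _check_full_rank(X_full, names)
    X_red = np.delete(X_full, names.index("group"), axis=1)

    P_full, P_red = _hat(X_full), _hat(X_red)
    E = Y.T @ (np.eye(n) - P_full) @ Y
    H = Y.T @ (P_full - P_red) @ Y
    pillai = float(np.trace(H @ np.linalg.inv(H + E)))

    # F approximation (general Pillai form, s = min(q, hypothesis df) = 1 here)
    q_hyp = 1
    s = min(q, q_hyp)
    m = (abs(q - q_hyp) - 1) / 2.0
    df_model_err = n - X_full.shape[1]
    n_par = (df_model_err - q - 1) / 2.0
    df_hyp = int(s * (2 * m + s + 1))
    df_err = int(s * (2 * n_par + s + 1))
    f = (df_err / df_hyp) * (pillai / s) / (1.0 - pillai / s)
    p = float(spstats.f.sf(f, df_hyp, df_err))
    return MancovaResult(pillai, float(f), df_hyp, df_err, p, n)


def _binary_group(group) -> np.ndarray:
    """0/1 coding of a 2-level factor; 'patient' codes as 1 when present."""
    g = np.asarray(group)
    if g.dtype.kind in "if":
        if len(np.unique(g)) != 2:
            raise ValueError("group must have exactly 2 levels")
        return g.astype(float)
    levels = sorted(pd.unique(pd.Series(g)))
    if len(levels) != 2:
        raise ValueError(f"group must have exactly 2 levels, found {len(levels)}")
    ref = "patient" if "patient" in levels else levels[1]
    return (g == ref).astype(float)


# ---------------------------------------------------------------------------
# OLS layers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionTerm:
    name: str
    beta: float
    t: float
    p: float
    p_corrected: float


@dataclass(frozen=True)
class RegressionResult:
    outcome: str
    terms: list[RegressionTerm]
    df_resid: int
    family_size: int

    def term(self, name: str) -> RegressionTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


def _ols(y: np.ndarray, cols: dict[str, np.ndarray], outcome: str, family_size: int = 1,
         corrected_terms: tuple[str, ...] = ()) -> RegressionResult:
    import statsmodels.api as sm

    X, names = _design(cols)
    _check_full_rank(X, names)
    res = sm.OLS(np.asarray(y, dtype=float), X).fit()
    terms = []
    for i, name in enumerate(names):
        p_raw = float(res.pvalues[i])
        p_corr = bonferroni(p_raw, family_size) if (not corrected_terms or name in corrected_terms) else p_raw
        terms.append(RegressionTerm(name, float(res.params[i]), float(res.tvalues[i]), p_raw, p_corr))
    return RegressionResult(outcome, terms, int(res.df_resid), family_size)


def posthoc_group_regressions(
    table: pd.DataFrame,
    connections: list[str],
    group_col: str = "group",
    covariate_cols: tuple[str, ...] = ("age", "gender", "dvars"),
    family_size: int | None = None,
) -> list[RegressionResult]:
    """Per-connection OLS of DEC on group + covariates, Bonferroni-corrected.

    One model per connection; ``family_size`` defaults to the number of
    connections tested.
    """
    m = family_size if family_size is not None else len(connections)
    g = _binary_group(table[group_col].to_numpy())
    if len(np.unique(g)) < 2:
        raise ValueError("group indicator is constant")
    out = []
    for conn in connections:
        cols = {"group": g}
        for cov in covariate_cols:
            cols[cov] = table[cov].to_numpy(dtype=float)
        out.append(_ols(table[conn].to_numpy(dtype=float), cols, outcome=conn,
                        family_size=m, corrected_terms=("group",)))
    return out


def symptom_regression(
    table: pd.DataFrame,
    symptom_col: str,
    connection_cols: list[str],
    family_size: int | None = None,
) -> RegressionResult:
    """Multiple regression of a symptom score on connection means.

    All connections enter one model; per-connection p-values are
    Bonferroni-corrected over the connection family.
    """
    m = family_size if family_size is not None else len(connection_cols)
    sub = table.dropna(subset=[symptom_col])
    if len(sub) <= len(connection_cols) + 1:
        raise ValueError("too few complete observations for the symptom regression")
    cols = {c: sub[c].to_numpy(dtype=float) for c in connection_cols}
    return _ols(sub[symptom_col].to_numpy(dtype=float), cols, outcome=symptom_col,
                family_size=m, corrected_terms=tuple(connection_cols))


def medication_interaction(
    ybocs: np.ndarray, dec: np.ndarray, medicated: np.ndarray
) -> tuple[RegressionResult, dict[int, PearsonResult]]:
    """Moderation model: symptom ~ DEC * medication status.

    Fits ``ybocs = b0 + b1 dec + b2 med + b3 dec*med`` and additionally
    reports a per-stratum Pearson test of the DEC-symptom correlation.
    Refuses if either medication stratum is empty.
    """
    ybocs = np.asarray(ybocs, dtype=float)
    dec = np.asarray(dec, dtype=float)
    med = np.asarray(medicated, dtype=float)
    if len(np.unique(med)) < 2:
        raise ValueError("both medication strata must be non-empty")
    res = _ols(ybocs, {"dec": dec, "medicated": med, "dec_x_medicated": dec * med},
               outcome="ybocs", family_size=1)
    strata: dict[int, PearsonResult] = {}
    for level in (0, 1):
        mask = med == level
        if mask.sum() >= 4:
            r = float(np.corrcoef(dec[mask], ybocs[mask])[0, 1])
            strata[level] = pearson_test(r, int(mask.sum()))
    return res, strata


# ---------------------------------------------------------------------------
# power / sample size
# ---------------------------------------------------------------------------

def required_n(
    d: float,
    power: float = 0.85,
    alpha: float = 0.05,
    one_sided: bool = True,
    allocation_ratio: float = 1.0,
    max_n: int = 100_000,
) -> int:
    """Smallest total n whose two-sample t test reaches the target power.

    Power is computed exactly from the noncentral t distribution with
    noncentrality ``d sqrt(n1 n2 / (n1 + n2))``; ``allocation_ratio``
    is n1:n2.  Raises if the power is unreachable below ``max_n``.
    """
    if not d > 0:
        raise ValueError("d must be positive")
    if not 0 < power < 1:
        raise ValueError("power must lie in (0, 1)")
    r = allocation_ratio
    for total in range(4, max_n + 1):
        n1 = max(2, int(round(total * r / (1.0 + r))))
        n2 = total - n1
        if n2 < 2:
            continue
        if _t_power(d, n1, n2, alpha, one_sided) >= power:
            return total
    raise ValueError(f"target power {power} unreachable below n = {max_n}")


def _t_power(d: float, n1: int, n2: int, alpha: float, one_sided: bool) -> float:
    df = n1 + n2 - 2
    ncp = d * np.sqrt(n1 * n2 / (n1 + n2))
    if one_sided:
        crit = spstats.t.ppf(1 - alpha, df)
        return float(spstats.nct.sf(crit, df, ncp))
    crit = spstats.t.ppf(1 - alpha / 2, df)
    return float(spstats.nct.sf(crit, df, ncp) + spstats.nct.cdf(-crit, df, ncp))
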