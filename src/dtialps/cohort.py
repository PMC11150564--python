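"""Cohort-level statistics: group comparisons, covariate-adjusted GLM, correlations.

The battery applied to a subject table (one row per subject, T2DM vs HC):

- Shapiro-Wilk normality gate per group, then pooled two-sample t for
  variables normal in both groups (alpha = 0.05), Mann-Whitney U otherwise;
- Pearson chi-square (no continuity correction) for the sex distribution;
- an OLS GLM of the ALPS index on group plus eight covariates (age, sex,
  education years, BMI, triglyceride, total cholesterol, LDL, HDL), with a
  variance-inflation-factor screen of the covariates (VIF_j = 1/(1 - R_j^2));
- Spearman rank correlation and rank-based partial correlation (residualize
  the midranks of x and y on the covariates, correlate the residuals).

The pooled/summary t-test is implemented from the textbook formulas so that
the raw-data and summary-statistic paths agree algebraically, and so that
printed group summaries (mean +/- SD, n) from a publication table can be
re-tested directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .exceptions import DtialpsError, ValidationError

__all__ = [
    "TestResult",
    "GlmResult",
    "CorrelationResult",
    "shapiro_wilk",
    "two_sample_t_from_summary",
    "two_sample_t",
    "mann_whitney_u",
    "chi_square_2x2",
    "fit_alps_glm",
    "spearman_corr",
    "partial_corr",
    "table1_report",
    "GLM_COVARIATES",
]

#: the eight nuisance covariates controlled for in the ALPS group GLM
GLM_COVARIATES = (
    "age",
    "sex",
    "education_years",
    "BMI",
    "triglyceride",
    "cholesterol",
    "LDL",
    "HDL",
)


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p: float
    df: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ValidationError(f"p-value {self.p} outside [0, 1]")


@dataclass(frozen=True)
class CorrelationResult:
    method: str
    r: float
    p: float
    n: int
    covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if np.isfinite(self.r) and abs(self.r) > 1 + 1e-12:
            raise ValidationError(f"|r| = {abs(self.r)} exceeds 1")


@dataclass
class GlmResult:
    """ALPS-on-group OLS fit with covariate VIFs."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    group_effect: float
    group_se: float
    group_t: float
    group_p: float
    vif: pd.Series
    n: int
    df_resid: float

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "df_resid": self.df_resid,
            "group_effect": self.group_effect,
            "group_se": self.group_se,
            "group_t": self.group_t,
            "group_p": self.group_p,
            "coefficients": self.params.to_dict(),
            "vif": self.vif.to_dict(),
        }


def shapiro_wilk(values) -> TestResult:
    """Shapiro-Wilk W and p (Royston algorithm, via scipy)."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3 or x.size > 5000:
        raise ValidationError(f"Shapiro-Wilk needs 3 <= n <= 5000, got {x.size}")
    if np.ptp(x) == 0:
        raise ValidationError("Shapiro-Wilk is undefined for constant input")
    w, p = stats.shapiro(x)
    return TestResult(test_name="shapiro_wilk", statistic=float(w), p=float(p))


def two_sample_t_from_summary(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    variant: str = "pooled",
) -> TestResult:
    """Independent two-sample t-test from group summaries (mean, SD, n).

    ``variant="pooled"`` (Student, default): pooled variance, df = n1+n2-2.
    ``variant="welch"``: unpooled variance with Welch-Satterthwaite df.
    """
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs n >= 2")
    if not (sd1 > 0 and sd2 > 0):
        raise ValidationError("group SDs must be positive")
    v1, v2 = sd1**2, sd2**2
    if variant == "pooled":
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = n1 + n2 - 2
        name = "student_t"
    elif variant == "welch":
        a, b = v1 / n1, v2 / n2
        se = np.sqrt(a + b)
        df = (a + b) ** 2 / (a**2 / (n1 - 1) + b**2 / (n2 - 1))
        name = "welch_t"
    else:
        raise ValueError(f"unknown t-test variant {variant!r}")
    t = (mean1 - mean2) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(test_name=name, statistic=float(t), p=float(p), df=float(df))


def two_sample_t(group1, group2, variant: str = "pooled") -> TestResult:
    """Independent two-sample t-test on raw per-group values.

    Computed through :func:`two_sample_t_from_summary` on the sample moments,
    so the two paths agree exactly.
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if x.size < 2 or y.size < 2:
        raise ValidationError("each group needs n >= 2 finite values")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        if x.mean() == y.mean():
            return TestResult(
                test_name="student_t", statistic=0.0, p=1.0, df=float(x.size + y.size - 2)
            )
        raise ValidationError("both groups constant with unequal means")
    return two_sample_t_from_summary(
        x.mean(), x.std(ddof=1), x.size, y.mean(), y.std(ddof=1), y.size, variant
    )


def mann_whitney_u(group1, group2) -> TestResult:
    """Mann-Whitney U test, two-sided.

    Exact enumeration when n1 + n2 <= 12 and there are no ties; otherwise the
    normal approximation with tie correction (no continuity correction, so a
    centred statistic gives exactly p = 1).
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if x.size < 1 or y.size < 1:
        raise ValidationError("each group needs at least one value")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if np.ptp(pooled) == 0:
        return TestResult(
            test_name="mann_whitney_u", statistic=float(x.size * y.size / 2.0), p=1.0
        )
    if x.size + y.size <= 12 and not has_ties:
        u, p = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        u, p = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
    return TestResult(test_name="mann_whitney_u", statistic=float(u), p=float(p))


def chi_square_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Pearson chi-square on the 2x2 table [[a, b], [c, d]], no continuity correction."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0):
        raise ValidationError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValidationError("chi-square requires positive margins")
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    chi2 = float(((table - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return TestResult(test_name="chi_square", statistic=chi2, p=p, df=1.0)


def _encode_sex(col: pd.Series) -> pd.Series:
    """Code sex 0/1 (F=0, M=1); numeric input passes through."""
    if pd.api.types.is_numeric_dtype(col):
        return col.astype(float)
    mapping = {"F": 0.0, "M": 1.0, "female": 0.0, "male": 1.0}
    out = col.map(lambda v: mapping.get(str(v), np.nan))
    if out.isna().any() and col.notna().any():
        bad = col[out.isna() & col.notna()].iloc[0]
        raise ValidationError(f"cannot encode sex value {bad!r}")
    return out


def fit_alps_glm(cohort: pd.DataFrame, outcome: str = "alps") -> GlmResult:
    """OLS of the ALPS index on group + the eight standard covariates.

    The group indicator codes T2DM=1, HC=0, so a negative group effect means
    a lower index in patients. VIFs are computed for every covariate from the
    auxiliary regression of that covariate on the others (intercept included,
    group excluded from the screen). Complete cases only; needs >= 15.
    """
    cols = [outcome, "group", *GLM_COVARIATES]
    missing = [c for c in cols if c not in cohort.columns]
    if missing:
        raise ValidationError(f"cohort table lacks columns {missing}")
    df = cohort[cols].copy()
    df["sex"] = _encode_sex(df["sex"])
    df["group"] = (df["group"].astype(str) == "T2DM").astype(float)
    df = df.apply(pd.to_numeric)
    df = df.dropna()
    n = len(df)
    if n < 15:
        raise ValidationError(f"only {n} complete cases; need >= 15")

    X = sm.add_constant(df[["group", *GLM_COVARIATES]], has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = np.corrcoef(df[list(GLM_COVARIATES)].to_numpy().T)
        dup = [
            (GLM_COVARIATES[i], GLM_COVARIATES[j])
            for i in range(len(GLM_COVARIATES))
            for j in range(i + 1, len(GLM_COVARIATES))
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ValidationError(f"design is rank deficient; collinear columns: {dup}")
    fit = sm.OLS(df[outcome], X).fit()

    vif_exog = sm.add_constant(df[list(GLM_COVARIATES)], has_constant="add").to_numpy()
    vif = pd.Series(
        [variance_inflation_factor(vif_exog, i + 1) for i in range(len(GLM_COVARIATES))],
        index=list(GLM_COVARIATES),
        name="VIF",
    )
    return GlmResult(
        params=fit.params,
        bse=fit.bse,
        tvalues=fit.tvalues,
        pvalues=fit.pvalues,
        group_effect=float(fit.params["group"]),
        group_se=float(fit.bse["group"]),
        group_t=float(fit.tvalues["group"]),
        group_p=float(fit.pvalues["group"]),
        vif=vif,
        n=n,
        df_resid=float(fit.df_resid),
    )


def _corr_p_from_t(r: float, df: int) -> float:
    """Two-sided p for a correlation via the t approximation with given df."""
    if df <= 0:
        return float("nan")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df))


def spearman_corr(x, y) -> CorrelationResult:
    """Spearman rank correlation: Pearson correlation of midranks, t-approx p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 4:
        raise ValidationError(f"Spearman correlation needs n >= 4, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("Spearman correlation is undefined for constant input")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    r = float(np.corrcoef(rx, ry)[0, 1])
    return CorrelationResult(method="spearman", r=r, p=_corr_p_from_t(r, n - 2), n=n)


def partial_corr(x, y, covariates, rank_based: bool = True) -> CorrelationResult:
    """Partial correlation of x and y given covariates.

    x, y, and each covariate are residualized on the covariates (plus an
    intercept) by least squares and the residuals are correlated; when
    ``rank_based`` (default) all variables are midrank-transformed first, so
    with no covariates the result reduces exactly to the Spearman correlation.
    p uses the t approximation with df = n - n_covariates - 2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cov = np.asarray(covariates, dtype=float)
    if cov.size == 0:
        cov = np.empty((x.size, 0))
    elif cov.ndim == 1:
        cov = cov[:, None]
    if cov.shape[0] != x.size:
        cov = cov.T
    ok = np.isfinite(x) & np.isfinite(y) & np.isfinite(cov).all(axis=1)
    x, y, cov = x[ok], y[ok], cov[ok]
    n = x.size
    k = cov.shape[1]
    if n <= k + 3:
        raise ValidationError(f"partial correlation needs n > {k + 3}, got {n}")
    if rank_based:
        x = stats.rankdata(x)
        y = stats.rankdata(y)
        cov = np.column_stack([stats.rankdata(cov[:, j]) for j in range(k)]) if k else cov
    Z = np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValidationError("covariates are rank deficient")
    coef, *_ = np.linalg.lstsq(Z, np.column_stack([x, y]), rcond=None)
    resid = np.column_stack([x, y]) - Z @ coef
    rx, ry = resid[:, 0], resid[:, 1]
    # a variable fully explained by the covariates carries no extra signal:
    # its partial correlation with anything is zero by convention
    tol = 1e-10
    if (np.linalg.norm(rx) < tol * max(np.linalg.norm(x), 1.0)
            or np.linalg.norm(ry) < tol * max(np.linalg.norm(y), 1.0)):
        return CorrelationResult(
            method="partial", r=0.0, p=1.0, n=n,
            covariates=tuple(f"c{j}" for j in range(k)),
        )
    r = float(np.corrcoef(rx, ry)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    return CorrelationResult(
        method="partial",
        r=r,
        p=_corr_p_from_t(r, n - k - 2),
        n=n,
        covariates=tuple(f"c{j}" for j in range(k)),
    )


#: continuous variables reported in the demographics table, in display order
TABLE1_CONTINUOUS = (
    "age",
    "BMI",
    "HbA1c",
    "insulin",
    "FG",
    "cholesterol",
    "triglyceride",
    "HDL",
    "LDL",
    "Hcy",
    "SDMT",
    "MoCA",
    "MMSE",
)


def table1_report(cohort: pd.DataFrame, alpha_normality: float = 0.05) -> pd.DataFrame:
    """Demographics-table battery: normality-gated t / Mann-Whitney + sex chi-square.

    For each continuous variable the Shapiro-Wilk gate is applied per group;
    the pooled t-test is used only if both groups pass (p > alpha in each),
    otherwise the Mann-Whitney U. Sex is compared by Pearson chi-square.
    Missing columns are skipped. Returns a tidy frame with one row per
    variable: summaries, test name, statistic, and two-sided p.
    """
    g = cohort["group"].astype(str)
    t2dm = cohort[g == "T2DM"]
    hc = cohort[g == "HC"]
    rows = []
    for var in TABLE1_CONTINUOUS:
        if var not in cohort.columns:
            continue
        a = t2dm[var].dropna().to_numpy(dtype=float)
        b = hc[var].dropna().to_numpy(dtype=float)
        if a.size < 3 or b.size < 3:
            continue
        try:
            normal = (
                shapiro_wilk(a).p > alpha_normality
                and shapiro_wilk(b).p > alpha_normality
            )
        except DtialpsError:
            normal = False
        res = two_sample_t(a, b) if normal else mann_whitney_u(a, b)
        rows.append(
            {
                "variable": var,
                "t2dm_mean": a.mean(),
                "t2dm_sd": a.std(ddof=1),
                "hc_mean": b.mean(),
                "hc_sd": b.std(ddof=1),
                "test_name": res.test_name,
                "statistic": res.statistic,
                "p": res.p,
            }
        )
    if "sex" in cohort.columns:
        sx_t = _encode_sex(t2dm["sex"])
        sx_h = _encode_sex(hc["sex"])
        res = chi_square_2x2(
            int((sx_t == 0).sum()),
            int((sx_t == 1).sum()),
            int((sx_h == 0).sum()),
            int((sx_h == 1).sum()),
        )
        rows.append(
            {
                "variable": "sex",
                "t2dm_mean": float((sx_t == 0).mean()),
                "t2dm_sd": np.nan,
                "hc_mean": float((sx_h == 0).mean()),
                "hc_sd": np.nan,
                "test_name": res.test_name,
                "statistic": res.statistic,
                "p": res.p,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "variable",
            "t2dm_mean",
            "t2dm_sd",
            "hc_mean",
            "hc_sd",
            "test_name",
            "statistic",
            "p",
        ],
    )
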