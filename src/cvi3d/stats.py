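"""Agreement and association statistics for per-eye CVI/SFCT cohorts.

Covers the statistical layer of a CVI reliability study: coefficient of
variation for comparing variability across differently scaled measures,
ICC(2,1) (two-way random effects, absolute agreement, single measurement)
with an F-based confidence interval, Bland-Altman mean difference and 95%
limits of agreement, the F-test of variance equality, one-way ANOVA and
chi-square group comparisons, a univariate regression screen feeding a
multivariable OLS model, and quintile-stratified sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import UndefinedValueError, ValidationError

#: Reference levels for categorical predictors; anything not listed uses its
#: most frequent level as reference.
DEFAULT_REFERENCE_LEVELS = {"ethnicity": "Chinese"}


@dataclass(frozen=True)
class IccResult:
    """ICC(2,1) estimate with a 95% F-based confidence interval and the
    conventional qualitative reliability band."""

    value: float
    ci_low: float
    ci_high: float
    quality: str


@dataclass(frozen=True)
class BlandAltmanResult:
    """Paired-difference agreement: mean difference (with t-based CI) and
    95% limits of agreement (mean +/- 1.96 * SD of the differences)."""

    mean_diff: float
    mean_diff_ci: tuple[float, float]
    loa: tuple[float, float]


@dataclass(frozen=True)
class RegressionResult:
    """Fitted OLS summary: one row per term (estimate, std_error, p) plus
    model-level adjusted R^2 and overall F-test p."""

    terms: pd.DataFrame
    adj_r2: float
    model_p: float
    predictors: tuple[str, ...]


def icc_quality(value: float) -> str:
    """Conventional reliability band: <0.5 poor, 0.5-0.75 moderate,
    0.75-0.9 good, >0.9 excellent."""
    if value < 0.5:
        return "poor"
    if value < 0.75:
        return "moderate"
    if value <= 0.9:
        return "good"
    return "excellent"


def cov_percent(mean, sd: float | None = None, ndigits: int | None = 2) -> float:
    """Coefficient of variation, 100 * SD / mean, as a percentage.

    Accepts either a (mean, sd) pair or a raw sample (computing its mean and
    n-1 SD first).  Reported to 2 decimals by default; pass ``ndigits=None``
    for full precision.
    """
    if sd is None:
        sample = np.asarray(mean, dtype=np.float64)
        if sample.ndim != 1 or sample.size < 2:
            raise ValidationError("a raw sample needs at least two values")
        mean = float(sample.mean())
        sd = float(sample.std(ddof=1))
    if sd < 0:
        raise ValidationError("sd must be non-negative")
    if mean == 0:
        raise UndefinedValueError("COV undefined for zero mean")
    value = 100.0 * sd / mean
    return round(value, ndigits) if ndigits is not None else value


def icc_2_1(ratings: np.ndarray, alpha: float = 0.05) -> IccResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is an n-subjects x k-raters matrix with no missing cells.
    The estimate comes from the two-way ANOVA mean squares,

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n) (MSC - MSE)),

    and the confidence interval from the standard F-based construction with
    Satterthwaite degrees of freedom for the lower/upper F quantiles.
    """
    x = np.asarray(ratings, dtype=np.float64)
    if x.ndim != 2:
        raise ValidationError("ratings must be a 2D subjects x raters matrix")
    n, k = x.shape
    if n < 3 or k < 2:
        raise ValidationError("need at least 3 subjects and 2 raters")
    if np.isnan(x).any():
        raise ValidationError("missing cells are not supported (no imputation)")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((x - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = max(sse / ((n - 1) * (k - 1)), 0.0)

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise UndefinedValueError("ICC undefined: no variance in the data")
    icc = (msr - mse) / denom

    if mse == 0 and msc == 0:
        return IccResult(1.0, 1.0, 1.0, icc_quality(1.0))

    a = (k * icc) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    if np.isfinite(a) and (a * msc + b * mse) > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_lo = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f_hi = sps.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - f_lo * mse) / (
            f_lo * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        upper = n * (f_hi * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_hi * msr
        )
    else:  # perfect agreement up to numerical noise
        lower = upper = icc
    return IccResult(float(icc), float(lower), float(upper), icc_quality(float(icc)))


def bland_altman(x, y, alpha: float = 0.05) -> BlandAltmanResult:
    """Bland-Altman agreement of two paired measurement series.

    The mean difference equals mean(x) - mean(y) exactly; the limits of
    agreement are mean +/- 1.96 * SD of the paired differences (n-1 SD) and
    the CI of the mean difference is the usual t-interval.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("paired series must be 1D and of equal length")
    n = x.size
    if n < 3:
        raise ValidationError("need at least 3 pairs")
    d = x - y
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    half = 1.96 * sd
    t_half = float(sps.t.ppf(1 - alpha / 2, n - 1)) * sd / np.sqrt(n)
    return BlandAltmanResult(
        mean_diff=mean_diff,
        mean_diff_ci=(mean_diff - t_half, mean_diff + t_half),
        loa=(mean_diff - half, mean_diff + half),
    )


def f_test_equal_variance(x, y) -> tuple[float, float]:
    """F-test of variance equality: F = var(x)/var(y) (sample variances),
    two-sided p = 2 * min(P(F<=f), P(F>=f)) on F(n_x-1, n_y-1)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 2 or y.size < 2:
        raise ValidationError("each sample needs at least 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vy == 0:
        raise UndefinedValueError("zero variance in the denominator sample")
    f = vx / vy
    dist = sps.f(x.size - 1, y.size - 1)
    p = 2.0 * min(dist.cdf(f), dist.sf(f))
    return float(f), float(min(p, 1.0))


def _expand_predictor(
    cohort: pd.DataFrame, predictor: str, reference_levels: dict | None
) -> pd.DataFrame | None:
    """Design columns for one predictor: the column itself if numeric,
    indicator contrasts against a reference level if categorical.
    Returns None for a constant predictor."""
    col = cohort[predictor]
    if pd.api.types.is_numeric_dtype(col) and col.nunique() > 2:
        if col.nunique() < 2:
            return None
        return col.to_frame(predictor).astype(float)
    # categorical (or binary-coded numeric): indicators vs reference
    levels = col.value_counts()
    if len(levels) < 2:
        return None
    refs = dict(DEFAULT_REFERENCE_LEVELS)
    if reference_levels:
        refs.update(reference_levels)
    ref = refs.get(predictor, levels.index[0])  # most frequent by default
    out = {}
    for level in sorted(lv for lv in levels.index if lv != ref):
        out[f"{predictor}[{level}]"] = (col == level).astype(float)
    return pd.DataFrame(out, index=cohort.index)


def univariate_screen(
    cohort: pd.DataFrame,
    outcome: str,
    predictors: list[str],
    reference_levels: dict | None = None,
) -> pd.DataFrame:
    """One simple OLS regression of ``outcome`` per predictor.

    Returns a tidy frame with one row per term (categorical predictors
    contribute one indicator term per non-reference level): estimate,
    std_error, two-sided p, and the minimum term p per predictor used by the
    multivariable screen.  Constant predictors are flagged and excluded.
    """
    y = cohort[outcome].to_numpy(dtype=float)
    rows = []
    for predictor in predictors:
        design = _expand_predictor(cohort, predictor, reference_levels)
        if design is None:
            rows.append(
                {
                    "predictor": predictor,
                    "term": predictor,
                    "estimate": np.nan,
                    "std_error": np.nan,
                    "p": np.nan,
                    "excluded": True,
                }
            )
            continue
        X = sm.add_constant(design.to_numpy(dtype=float))
        fit = sm.OLS(y, X).fit()
        for j, term in enumerate(design.columns, start=1):
            rows.append(
                {
                    "predictor": predictor,
                    "term": term,
                    "estimate": fit.params[j],
                    "std_error": fit.bse[j],
                    "p": fit.pvalues[j],
                    "excluded": False,
                }
            )
    return pd.DataFrame(rows)


def multivariable_model(
    cohort: pd.DataFrame,
    outcome: str,
    predictors: list[str],
    screen_alpha: float = 0.05,
    age_col: str = "age",
    reference_levels: dict | None = None,
) -> RegressionResult:
    """Multivariable OLS on age plus the univariately significant predictors.

    Predictors whose univariate screen yields any term with p < screen_alpha
    join ``age_col`` in the final model (age is always retained); if nothing
    passes the screen, the model is outcome ~ age alone.
    """
    screen = univariate_screen(cohort, outcome, predictors, reference_levels)
    passing = (
        screen[~screen["excluded"]]
        .groupby("predictor")["p"]
        .min()
        .pipe(lambda s: s[s < screen_alpha])
        .index.tolist()
    )
    selected = [age_col] + [p for p in predictors if p in passing and p != age_col]

    blocks = []
    for predictor in selected:
        design = _expand_predictor(cohort, predictor, reference_levels)
        if design is not None:
            blocks.append(design)
    design = pd.concat(blocks, axis=1)
    X = sm.add_constant(design.to_numpy(dtype=float))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError(
            f"rank-deficient design among columns {list(design.columns)}"
        )
    fit = sm.OLS(cohort[outcome].to_numpy(dtype=float), X).fit()
    terms = pd.DataFrame(
        {
            "term": ["intercept"] + list(design.columns),
            "estimate": fit.params,
            "std_error": fit.bse,
            "p": fit.pvalues,
        }
    )
    return RegressionResult(
        terms=terms,
        adj_r2=float(fit.rsquared_adj),
        model_p=float(fit.f_pvalue),
        predictors=tuple(selected),
    )


def group_compare(cohort: pd.DataFrame, group_col: str, var: str) -> float:
    """Across-group comparison p-value: one-way ANOVA for a numeric variable,
    Pearson chi-square (no continuity correction) for a categorical one."""
    groups = [g for _, g in cohort.groupby(group_col, observed=True)[var]]
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    if pd.api.types.is_numeric_dtype(cohort[var]) and cohort[var].nunique() > 2:
        if any(len(g) < 2 for g in groups):
            raise ValidationError("ANOVA needs at least 2 observations per group")
        return float(sps.f_oneway(*groups).pvalue)
    table = pd.crosstab(cohort[group_col], cohort[var])
    return float(sps.chi2_contingency(table.to_numpy(), correction=False).pvalue)


def quintile_stratified_sample(
    values: pd.Series, per_stratum: int, seed: int
) -> list:
    """Quintile-stratified random sample: split at the 20/40/60/80th
    percentiles (inclusive linear interpolation; boundary ties go to the
    lower stratum) and draw ``per_stratum`` ids uniformly without
    replacement from each quintile.  Deterministic under a fixed seed."""
    values = pd.Series(values)
    if len(values) < 5 * per_stratum:
        raise ValidationError("population smaller than 5 * per_stratum")
    cuts = np.percentile(values.to_numpy(dtype=float), [20, 40, 60, 80])
    strata = np.searchsorted(cuts, values.to_numpy(dtype=float), side="left")
    rng = np.random.default_rng(seed)
    selected: list = []
    for q in range(5):
        ids = values.index[strata == q]
        if len(ids) < per_stratum:
            raise ValidationError(
                f"quintile {q + 1} has {len(ids)} members, need {per_stratum}"
            )
        pick = rng.choice(len(ids), size=per_stratum, replace=False)
        selected.extend(ids[np.sort(pick)])
    return selected


def quintile_rank(values: pd.Series) -> pd.Series:
    """1-based quintile rank with the same split convention as
    :func:`quintile_stratified_sample`."""
    arr = pd.Series(values).to_numpy(dtype=float)
    cuts = np.percentile(arr, [20, 40, 60, 80])
    return pd.Series(
        np.searchsorted(cuts, arr, side="left") + 1, index=pd.Series(values).index
    )


# ---------------------------------------------------------------------------
# Report assembly

AGREEMENT_REGIONS = ("whole", "superior", "central", "inferior")
SUBSET_PAIRS = ((11, 21), (11, 31), (21, 31))


def _agreement_row(label: str, x: np.ndarray, y: np.ndarray) -> dict:
    icc = icc_2_1(np.column_stack([x, y]))
    ba = bland_altman(x, y)
    f_stat, f_p = f_test_equal_variance(x, y)
    return {
        "comparison": label,
        "icc": round(icc.value, 3),
        "icc_ci_low": round(icc.ci_low, 3),
        "icc_ci_high": round(icc.ci_high, 3),
        "loa_low": round(ba.loa[0], 2),
        "loa_high": round(ba.loa[1], 2),
        "mean_diff": round(ba.mean_diff, 2),
        "mean_diff_ci_low": round(ba.mean_diff_ci[0], 2),
        "mean_diff_ci_high": round(ba.mean_diff_ci[1], 2),
        "f_p": round(f_p, 3),
    }


def build_report(
    cohort: pd.DataFrame,
    covariates: list[str] | None = None,
    outcome: str = "cvi3d_whole",
    screen_alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Assemble the study's four report tables from a measured cohort.

    Returns a dict with keys ``characteristics`` (per-variable overall
    mean/SD or counts with an across-quintile comparison p), ``agreement``
    (2D subfoveal vs each 3D region: ICC, limits of agreement, mean
    difference, F-test), ``scanning_volume`` (11/21/31-scan pairwise
    agreement), and ``regression`` (univariate screen plus the multivariable
    model for ``outcome``).
    """
    required = {"cvi2d_subfoveal", "sfct_um"} | {
        f"cvi3d_{r}" for r in AGREEMENT_REGIONS
    } | {f"cvi3d_{k}" for k in (11, 21, 31)}
    missing = sorted(required - set(cohort.columns))
    if missing:
        raise ValidationError(f"cohort table missing columns: {missing}")

    cohort = cohort.copy()
    cohort["sfct_quintile"] = quintile_rank(cohort["sfct_um"])

    char_vars = [
        "sfct_um",
        "cvi3d_whole",
        "cvi3d_superior",
        "cvi3d_central",
        "cvi3d_inferior",
        "cvi2d_subfoveal",
    ] + (covariates or [])
    def _safe_p(var: str) -> float:
        # a quintile with < 2 members makes the ANOVA infeasible; report NaN
        try:
            return round(group_compare(cohort, "sfct_quintile", var), 3)
        except ValidationError:
            return float("nan")

    char_rows = []
    for var in char_vars:
        if pd.api.types.is_numeric_dtype(cohort[var]) and cohort[var].nunique() > 2:
            summary = f"{cohort[var].mean():.2f} ({cohort[var].std(ddof=1):.2f})"
        else:
            counts = cohort[var].value_counts().to_dict()
            summary = "; ".join(f"{k}: {v}" for k, v in counts.items())
        char_rows.append({"variable": var, "summary": summary, "p": _safe_p(var)})
    characteristics = pd.DataFrame(char_rows)

    x = cohort["cvi2d_subfoveal"].to_numpy(dtype=float)
    agreement = pd.DataFrame(
        [
            _agreement_row(
                f"2d_subfoveal_vs_3d_{region}",
                x,
                cohort[f"cvi3d_{region}"].to_numpy(dtype=float),
            )
            for region in AGREEMENT_REGIONS
        ]
    )

    scanning = pd.DataFrame(
        [
            _agreement_row(
                f"{a}_vs_{b}_scans",
                cohort[f"cvi3d_{a}"].to_numpy(dtype=float),
                cohort[f"cvi3d_{b}"].to_numpy(dtype=float),
            )
            for a, b in SUBSET_PAIRS
        ]
    )

    tables = {
        "characteristics": characteristics,
        "agreement": agreement,
        "scanning_volume": scanning,
    }
    if covariates:
        screen = univariate_screen(cohort, outcome, covariates)
        model = multivariable_model(
            cohort, outcome, covariates, screen_alpha=screen_alpha
        )
        tables["regression_univariate"] = screen
        tables["regression_multivariable"] = model.terms.assign(
            adj_r2=model.adj_r2, model_p=model.model_p
        )
    return tables
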