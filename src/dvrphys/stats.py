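"""Cohort statistics: group tests, covariate separation, correlations.

The comparison machinery for two-group marker/score tables: Welch
(unequal-variance) two-sample t-tests with Satterthwaite degrees of
freedom, Pearson 2x2 chi-square for categorical demographics, linear
fixed-effects separation of age/gender/education, pairwise Pearson
correlations with pairwise-complete deletion, and ordinary
least-squares regression lines.  Significance is reported raw (no
multiplicity correction) with the conventional 0.05 threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


class DegenerateVarianceError(ValueError):
    pass


@dataclass
class TestResult:
    statistic: float
    df: float
    p: float
    estimate: float | tuple
    n: int | tuple

    def __post_init__(self):
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value {self.p} outside [0, 1]")


def _summaries(x):
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    return float(x.mean()), float(x.std(ddof=1)), x.size


def welch_t(m1, s1=None, n1=None, m2=None, s2=None, n2=None) -> TestResult:
    """Welch's unequal-variance two-sample t-test, two-sided.

    Accepts either summary statistics ``(m1, s1, n1, m2, s2, n2)`` or two
    raw vectors ``welch_t(x, y)`` (summaries computed with ddof=1).
    """
    if s1 is None or (n1 is None and m2 is None):
        # vector form: welch_t(x, y)
        x, y = m1, s1 if s1 is not None else n1
        if y is None:
            raise TypeError("welch_t needs two vectors or six summaries")
        m1, s1, n1 = _summaries(x)
        m2, s2, n2 = _summaries(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per group")
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    v1, v2 = s1**2 / n1, s2**2 / n2
    se2 = v1 + v2
    if se2 == 0.0:
        raise DegenerateVarianceError(
            "both group variances are zero; t-statistic undefined")
    t = (m1 - m2) / np.sqrt(se2)
    df = se2**2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(statistic=float(t), df=float(df), p=float(p),
                      estimate=float(m1 - m2), n=(int(n1), int(n2)))


def chi2_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Pearson chi-square on a 2x2 table, df=1, no continuity correction.

    Table rows are (a, b) and (c, d); all margins must be positive.
    """
    for v in (a, b, c, d):
        if v < 0 or v != int(v):
            raise ValueError("counts must be nonnegative integers")
    n = a + b + c + d
    margins = [a + b, c + d, a + c, b + d]
    if min(margins) == 0:
        raise ValueError("chi-square undefined: a table margin is zero")
    chi2 = n * (a * d - b * c) ** 2 / np.prod([float(m) for m in margins])
    p = sps.chi2.sf(chi2, df=1)
    return TestResult(statistic=float(chi2), df=1.0, p=float(p),
                      estimate=float(a * d - b * c) / n, n=int(n))


def covariate_adjust(table: pd.DataFrame, variable: str,
                     covariates=("age", "gender", "education"),
                     reference_group: str = "CS") -> pd.Series:
    """Separate covariate effects from a marker/score by linear regression.

    Ordinary least squares of ``variable`` on the covariates over all
    subjects pooled; the adjusted value is the residual plus the fitted
    value at the reference (control) group's covariate means, so the
    control-group mean is preserved exactly.  Rows with missing values
    stay missing.
    """
    covariates = list(covariates)
    y = pd.to_numeric(table[variable], errors="coerce")
    X = table[covariates].apply(pd.to_numeric, errors="coerce")
    ok = y.notna() & X.notna().all(axis=1)
    if ok.sum() < len(covariates) + 2:
        raise ValueError(f"too few complete cases ({int(ok.sum())}) to adjust "
                         f"{variable!r} for {covariates}")
    Xc = np.column_stack([np.ones(ok.sum()), X[ok].to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        raise ValueError(f"collinear covariates {covariates}")
    beta, *_ = np.linalg.lstsq(Xc, y[ok].to_numpy(dtype=float), rcond=None)
    resid = y[ok].to_numpy(dtype=float) - Xc @ beta
    ref = table["group"] == reference_group
    ref_means = X[ok & ref].mean().to_numpy(dtype=float)
    anchor = float(beta[0] + ref_means @ beta[1:])
    out = pd.Series(np.nan, index=table.index, name=f"{variable}_adj")
    out[ok] = resid + anchor
    return out


def pearson(x, y) -> TestResult:
    """Pearson correlation with two-sided p via the t transform (n-2 df).

    Missing cells are dropped pairwise-complete.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 complete pairs, got {n}")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise DegenerateVarianceError("zero variance in a correlation input")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
        t = np.inf * np.sign(r)
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = 2.0 * sps.t.sf(abs(t), n - 2)
    return TestResult(statistic=float(t), df=float(n - 2), p=float(p),
                      estimate=r, n=n)


def simple_regression(x, y):
    """OLS line y = slope*x + intercept with r^2 and slope p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if x.std() == 0:
        raise DegenerateVarianceError("constant x in regression")
    slope = float(np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1))
    intercept = float(y.mean() - slope * x.mean())
    if y.std() == 0:
        return {"slope": slope, "intercept": intercept, "r2": 0.0,
                "p": 1.0, "n": int(x.size)}
    res = pearson(x, y)
    return {"slope": slope, "intercept": intercept,
            "r2": res.estimate**2, "p": res.p, "n": int(x.size)}


def group_table(table: pd.DataFrame, variables=None,
                covariates=("age", "gender", "education"),
                group_col: str = "group", groups=("CS", "MP")) -> pd.DataFrame:
    """Two-group report: mean (SD), Welch p, before and after adjustment.

    One row per variable with group means/SDs and the Welch p-value on
    the raw values and on the covariate-adjusted values; ``sig_*``
    columns mark p < 0.05 and p < 0.01.  Variables entirely missing in a
    group are reported with NaN statistics and a note.
    """
    g1, g2 = groups
    for g in groups:
        if not (table[group_col] == g).any():
            raise ValueError(f"group {g!r} absent from table")
        if (table[group_col] == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
    if variables is None:
        reserved = {"id", group_col, *covariates}
        variables = [c for c in table.columns if c not in reserved]
    rows = []
    for var in variables:
        row = {"variable": var}
        vals = pd.to_numeric(table[var], errors="coerce")
        note = ""
        for suffix, series in (("", vals), ("_adj", None)):
            if suffix == "_adj":
                try:
                    series = covariate_adjust(table, var, covariates,
                                              reference_group=g1)
                except ValueError as e:
                    note = str(e)
                    for g in groups:
                        row[f"mean_{g}{suffix}"] = np.nan
                        row[f"sd_{g}{suffix}"] = np.nan
                    row[f"p{suffix}"] = np.nan
                    continue
            x1 = series[table[group_col] == g1].dropna()
            x2 = series[table[group_col] == g2].dropna()
            row[f"mean_{g1}{suffix}"] = x1.mean()
            row[f"sd_{g1}{suffix}"] = x1.std(ddof=1)
            row[f"mean_{g2}{suffix}"] = x2.mean()
            row[f"sd_{g2}{suffix}"] = x2.std(ddof=1)
            if len(x1) < 2 or len(x2) < 2:
                note = f"insufficient data in a group for {var!r}"
                row[f"p{suffix}"] = np.nan
                continue
            try:
                row[f"p{suffix}"] = welch_t(x1, x2).p
            except DegenerateVarianceError as e:
                note = str(e)
                row[f"p{suffix}"] = np.nan
        row["n_CS"] = int(vals[table[group_col] == g1].notna().sum())
        row["n_MP"] = int(vals[table[group_col] == g2].notna().sum())
        row["sig_05"] = bool(row.get("p", np.nan) < 0.05)
        row["sig_01"] = bool(row.get("p", np.nan) < 0.01)
        row["sig_05_adj"] = bool(row.get("p_adj", np.nan) < 0.05)
        row["sig_01_adj"] = bool(row.get("p_adj", np.nan) < 0.01)
        row["note"] = note
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")


def correlation_matrix(table: pd.DataFrame, variables) -> pd.DataFrame:
    """Symmetric matrix of pairwise Pearson (r, p, n), NaN where undefined.

    Per-cell failures (zero variance, too few pairs) do not abort the
    matrix; the offending cells are NaN.
    """
    if len(table) < 4:
        raise ValueError("need at least 4 subjects")
    k = len(variables)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(p, 0.0)
    for i in range(k):
        n[i, i] = pd.to_numeric(table[variables[i]], errors="coerce").notna().sum()
        for j in range(i + 1, k):
            try:
                res = pearson(pd.to_numeric(table[variables[i]], errors="coerce"),
                              pd.to_numeric(table[variables[j]], errors="coerce"))
            except ValueError:
                continue
            r[i, j] = r[j, i] = res.estimate
            p[i, j] = p[j, i] = res.p
            n[i, j] = n[j, i] = res.n
    idx = pd.Index(variables, name="variable")
    return pd.concat(
        {"r": pd.DataFrame(r, index=idx, columns=variables),
         "p": pd.DataFrame(p, index=idx, columns=variables),
         "n": pd.DataFrame(n, index=idx, columns=variables)}, axis=1)
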