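"""Cohort statistics relating regional microstructure to age and volume.

The battery: Kolmogorov-Smirnov normality screening, partial Pearson
correlation controlling for sex (optionally also a free-water fraction
covariate), Benjamini-Hochberg FDR within a declared results-table
family, ANCOVA comparing the three age groups with sex as covariate plus
FDR-corrected pairwise post hoc t-tests, Fisher r-to-z comparison of two
correlation strengths, and linear/quadratic age-trend regression with
nested R^2 and the vertex ("peak age") of concave quadratics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

#: Age-group cut points (years): young <= 34, middle 35-54, older >= 55.
GROUP_CUTS = (34, 54)


def assign_age_group(age) -> np.ndarray:
    age = np.asarray(age, dtype=float)
    out = np.where(age <= GROUP_CUTS[0], "young",
                   np.where(age <= GROUP_CUTS[1], "middle", "older"))
    return out


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    covariates: tuple = ()
    fdr_p: float = float("nan")

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError("correlation outside [-1, 1]")


@dataclass(frozen=True)
class GroupComparisonResult:
    f_stat: float
    p: float
    pairwise: dict  # {(g1, g2): (t, raw_p, fdr_p)}


@dataclass(frozen=True)
class AgeTrendFit:
    linear_coefficients: tuple  # (intercept, slope)
    quadratic_coefficients: tuple  # (intercept, b1, b2)
    r2_linear: float
    r2_quadratic: float
    concave: bool
    peak_age: float | None


def _residualize(y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(y.size), covariates])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def partial_pearson(x, y, covariates=None) -> CorrelationResult:
    """Pearson correlation of x and y after regressing out covariates.

    r is the plain Pearson correlation of the OLS residuals of x and y
    on the covariate columns (with intercept); the two-sided p-value
    comes from t = r sqrt((n - 2 - k)/(1 - r^2)) on n - 2 - k degrees of
    freedom.  With no covariates this is the ordinary Pearson r.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if covariates is None or (hasattr(covariates, "__len__") and len(covariates) == 0):
        z = np.empty((x.size, 0))
    else:
        z = np.column_stack(np.atleast_2d(np.asarray(covariates, dtype=float))
                            if np.asarray(covariates).ndim == 1
                            else np.asarray(covariates, dtype=float))
        if z.shape[0] != x.size:
            z = z.T
        if z.shape[0] != x.size:
            raise ValueError("covariate length does not match data")
    k = z.shape[1]
    n = x.size
    if n <= k + 2:
        raise ValueError("need n > number of covariates + 2")
    rx = _residualize(x, z) if k else x - x.mean()
    ry = _residualize(y, z) if k else y - y.mean()
    sx, sy = np.sqrt(np.sum(rx**2)), np.sqrt(np.sum(ry**2))
    # relative floor: residuals indistinguishable from rounding noise mean
    # the input is constant or collinear with the covariates
    floor_x = 1e-10 * max(1e-300, float(np.abs(x - x.mean()).max()))
    floor_y = 1e-10 * max(1e-300, float(np.abs(y - y.mean()).max()))
    if sx <= floor_x * np.sqrt(n) or sy <= floor_y * np.sqrt(n):
        raise ValueError("zero residual variance (constant or collinear input)")
    r = float(np.clip(np.sum(rx * ry) / (sx * sy), -1.0, 1.0))
    df = n - 2 - k
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r**2))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return CorrelationResult(r=r, p=p, n=n, covariates=tuple(range(k)))


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, <= 1)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def compare_groups_ancova(table: pd.DataFrame, metric: str,
                          group_col: str = "group", sex_col: str = "sex_code",
                          welch: bool = False) -> GroupComparisonResult:
    """ANCOVA group effect (sex-adjusted) plus pairwise post hoc t-tests.

    The F statistic compares the full OLS model (group dummies + sex +
    intercept) to the reduced model (sex + intercept)::

        F = ((RSS_r - RSS_f)/(g-1)) / (RSS_f/(n - g - 1))

    for g groups.  Post hoc comparisons are Student's unpaired
    equal-variance t-tests (Welch optional) with BH-FDR over the three
    pairwise p-values.
    """
    groups = [g for g in ("young", "middle", "older")
              if g in set(table[group_col])]
    if len(groups) < 2:
        raise ValueError("need at least two non-empty groups")
    for g in groups:
        if (table[group_col] == g).sum() < 2:
            raise ValueError(f"empty or singleton group '{g}'")
    y = table[metric].to_numpy(dtype=float)
    sex = table[sex_col].to_numpy(dtype=float)
    n = y.size
    dummies = np.column_stack([(table[group_col] == g).to_numpy(dtype=float)
                               for g in groups[1:]])
    full = np.column_stack([np.ones(n), dummies, sex])
    reduced = np.column_stack([np.ones(n), sex])

    def rss(design):
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        res = y - design @ beta
        return float(res @ res)

    rss_f, rss_r = rss(full), rss(reduced)
    df1 = len(groups) - 1
    df2 = n - len(groups) - 1
    if rss_f <= 0:
        f_stat, p = np.inf, 0.0
    else:
        f_stat = ((rss_r - rss_f) / df1) / (rss_f / df2)
        f_stat = max(f_stat, 0.0)
        p = float(sps.f.sf(f_stat, df1, df2))

    pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
    raw = []
    tstats = []
    for a, b in pairs:
        ya = y[table[group_col] == a]
        yb = y[table[group_col] == b]
        t, pv = sps.ttest_ind(ya, yb, equal_var=not welch)
        tstats.append(float(t))
        raw.append(float(pv))
    adj = fdr_adjust(raw)
    pairwise = {pair: (tstats[i], raw[i], float(adj[i]))
                for i, pair in enumerate(pairs)}
    return GroupComparisonResult(f_stat=float(f_stat), p=p, pairwise=pairwise)


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> tuple:
    """Compare two correlation strengths via Fisher's r-to-z transform.

    z = (atanh|r1| - atanh|r2|) / sqrt(1/(n1-3) + 1/(n2-3)); the sign
    reports which correlation is stronger in magnitude (positive when
    the first is).  Returns (z, two-sided p).
    """
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError("|r| must be < 1")
    for n in (n1, n2):
        if n <= 3:
            raise ValueError("need n > 3")
    z = (np.arctanh(abs(r1)) - np.arctanh(abs(r2))) / np.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = float(2.0 * sps.norm.sf(abs(z)))
    return float(z), p


def fisher_z_compare_dependent(r1: float, r2: float, r12: float, n: int) -> tuple:
    """Steiger comparison of two correlations sharing a variable (non-default).

    ``r12`` is the correlation between the two non-shared variables.
    """
    if n <= 3:
        raise ValueError("need n > 3")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    rbar2 = ((r1 + r2) / 2.0) ** 2
    cov = (r12 * (1 - 2 * rbar2) - 0.5 * rbar2 * (1 - 2 * rbar2 - r12**2)) / (
        (1 - rbar2) ** 2)
    z = (z1 - z2) * np.sqrt((n - 3) / (2.0 * (1.0 - cov)))
    return float(z), float(2.0 * sps.norm.sf(abs(z)))


def polynomial_age_fit(age, values, degree: int = 2) -> AgeTrendFit:
    """Linear and quadratic OLS age trends with nested R^2 and peak age.

    The peak age -b1/(2 b2) is reported only for concave quadratics
    (b2 < 0); concavity is flagged either way.
    """
    age = np.asarray(age, dtype=float)
    y = np.asarray(values, dtype=float)
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    if age.size < degree + 2:
        raise ValueError("too few observations")
    if np.ptp(age) == 0:
        raise ValueError("degenerate design: all ages equal")

    def ols_r2(deg):
        design = np.vander(age, deg + 1, increasing=True)
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        res = y - design @ beta
        tss = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 if tss == 0 else 1.0 - np.sum(res**2) / tss
        return beta, float(r2)

    lin, r2_lin = ols_r2(1)
    quad, r2_quad = ols_r2(2)
    r2_quad = max(r2_quad, r2_lin)  # guard rounding on the nested pair
    concave = quad[2] < 0
    peak = float(-quad[1] / (2.0 * quad[2])) if concave else None
    if peak is not None and not (age.min() <= peak <= age.max()):
        peak = None
    return AgeTrendFit(
        linear_coefficients=tuple(map(float, lin)),
        quadratic_coefficients=tuple(map(float, quad)),
        r2_linear=r2_lin, r2_quadratic=r2_quad,
        concave=bool(concave), peak_age=peak,
    )


def ks_normality(values) -> tuple:
    """One-sample KS test against Normal(mean-hat, sd-hat).

    Plain KS with estimated moments (no Lilliefors correction); the
    returned p-value is therefore conservative only as a screening
    statistic.  Returns (D, p).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 5:
        raise ValueError("need at least 5 observations")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance")
    d, p = sps.kstest(v, "norm", args=(v.mean(), sd))
    return float(d), float(p)


def build_results_table(table: pd.DataFrame, metrics, targets=("age",),
                        covariates=("sex_code",), region_col: str = "region",
                        fdr_family: str = "per_target") -> pd.DataFrame:
    """Partial-correlation matrix of metrics vs targets per region.

    For every metric x region x target cell, computes the partial
    Pearson correlation controlling for ``covariates`` and applies
    BH-FDR within the declared family (``per_target``: all metric x
    region cells of one target; ``global``: everything).  Returns a tidy
    frame with columns metric, region, target, r, p, fdr_p, n.
    """
    for col in list(metrics) + list(targets) + list(covariates):
        if col not in table.columns:
            raise ValueError(f"missing column '{col}'")
    rows = []
    for target in targets:
        for region, sub in table.groupby(region_col, sort=False):
            cov = sub.loc[:, list(covariates)].to_numpy(dtype=float)
            for metric in metrics:
                res = partial_pearson(sub[target].to_numpy(dtype=float),
                                      sub[metric].to_numpy(dtype=float),
                                      cov)
                rows.append({"metric": metric, "region": region,
                             "target": target, "r": res.r, "p": res.p,
                             "n": res.n})
    out = pd.DataFrame(rows)
    if fdr_family == "global":
        out["fdr_p"] = fdr_adjust(out["p"].to_numpy())
    elif fdr_family == "per_target":
        out["fdr_p"] = np.nan
        for target in targets:
            sel = out["target"] == target
            out.loc[sel, "fdr_p"] = fdr_adjust(out.loc[sel, "p"].to_numpy())
    else:
        raise ValueError("fdr_family must be 'per_target' or 'global'")
    return out
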