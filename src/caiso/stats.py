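"""Diagnostic biostatistics, implemented from first principles.

Group contrasts (one-way ANOVA, Kruskal–Wallis with tie correction, Pearson
χ²), product-moment correlation with t-based p-values, backward stepwise
linear regression selected by adjusted R², and ROC analysis with a Youden-J
operating point.  Test statistics are computed from their defining formulas;
only the reference distributions (F, χ², t) come from :mod:`scipy.stats`.

Missing-data policy: pairwise-complete for correlations, listwise-complete
for regression and ROC; every result reports its effective n.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import AnalysisError, CollinearityError, DataError

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "RegressionModel",
    "ROCCurve",
    "one_way_anova",
    "kruskal_wallis",
    "chi_squared",
    "compare_groups",
    "pearson_correlation",
    "backward_stepwise",
    "roc_curve",
    "optimal_cutoff",
    "interpret_auc",
]


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    variable: str
    test: str  # one_way_anova | kruskal_wallis | chi_squared
    statistic: float
    p_value: float
    group_summaries: dict[str, dict[str, float]] = field(default_factory=dict)
    n: int = 0


def one_way_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA F statistic and p-value.

    F = MS_between / MS_within with k−1 and N−k degrees of freedom.  A zero
    within-group mean square with zero between-group mean square (identical
    value multisets) returns F = 0, p = 1.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise AnalysisError("ANOVA needs ≥2 groups with ≥2 values each")
    all_values = np.concatenate(groups)
    grand = all_values.mean()
    n_total = all_values.size
    k = len(groups)
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n_total - k
    ms_between = ss_between / df_b
    ms_within = ss_within / df_w
    if ms_within == 0:
        if ms_between == 0:
            return 0.0, 1.0
        return math.inf, 0.0
    f = ms_between / ms_within
    p = float(sps.f.sf(f, df_b, df_w))
    return float(f), p


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal–Wallis H with tie correction, p from the χ²(k−1) approximation."""
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(g.size < 1 for g in groups):
        raise AnalysisError("Kruskal–Wallis needs ≥2 non-empty groups")
    all_values = np.concatenate(groups)
    n = all_values.size
    ranks = sps.rankdata(all_values)
    idx = 0
    h = 0.0
    for g in groups:
        r = ranks[idx: idx + g.size]
        idx += g.size
        h += g.size * (r.mean() - (n + 1) / 2.0) ** 2
    h *= 12.0 / (n * (n + 1))
    # tie correction
    _, counts = np.unique(all_values, return_counts=True)
    tie = 1.0 - ((counts**3 - counts).sum()) / (n**3 - n) if n > 1 else 1.0
    if tie == 0:
        return 0.0, 1.0
    h /= tie
    p = float(sps.chi2.sf(h, len(groups) - 1))
    return float(h), p


def chi_squared(table: np.ndarray) -> tuple[float, float, int]:
    """Pearson χ² on a contingency table (no continuity correction)."""
    t = np.asarray(table, float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise AnalysisError("contingency table must be at least 2×2")
    if np.any(t < 0):
        raise DataError("negative count in contingency table")
    total = t.sum()
    if total == 0:
        raise AnalysisError("empty contingency table")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(expected > 0, (t - expected) ** 2 / expected, 0.0)
    stat = float(contrib.sum())
    dof = (t.shape[0] - 1) * (t.shape[1] - 1)
    p = float(sps.chi2.sf(stat, dof))
    return stat, p, dof


def compare_groups(
    cohort: pd.DataFrame,
    variable: str,
    test: str = "auto",
    group_col: str = "group",
    normal_vars: tuple[str, ...] = (),
) -> GroupComparison:
    """Compare one variable across the cohort groups with the named test.

    ``auto`` uses Pearson χ² for non-numeric (categorical) variables, ANOVA
    for variables flagged normal, and Kruskal–Wallis otherwise.
    """
    sub = cohort[[group_col, variable]].dropna()
    if sub.empty:
        raise DataError(f"variable {variable!r} is all-missing")
    is_numeric = pd.api.types.is_numeric_dtype(sub[variable]) and not (
        pd.api.types.is_bool_dtype(cohort[variable].dtype)
        or cohort[variable].dtype == object
    )
    if test == "auto":
        if not is_numeric:
            test = "chi_squared"
        elif variable in normal_vars:
            test = "one_way_anova"
        else:
            test = "kruskal_wallis"

    summaries: dict[str, dict[str, float]] = {}
    if test == "chi_squared":
        table = pd.crosstab(sub[group_col], sub[variable])
        stat, p, _ = chi_squared(table.to_numpy())
        for g, row in table.iterrows():
            summaries[str(g)] = {str(k): float(v) for k, v in row.items()}
    else:
        groups = [
            sub.loc[sub[group_col] == g, variable].to_numpy(dtype=float)
            for g in sub[group_col].unique()
        ]
        if test == "one_way_anova":
            stat, p = one_way_anova(groups)
        elif test == "kruskal_wallis":
            stat, p = kruskal_wallis(groups)
        else:
            raise AnalysisError(f"unknown test {test!r}")
        for g in sub[group_col].unique():
            v = sub.loc[sub[group_col] == g, variable].to_numpy(dtype=float)
            summaries[str(g)] = {
                "n": float(v.size),
                "mean": float(v.mean()),
                "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
                "median": float(np.median(v)),
            }
    return GroupComparison(
        variable=variable,
        test=test,
        statistic=stat,
        p_value=p,
        group_summaries=summaries,
        n=int(len(sub)),
    )


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    x_name: str
    y_name: str
    transform: str  # none | log10
    r: float
    p_value: float
    n: int


def pearson_correlation(
    x,
    y,
    transform: str = "none",
    x_name: str = "x",
    y_name: str = "y",
) -> CorrelationResult:
    """Product-moment correlation with a t-distribution p-value (df = n−2).

    ``transform='log10'`` applies a base-10 log to x before correlating
    (biomarkers such as creatinine and FGF23 are log-normal); nonpositive
    values under the log raise a :class:`DataError` naming the record.
    Missing values are removed pairwise.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if transform == "log10":
        bad = np.nonzero(x <= 0)[0]
        if bad.size:
            raise DataError(
                f"log10 transform of {x_name!r}: nonpositive value at record {int(bad[0])}"
            )
        x = np.log10(x)
    elif transform != "none":
        raise AnalysisError(f"unknown transform {transform!r}")
    n = x.size
    if n < 3:
        raise AnalysisError("Pearson correlation needs ≥3 complete pairs")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        raise AnalysisError("zero variance in correlation input")
    r = float((xc * yc).sum() / denom)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1 - r * r))
        p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    return CorrelationResult(x_name, y_name, transform, r, p, n)


# ---------------------------------------------------------------------------
# ordinary least squares and backward stepwise selection
# ---------------------------------------------------------------------------

@dataclass
class OLSFit:
    names: list[str]
    coefs: np.ndarray
    se: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    r2: float
    adj_r2: float
    n: int


@dataclass
class RegressionModel:
    response: str
    terms: list[dict]  # {name, coef, se, p_value}
    intercept: float
    adj_r2: float
    r2: float
    n: int


def _check_rank(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """QR factor of X; raises :class:`CollinearityError` naming dependent terms."""
    n, p = X.shape
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = max(n, p) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    deficient = np.nonzero(diag < tol)[0]
    if deficient.size:
        bad = [names[j] for j in deficient]
        raise CollinearityError(
            f"rank-deficient design; collinear terms: {bad}", terms=bad
        )
    return q, r


def _ols(X: np.ndarray, y: np.ndarray, names: list[str]) -> OLSFit:
    """OLS via QR orthogonalisation; raises on rank deficiency."""
    n, p = X.shape
    if n <= p:
        raise AnalysisError(f"need more observations ({n}) than parameters ({p})")
    q, r = _check_rank(X, names)
    coefs = np.linalg.solve(r, q.T @ y)
    resid = y - X @ coefs
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    dof = n - p
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p) if n > p else -math.inf
    sigma2 = ss_res / dof if dof > 0 else 0.0
    rinv = np.linalg.inv(r)
    cov = sigma2 * (rinv @ rinv.T)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_vals = np.where(se > 0, coefs / se, np.inf * np.sign(coefs))
    p_vals = 2.0 * sps.t.sf(np.abs(t_vals), dof)
    return OLSFit(list(names), coefs, se, t_vals, np.asarray(p_vals, float), r2, adj_r2, n)


def _design(df: pd.DataFrame, cols: list[str]) -> tuple[np.ndarray, list[str]]:
    X = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(float) for c in cols])
    return X, ["(intercept)"] + list(cols)


def backward_stepwise(
    cohort: pd.DataFrame,
    response: str,
    candidates: list[str],
    screen_p: float = 0.2,
) -> RegressionModel:
    """Backward stepwise OLS selected by adjusted R².

    Procedure: (i) screen each candidate by univariable regression and keep
    those with p < ``screen_p``; (ii) fit the full model on the kept set;
    (iii) repeatedly remove the single term whose removal yields the largest
    adjusted R², accepting a removal only if adjusted R² does not decrease
    (ties therefore favour the smaller model); (iv) stop when no removal
    helps.  Rows are deleted listwise over the response and all candidates.
    """
    cols = [response] + list(candidates)
    data = cohort[cols].dropna()
    n = len(data)
    if n < len(candidates) + 5:
        raise AnalysisError(
            f"{n} complete records is too few for {len(candidates)} candidates"
        )
    y = data[response].to_numpy(float)

    # detect a rank-deficient candidate design up front (duplicated or
    # linearly dependent columns), before any screening can mask it
    X_all, names_all = _design(data, list(candidates))
    _check_rank(X_all, names_all)

    kept: list[str] = []
    for c in candidates:
        X, names = _design(data, [c])
        fit = _ols(X, y, names)
        if fit.p_values[1] < screen_p:
            kept.append(c)

    if not kept:
        fit = _ols(np.ones((n, 1)), y, ["(intercept)"])
        return RegressionModel(response, [], float(fit.coefs[0]), fit.adj_r2, fit.r2, n)

    current = list(kept)
    X, names = _design(data, current)
    fit = _ols(X, y, names)
    while len(current) > 0:
        best_fit = None
        best_drop = None
        for c in current:
            trial = [t for t in current if t != c]
            Xt, nt = _design(data, trial)
            ft = _ols(Xt, y, nt)
            if best_fit is None or ft.adj_r2 > best_fit.adj_r2:
                best_fit, best_drop = ft, c
        if best_fit is not None and best_fit.adj_r2 >= fit.adj_r2:
            current.remove(best_drop)
            fit = best_fit
        else:
            break

    terms = [
        {
            "name": nm,
            "coef": float(fit.coefs[j]),
            "se": float(fit.se[j]),
            "p_value": float(fit.p_values[j]),
        }
        for j, nm in enumerate(fit.names)
        if nm != "(intercept)"
    ]
    return RegressionModel(
        response=response,
        terms=terms,
        intercept=float(fit.coefs[0]),
        adj_r2=fit.adj_r2,
        r2=fit.r2,
        n=n,
    )


# ---------------------------------------------------------------------------
# ROC analysis
# ---------------------------------------------------------------------------

@dataclass
class ROCCurve:
    """Operating points of the strictly-greater decision rule, plus AUC.

    ``thresholds`` ascend; at threshold t a score s is called positive iff
    s > t.  The first point (t = −∞) is (sens 1, spec 0); the last (t = max
    score) is (sens 0, spec 1).  ``auc`` is the trapezoidal area, which
    equals the Mann–Whitney pair-counting statistic.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    cutoff: float
    sensitivity_at_cutoff: float
    specificity_at_cutoff: float
    n_pos: int
    n_neg: int

    @property
    def n(self) -> int:
        return self.n_pos + self.n_neg


def roc_curve(scores, labels) -> ROCCurve:
    """ROC curve of a continuous score against boolean labels.

    Positive-class orientation is "higher score = positive".  Thresholds are
    −∞ plus the distinct score values; AUC is computed from integer
    true/false-positive counts so the trapezoidal area is exact.
    """
    s = np.asarray(scores, float)
    lab = np.asarray(labels, bool)
    if s.size != lab.size or s.size == 0:
        raise AnalysisError("scores and labels must be equal-length and non-empty")
    if np.any(~np.isfinite(s)):
        raise AnalysisError("missing or non-finite score")
    n_pos = int(lab.sum())
    n_neg = int((~lab).sum())
    if n_pos == 0 or n_neg == 0:
        raise AnalysisError("both classes must be present for ROC analysis")

    uniq = np.unique(s)  # ascending
    thresholds = np.concatenate(([-np.inf], uniq))
    # counts of positives/negatives with score > t, via suffix sums
    order = np.argsort(s, kind="mergesort")
    s_sorted = s[order]
    pos_sorted = lab[order].astype(np.int64)
    # for each threshold, index of first score > t
    first_gt = np.searchsorted(s_sorted, thresholds, side="right")
    pos_cum = np.concatenate(([0], np.cumsum(pos_sorted)))
    tp = n_pos - pos_cum[first_gt]           # positives called positive
    fp = (len(s) - first_gt) - tp            # negatives called positive
    sens = tp / n_pos
    spec = 1.0 - fp / n_neg

    # exact trapezoid over (FP, TP) counts: area*2*n_pos*n_neg is an integer
    twice_area = 0
    for i in range(len(thresholds) - 1):
        twice_area += int(fp[i] - fp[i + 1]) * int(tp[i] + tp[i + 1])
    auc = twice_area / (2 * n_pos * n_neg)

    curve = ROCCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=float(auc),
        cutoff=math.nan,
        sensitivity_at_cutoff=math.nan,
        specificity_at_cutoff=math.nan,
        n_pos=n_pos,
        n_neg=n_neg,
    )
    cutoff, se, sp = optimal_cutoff(curve)
    curve.cutoff = cutoff
    curve.sensitivity_at_cutoff = se
    curve.specificity_at_cutoff = sp
    return curve


def optimal_cutoff(roc: ROCCurve) -> tuple[float, float, float]:
    """Operating point maximising Youden's J = sensitivity + specificity − 1.

    Ties are broken toward higher specificity, then toward the higher
    threshold.  Returns ``(threshold, sensitivity, specificity)``.
    """
    j = roc.sensitivity + roc.specificity - 1.0
    best = 0
    for i in range(1, len(j)):
        if (j[i], roc.specificity[i], roc.thresholds[i]) >= (
            j[best],
            roc.specificity[best],
            roc.thresholds[best],
        ):
            best = i
    return (
        float(roc.thresholds[best]),
        float(roc.sensitivity[best]),
        float(roc.specificity[best]),
    )


_AUC_BANDS = [
    (0.9, "excellent"),
    (0.8, "very good"),
    (0.7, "good"),
    (0.6, "sufficient"),
    (0.5, "poor"),
]


def interpret_auc(auc: float) -> str:
    """Map an AUC to its conventional diagnostic-quality band.

    Bands: 0.9–1 excellent, 0.8–0.89 very good, 0.70–0.79 good, 0.6–0.7
    sufficient, 0.5–0.6 poor, <0.5 not useful; boundary values go to the
    higher band.
    """
    if not 0.0 <= auc <= 1.0:
        raise AnalysisError(f"AUC must lie in [0, 1], got {auc}")
    for lo, label in _AUC_BANDS:
        if auc >= lo:
            return label
    return "not useful"
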