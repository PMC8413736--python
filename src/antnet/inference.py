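"""Group-level statistics for attentional network scores.

Implements, from first principles, the inference layer used to compare two
groups on repeated network measurements: descriptives (moment skewness and
excess kurtosis), variance ratios, Welch's t with Cohen's d, Holm's
step-down p-value adjustment, Pearson chi-square on 2x2 tables with phi, a
2 (between) x k (within) mixed-design repeated-measures ANOVA with
Mauchly's sphericity test, the Greenhouse–Geisser correction and
generalized eta squared, pooled-error post hoc contrasts, and Cook's
distance influence screening with an F-median cutoff. Only distribution
functions (t, F, chi-square CDFs/quantiles) come from scipy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

# --------------------------------------------------------------------------
# descriptives


@dataclass(frozen=True)
class Descriptives:
    mean: float
    sd: float
    skewness: float
    kurtosis: float  # excess
    n: int


def describe(x) -> Descriptives:
    """Mean, SD (n-1), moment skewness g1 and excess kurtosis g2."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    mean = x.mean()
    sd = x.std(ddof=1)
    dev = x - mean
    m2 = np.mean(dev**2)
    if m2 == 0:
        return Descriptives(float(mean), 0.0, np.nan, np.nan, n)
    g1 = np.mean(dev**3) / m2**1.5 if n >= 3 else np.nan
    g2 = np.mean(dev**4) / m2**2 - 3.0 if n >= 4 else np.nan
    return Descriptives(float(mean), float(sd), float(g1), float(g2), n)


def variance_ratio(x, y) -> float:
    """max(var)/min(var); >= 1, symmetric in its arguments."""
    v1 = np.var(np.asarray(x, dtype=float), ddof=1)
    v2 = np.var(np.asarray(y, dtype=float), ddof=1)
    lo, hi = min(v1, v2), max(v1, v2)
    if lo == 0:
        return float("inf")
    return float(hi / lo)


# --------------------------------------------------------------------------
# two-sample tests


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    tails: str
    d: float  # Cohen's d, pooled-SD form


def cohen_d_from_summary(m1, s1, n1, m2, s2, n2) -> float:
    """Cohen's d with the pooled SD: (m1-m2)/s_p."""
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
    return float((m1 - m2) / np.sqrt(sp2))


def welch_t_from_summary(m1, s1, n1, m2, s2, n2, tails: str = "two") -> WelchResult:
    """Welch's t from group summaries (Welch–Satterthwaite df)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per group")
    v1, v2 = s1**2 / n1, s2**2 / n2
    se2 = v1 + v2
    if se2 == 0:
        raise ValueError("degenerate: zero variance in both samples")
    t = (m1 - m2) / np.sqrt(se2)
    df = se2**2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    if tails == "two":
        p = 2.0 * stats.t.sf(abs(t), df)
    elif tails == "one":
        p = stats.t.sf(abs(t), df)
    else:
        raise ValueError("tails must be 'one' or 'two'")
    d = cohen_d_from_summary(m1, s1, n1, m2, s2, n2)
    return WelchResult(float(t), float(df), float(p), tails, d)


def welch_t(x, y, tails: str = "two") -> WelchResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return welch_t_from_summary(
        x.mean(), x.std(ddof=1), x.size, y.mean(), y.std(ddof=1), y.size, tails
    )


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in the input order."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum(np.maximum.accumulate((m - np.arange(m)) * p[order]), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


@dataclass(frozen=True)
class ChiSquareResult:
    chi2: float
    df: int
    p: float
    phi: float


def chi_square_2x2(table) -> ChiSquareResult:
    """Pearson chi-square on a 2x2 count table, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.rint(t)):
        raise ValueError("table must be 2x2 nonnegative integer counts")
    n = t.sum()
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("chi-square undefined: zero margin")
    expected = np.outer(rows, cols) / n
    chi2 = float(((t - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, 1))
    phi = float(np.sqrt(chi2 / n))
    return ChiSquareResult(chi2, 1, p, phi)


# --------------------------------------------------------------------------
# mixed-design repeated-measures ANOVA


@dataclass(frozen=True)
class MauchlyResult:
    W: float
    chi2: float
    df: int
    p: float


@dataclass
class MixedAnovaResult:
    """Effect table plus the pieces post hoc contrasts need."""

    table: pd.DataFrame  # effect, SS, df1, df2, MS, F, p, p_gg, ges
    mauchly: MauchlyResult | None
    gg_epsilon: float
    k: int  # within levels
    group_sizes: dict[str, int]
    group_means: pd.Series  # subject-average composite mean per group
    cell_means: pd.DataFrame  # group x within-level means
    ms_subject: float
    df_subject: float
    ms_error: float
    df_error: float
    within_levels: list = field(default_factory=list)
    groups: list = field(default_factory=list)

    def effect(self, name: str) -> pd.Series:
        return self.table.set_index("effect").loc[name]


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal basis of the subspace orthogonal to the mean."""
    helmert = np.zeros((k - 1, k))
    for i in range(k - 1):
        helmert[i, : i + 1] = 1.0
        helmert[i, i + 1] = -(i + 1.0)
    return helmert / np.linalg.norm(helmert, axis=1, keepdims=True)


def mixed_anova(
    data: pd.DataFrame,
    dv: str = "composite",
    within: str = "network",
    between: str = "group",
    subject: str = "participant_id",
) -> MixedAnovaResult:
    """2-group x k-level mixed ANOVA with sphericity machinery.

    Requires complete, balanced within-subject data (every subject measured
    at every within level). F(between) is tested against subjects-within-
    groups; within effects against the within-subject error. Mauchly's W is
    computed on the pooled within-group covariance of the orthonormalised
    within-subject contrasts; the Greenhouse–Geisser epsilon rescales the
    within dfs; generalized eta squared uses all subject-related variance in
    its denominator.
    """
    wide = data.pivot_table(index=[subject, between], columns=within, values=dv)
    if wide.isna().any().any():
        raise ValueError("unbalanced design: every subject needs all within levels")
    within_levels = list(wide.columns)
    k = len(within_levels)
    groups = sorted(wide.index.get_level_values(between).unique())
    g = len(groups)
    if g < 2:
        raise ValueError("need at least 2 between-subject groups")
    Y = wide.to_numpy()
    glab = wide.index.get_level_values(between).to_numpy()
    N = Y.shape[0]
    ns = {lab: int((glab == lab).sum()) for lab in groups}
    if min(ns.values()) < 2:
        raise ValueError("need at least 2 subjects per group")

    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    group_means = np.array([subj_means[glab == lab].mean() for lab in groups])
    level_means = Y.mean(axis=0)
    cell = np.array([Y[glab == lab].mean(axis=0) for lab in groups])

    ss_total = ((Y - grand) ** 2).sum()
    ss_between_subj = k * ((subj_means - grand) ** 2).sum()
    ss_group = k * sum(ns[lab] * (gm - grand) ** 2 for lab, gm in zip(groups, group_means))
    ss_subj = ss_between_subj - ss_group
    ss_within_lvl = N * ((level_means - grand) ** 2).sum()
    ss_inter = sum(
        ns[lab] * ((cell[i] - group_means[i] - level_means + grand) ** 2).sum()
        for i, lab in enumerate(groups)
    )
    ss_error = ss_total - ss_between_subj - ss_within_lvl - ss_inter

    df_group, df_subj = g - 1, N - g
    df_within, df_inter = k - 1, (g - 1) * (k - 1)
    df_error = (N - g) * (k - 1)

    ms_group = ss_group / df_group
    ms_subj = ss_subj / df_subj
    ms_within = ss_within_lvl / df_within
    ms_inter = ss_inter / df_inter
    ms_error = ss_error / df_error if df_error > 0 else np.nan

    def f_p(ms_num, df_num, ms_den, df_den):
        if ms_den == 0 or not np.isfinite(ms_den):
            return np.nan, np.nan
        F = ms_num / ms_den
        return F, stats.f.sf(F, df_num, df_den)

    F_group, p_group = f_p(ms_group, df_group, ms_subj, df_subj)
    F_within, p_within = f_p(ms_within, df_within, ms_error, df_error)
    F_inter, p_inter = f_p(ms_inter, df_inter, ms_error, df_error)

    # sphericity on the pooled within-group covariance of the contrasts
    mauchly = None
    eps = 1.0
    if k > 2:
        C = _orthonormal_contrasts(k)
        S = np.zeros((k, k))
        for lab in groups:
            sub = Y[glab == lab]
            S += (sub.shape[0] - 1) * np.cov(sub, rowvar=False)
        S /= N - g
        Sc = C @ S @ C.T
        p_dim = k - 1
        tr, tr2 = np.trace(Sc), np.trace(Sc @ Sc)
        eps = float(tr**2 / (p_dim * tr2)) if tr2 > 0 else 1.0
        eigs = np.linalg.eigvalsh(Sc)
        W = float(np.prod(eigs) / (tr / p_dim) ** p_dim) if tr > 0 else np.nan
        df_m = p_dim * (p_dim + 1) // 2 - 1
        if np.isfinite(W) and W > 0:
            f_corr = (2 * p_dim**2 + p_dim + 2) / (6.0 * p_dim)
            chi2_m = -((N - g) - f_corr) * np.log(W)
            p_m = float(stats.chi2.sf(chi2_m, df_m))
            mauchly = MauchlyResult(W, float(chi2_m), df_m, p_m)
        else:
            mauchly = MauchlyResult(W, np.nan, df_m, np.nan)
    eps = float(np.clip(eps, 1.0 / (k - 1), 1.0)) if k > 1 else 1.0

    p_gg_within = (
        float(stats.f.sf(F_within, df_within * eps, df_error * eps))
        if np.isfinite(F_within)
        else np.nan
    )
    p_gg_inter = (
        float(stats.f.sf(F_inter, df_inter * eps, df_error * eps))
        if np.isfinite(F_inter)
        else np.nan
    )

    def ges(ss_effect):
        denom = ss_effect + ss_subj + ss_error
        return ss_effect / denom if denom > 0 else np.nan

    table = pd.DataFrame(
        {
            "effect": [between, within, f"{between}:{within}"],
            "SS": [ss_group, ss_within_lvl, ss_inter],
            "df1": [df_group, df_within, df_inter],
            "df2": [df_subj, df_error, df_error],
            "MS": [ms_group, ms_within, ms_inter],
            "F": [F_group, F_within, F_inter],
            "p": [p_group, p_within, p_inter],
            "p_gg": [p_group, p_gg_within, p_gg_inter],
            "ges": [ges(ss_group), ges(ss_within_lvl), ges(ss_inter)],
        }
    )
    return MixedAnovaResult(
        table=table,
        mauchly=mauchly,
        gg_epsilon=eps,
        k=k,
        group_sizes=ns,
        group_means=pd.Series(group_means, index=groups),
        cell_means=pd.DataFrame(cell, index=groups, columns=within_levels),
        ms_subject=float(ms_subj),
        df_subject=float(df_subj),
        ms_error=float(ms_error),
        df_error=float(df_error),
        within_levels=within_levels,
        groups=list(groups),
    )


def recommended_p(result: MixedAnovaResult, effect: str, alpha: float = 0.05) -> float:
    """GG-corrected p when Mauchly rejects sphericity, uncorrected otherwise."""
    row = result.effect(effect)
    if result.mauchly is not None and result.mauchly.p < alpha:
        return float(row["p_gg"])
    return float(row["p"])


@dataclass(frozen=True)
class ContrastResult:
    label: str
    estimate: float
    se: float
    t: float
    df: float
    p: float
    p_holm: float | None = None


def group_contrast(result: MixedAnovaResult, tails: str = "two") -> ContrastResult:
    """Between-group contrast on the subject-average score.

    SE comes from the subjects-within-groups mean square; with two groups
    this is exactly the Tukey HSD comparison, df = N - g.
    """
    if len(result.groups) != 2:
        raise ValueError("group_contrast is defined for 2 groups")
    g1, g2 = result.groups
    diff = result.group_means[g1] - result.group_means[g2]
    n1, n2 = result.group_sizes[g1], result.group_sizes[g2]
    se = np.sqrt(result.ms_subject / result.k * (1.0 / n1 + 1.0 / n2))
    t = diff / se
    df = result.df_subject
    p = (2.0 if tails == "two" else 1.0) * stats.t.sf(abs(t), df)
    return ContrastResult(f"{g1}-{g2}", float(diff), float(se), float(t), float(df), float(p))


def cellwise_posthoc(result: MixedAnovaResult, tails: str = "two") -> list[ContrastResult]:
    """Group contrasts within each within-subject level, Holm-adjusted.

    The cell-mean variance mixes both error strata,
    (MS_subj + (k-1) MS_error)/k per observation; the df of the combination
    follows Satterthwaite, which lands strictly between the between-subject
    and the total error df.
    """
    if len(result.groups) != 2:
        raise ValueError("cellwise_posthoc is defined for 2 groups")
    g1, g2 = result.groups
    n1, n2 = result.group_sizes[g1], result.group_sizes[g2]
    k = result.k
    w = 1.0 / n1 + 1.0 / n2
    a = w / k
    b = w * (k - 1) / k
    var = a * result.ms_subject + b * result.ms_error
    df_sat = var**2 / (
        (a * result.ms_subject) ** 2 / result.df_subject
        + (b * result.ms_error) ** 2 / result.df_error
    )
    se = np.sqrt(var)
    contrasts = []
    for lvl in result.within_levels:
        diff = result.cell_means.loc[g1, lvl] - result.cell_means.loc[g2, lvl]
        t = diff / se
        p = (2.0 if tails == "two" else 1.0) * stats.t.sf(abs(t), df_sat)
        contrasts.append(
            ContrastResult(f"{lvl}: {g1}-{g2}", float(diff), float(se), float(t), float(df_sat), float(p))
        )
    adj = holm_adjust([c.p for c in contrasts])
    return [
        ContrastResult(c.label, c.estimate, c.se, c.t, c.df, c.p, float(a_))
        for c, a_ in zip(contrasts, adj)
    ]


# --------------------------------------------------------------------------
# influence diagnostics


@dataclass(frozen=True)
class CooksDiagnostics:
    d: np.ndarray
    cutoff: float
    flagged: np.ndarray  # indices with D > cutoff
    k: int
    n: int


def cooks_screen(response, design) -> CooksDiagnostics:
    """Cook's distance for each observation of a least-squares fit.

    ``design`` holds the predictor columns (an intercept is prepended).
    The cutoff is the median of F(k+1, n-k-1), per the convention of
    screening against the 50th percentile of the parameter-confidence F.
    """
    y = np.asarray(response, dtype=float)
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    X1 = np.column_stack([np.ones(n), X])
    p = k + 1
    if n <= p:
        raise ValueError("need n > k + 1 observations")
    if np.linalg.matrix_rank(X1) < p:
        raise ValueError("rank-deficient design")
    H = X1 @ np.linalg.solve(X1.T @ X1, X1.T)
    h = np.diag(H)
    resid = y - H @ y
    s2 = resid @ resid / (n - p)
    d = resid**2 / (p * s2) * h / (1.0 - h) ** 2
    cutoff = float(stats.f.ppf(0.5, p, n - p))
    return CooksDiagnostics(d=d, cutoff=cutoff, flagged=np.flatnonzero(d > cutoff), k=k, n=n)
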