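"""Group comparisons, effect sizes, and connectivity-gait correlations.

The battery mirrors common movement-disorders reporting practice: a
Shapiro-Wilk normality screen per group and a Levene variance screen
decide between the two-sample t-test and the Mann-Whitney U test; the
pooled-SD Cohen's d accompanies every contrast; Pearson correlation
(with R^2 and a t-distribution p) relates connectivity to gait within a
group.  Small samples get exact permutation p-values for the rank tests.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from math import comb, sqrt
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .montage import Montage, build_default_montage, fc_column_order

logger = logging.getLogger(__name__)

#: Gait variables correlated with connectivity (per foot).
GAIT_CORRELATION_VARIABLES: tuple[str, ...] = (
    "gait_speed_L", "gait_speed_R", "stride_length_L", "stride_length_R",
)

#: Sample sizes at which rank tests switch to exact enumeration.
EXACT_N_MAX = 8


@dataclass
class GroupComparison:
    """One variable's two-group contrast."""

    variable: str
    mean_1: float
    sd_1: float
    n_1: int
    mean_2: float
    sd_2: float
    n_2: int
    test: str                     # "t_test" | "mann_whitney_u"
    statistic: float
    p_value: float
    cohens_d: float
    decision_trail: dict = field(default_factory=dict)


@dataclass
class CorrelationResult:
    """Pearson correlation between a connectivity measure and a gait variable."""

    x_name: str
    y_name: str
    r: float
    r_squared: float
    p_value: float
    n: int


# --------------------------------------------------------------------------
# Elementary statistics
# --------------------------------------------------------------------------

def cohens_d_pooled(m1: float, s1: float, n1: int,
                    m2: float, s2: float, n2: int) -> float:
    """Standardised mean difference with the pooled two-sample SD:

    d = (m1 - m2) / sqrt(((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2))
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be >= 0")
    if s1 == 0 and s2 == 0:
        raise ValueError("Cohen's d undefined when both SDs are zero")
    pooled = sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
    return (m1 - m2) / pooled


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of the first sample, with midrank tie handling."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    return float(ranks[: len(x)].sum() - len(x) * (len(x) + 1) / 2.0)


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact permutation enumeration (midranks, so ties are handled) when
    both samples have at most 8 observations; otherwise the normal
    approximation with tie and continuity correction.  Returns
    (U of the first sample, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    u_obs = _u_statistic(x, y)
    n1, n2 = x.size, y.size
    if max(n1, n2) <= EXACT_N_MAX:
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        offset = n1 * (n1 + 1) / 2.0
        mu = n1 * n2 / 2.0
        dev_obs = abs(u_obs - mu)
        hits = total = 0
        for combo in itertools.combinations(range(n1 + n2), n1):
            u = ranks[list(combo)].sum() - offset
            hits += abs(u - mu) >= dev_obs - 1e-12
            total += 1
        return u_obs, hits / total
    res = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method="asymptotic", use_continuity=True)
    return u_obs, float(res.pvalue)


def paired_t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired t-test; errors on unequal lengths."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired test requires equal-length samples")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0) and np.allclose(d.mean(), 0.0):
        return 0.0, 1.0
    res = sps.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)


def chi_squared_2x2(table: Sequence[Sequence[float]],
                    yates: bool = False) -> tuple[float, float]:
    """Chi-squared test of independence on a 2x2 count table (no Yates
    continuity correction by default).  Warns when an expected cell < 1."""
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    chi2, p, _, expected = sps.chi2_contingency(tab, correction=yates)
    if (expected < 1).any():
        logger.warning("chi-squared expected cell count below 1")
    return float(chi2), float(p)


def _kw_h(groups: list[np.ndarray]) -> float:
    """Kruskal-Wallis H with tie correction."""
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start:start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - ((counts**3 - counts).sum()) / (n**3 - n) if n > 1 else 1.0
    return h / tie if tie > 0 else 0.0


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H test across >= 2 groups.

    Exact permutation p when every group has at most 8 observations and
    the total is at most 10 (full enumeration of label assignments);
    otherwise the chi-squared approximation.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size == 0 for g in gs):
        raise ValueError("need >= 2 nonempty groups")
    h_obs = _kw_h(gs)
    sizes = [g.size for g in gs]
    n = sum(sizes)
    if max(sizes) <= EXACT_N_MAX and n <= 10:
        pooled = np.concatenate(gs)
        hits = total = 0
        indices = set(range(n))
        # enumerate assignments of pooled observations to group slots
        def rec(remaining: frozenset, gi: int, chosen: list) -> None:
            nonlocal hits, total
            if gi == len(sizes) - 1:
                parts = chosen + [sorted(remaining)]
                h = _kw_h([pooled[list(p)] for p in parts])
                hits += h >= h_obs - 1e-12
                total += 1
                return
            for combo in itertools.combinations(sorted(remaining), sizes[gi]):
                rec(remaining - set(combo), gi + 1, chosen + [list(combo)])

        rec(frozenset(indices), 0, [])
        return h_obs, hits / total
    p = float(sps.chi2.sf(h_obs, len(gs) - 1))
    return h_obs, p


def dunn_bonferroni(groups: Sequence[Sequence[float]]) -> pd.DataFrame:
    """Dunn's pairwise post-hoc z-tests on midranks with Bonferroni
    multiplication (capped at 1)."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(gs)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    start = 0
    for g in gs:
        mean_ranks.append(ranks[start:start + g.size].mean())
        start += g.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (12.0 * (n - 1)) if n > 1 else 0.0
    m = comb(len(gs), 2)
    rows = []
    for i in range(len(gs)):
        for j in range(i + 1, len(gs)):
            se = sqrt((n * (n + 1) / 12.0 - tie_term)
                      * (1.0 / gs[i].size + 1.0 / gs[j].size))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p = min(2 * sps.norm.sf(abs(z)) * m, 1.0)
            rows.append({"group_a": i, "group_b": j, "z": z, "p_adjusted": p})
    return pd.DataFrame(rows)


def pearson_corr(x: Sequence[float], y: Sequence[float],
                 x_name: str = "x", y_name: str = "y") -> CorrelationResult:
    """Pearson r with R^2 and the two-sided t-distribution p (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in correlation input")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in correlation input")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    return CorrelationResult(x_name=x_name, y_name=y_name, r=r,
                             r_squared=r * r, p_value=float(res.pvalue),
                             n=int(x.size))


# --------------------------------------------------------------------------
# Cohort-level analyses
# --------------------------------------------------------------------------

def compare_groups(
    table: pd.DataFrame,
    variables: Sequence[str],
    group_col: str = "group",
    groups: tuple[str, str] = ("PD", "HC"),
    alpha_screen: float = 0.05,
) -> list[GroupComparison]:
    """Per variable: Shapiro-Wilk per group and Levene across groups choose
    the test (both normal and homogeneous -> two-sample t, else
    Mann-Whitney U); pooled Cohen's d always reported; the screen outcome
    is stored in the decision trail."""
    g1 = table[table[group_col] == groups[0]]
    g2 = table[table[group_col] == groups[1]]
    if g1.empty or g2.empty:
        raise ValueError(f"both groups {groups} must be present")
    out: list[GroupComparison] = []
    for var in variables:
        if var not in table.columns:
            logger.warning("variable %r missing; skipped", var)
            continue
        x = g1[var].dropna().to_numpy(dtype=float)
        y = g2[var].dropna().to_numpy(dtype=float)
        if x.size < 3 or y.size < 3:
            logger.warning("variable %r has too few observations; skipped", var)
            continue
        sw1 = sps.shapiro(x).pvalue
        sw2 = sps.shapiro(y).pvalue
        lev = sps.levene(x, y).pvalue
        normal = sw1 > alpha_screen and sw2 > alpha_screen
        homogeneous = lev > alpha_screen
        if normal and homogeneous:
            res = sps.ttest_ind(x, y)
            test, stat, p = "t_test", float(res.statistic), float(res.pvalue)
        else:
            stat, p = mann_whitney_u(x, y)
            test = "mann_whitney_u"
        d = cohens_d_pooled(x.mean(), x.std(ddof=1), x.size,
                            y.mean(), y.std(ddof=1), y.size)
        out.append(GroupComparison(
            variable=var,
            mean_1=float(x.mean()), sd_1=float(x.std(ddof=1)), n_1=int(x.size),
            mean_2=float(y.mean()), sd_2=float(y.std(ddof=1)), n_2=int(y.size),
            test=test, statistic=stat, p_value=p, cohens_d=d,
            decision_trail={
                "shapiro_p": (float(sw1), float(sw2)),
                "levene_p": float(lev),
                "normal": bool(normal),
                "homogeneous": bool(homogeneous),
            },
        ))
    return out


def fc_group_analysis(
    cohort_table: pd.DataFrame, montage: Montage | None = None
) -> list[GroupComparison]:
    """The 6 within- and 15 between-ROI contrasts, in fixed order."""
    m = montage or build_default_montage()
    for g in ("PD", "HC"):
        if (cohort_table["group"] == g).sum() < 3:
            raise ValueError(f"group {g} has fewer than 3 subjects")
    return compare_groups(cohort_table, fc_column_order(m))


def fc_gait_correlation(
    cohort_table: pd.DataFrame,
    group: str,
    fc_measures: Sequence[str] | None = None,
    gait_variables: Sequence[str] = GAIT_CORRELATION_VARIABLES,
    montage: Montage | None = None,
) -> pd.DataFrame:
    """Within-group Pearson correlations of every connectivity measure with
    gait speed and stride length (left and right).  No pooling across
    groups."""
    m = montage or build_default_montage()
    sub = cohort_table[cohort_table["group"] == group]
    if len(sub) < 3:
        raise ValueError(f"group {group} has fewer than 3 subjects")
    measures = list(fc_measures) if fc_measures is not None else fc_column_order(m)
    rows = []
    for fc in measures:
        for gv in gait_variables:
            res = pearson_corr(sub[fc], sub[gv], x_name=fc, y_name=gv)
            rows.append({
                "group": group, "fc_measure": fc, "gait_variable": gv,
                "r": res.r, "r_squared": res.r_squared,
                "p_value": res.p_value, "n": res.n,
            })
    return pd.DataFrame(rows)


def comparisons_to_frame(comparisons: Iterable[GroupComparison]) -> pd.DataFrame:
    """Tabular report: mean +- SD per group, test, p, Cohen's d."""
    return pd.DataFrame([
        {
            "variable": c.variable,
            "pd_mean": c.mean_1, "pd_sd": c.sd_1, "n_pd": c.n_1,
            "hc_mean": c.mean_2, "hc_sd": c.sd_2, "n_hc": c.n_2,
            "test": c.test, "statistic": c.statistic,
            "p_value": c.p_value, "cohens_d": c.cohens_d,
        }
        for c in comparisons
    ])
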