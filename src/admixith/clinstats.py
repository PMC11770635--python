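"""Clinicomolecular and survival association battery.

Joins per-slide iLumA% with admixture and clinical tables, assigns iLumA%
quartiles (Q1 = most admixed, Q4 = purest), and runs the standard
association battery: Pearson/Spearman correlation of iLumA% with pLumA,
Q1-vs-Q4 contrasts (chi-square for binary features, Student t for
continuous ones, both two-sided and without continuity correction),
ordinal-quartile linear trend tests, the four-gene ER pathway score, the
MATH mutant-allele heterogeneity score, Kaplan-Meier/log-rank comparisons
of pure vs admixed cases, and Cox proportional-hazards ratios over the
entire follow-up and with a 3-year time split (early stratum censored at 36
months; late stratum a landmark analysis restricted to cases still at risk
at 36 months with the clock restarted there).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test
from scipy import stats

__all__ = [
    "SurvivalComparison", "correlate", "assign_quartiles", "q1_vs_q4_test",
    "trend_test", "er_gene_score", "math_score", "km_logrank", "cox_hr",
    "build_cohort_table", "quartile_table",
]

ER_GENES = ("ESR1", "PGR", "BCL2", "SCUBE2")
LANDMARK_MONTHS = 36.0


@dataclass
class SurvivalComparison:
    stratum: str             # "entire" | "0-3y" | ">3y"
    hazard_ratio: float
    ci_low: float
    ci_high: float
    logrank_p: float
    n: int
    n_events: int


# ---------------------------------------------------------------------------
# correlations, quartiles, contrasts
# ---------------------------------------------------------------------------


def correlate(x, y, method: str = "pearson") -> tuple[float, float]:
    """Pearson or Spearman correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("x and y must be equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def assign_quartiles(values) -> np.ndarray:
    """Quartile labels Q1 (lowest) .. Q4 (highest) at sample percentiles.

    Thresholds are the 25/50/75 sample percentiles; values tied with a
    threshold fall in the lower quartile.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 cases to form quartiles")
    if np.ptp(v) == 0:
        raise ValueError("all values equal; quartiles degenerate")
    q25, q50, q75 = np.percentile(v, [25, 50, 75])
    labels = np.where(v <= q25, "Q1",
             np.where(v <= q50, "Q2",
             np.where(v <= q75, "Q3", "Q4")))
    return labels


def q1_vs_q4_test(feature, quartiles, feature_type: str) -> tuple[float, float]:
    """Compare the purest (Q4) with the most admixed (Q1) quartile.

    Binary features: chi-square on the 2x2 table without continuity
    correction; continuous features: two-sample Student t.  Two-sided.
    """
    f = np.asarray(feature, dtype=float)
    q = np.asarray(quartiles)
    g1, g4 = f[q == "Q1"], f[q == "Q4"]
    if len(g1) == 0 or len(g4) == 0:
        raise ValueError("both Q1 and Q4 must be nonempty")
    if feature_type == "binary":
        table = np.array([[np.sum(g1 == 1), np.sum(g1 == 0)],
                          [np.sum(g4 == 1), np.sum(g4 == 0)]])
        stat, p, _, _ = stats.chi2_contingency(table, correction=False)
        return float(stat), float(p)
    if feature_type == "continuous":
        if np.ptp(g1) == 0 and np.ptp(g4) == 0:
            raise ValueError("zero variance in both groups; t test undefined")
        stat, p = stats.ttest_ind(g1, g4, equal_var=True)
        return float(stat), float(p)
    raise ValueError(f"unknown feature_type {feature_type!r}")


def trend_test(feature, quartiles) -> tuple[float, float]:
    """OLS linear-trend test of the feature on quartiles coded 1..4."""
    f = np.asarray(feature, dtype=float)
    q = np.asarray(quartiles)
    codes = np.array([int(lab[1]) for lab in q], dtype=float)
    if len(np.unique(codes)) < 2:
        raise ValueError("trend test needs >= 2 distinct quartiles")
    model = sm.OLS(f, sm.add_constant(codes)).fit()
    return float(model.params[1]), float(model.pvalues[1])


# ---------------------------------------------------------------------------
# composite scores
# ---------------------------------------------------------------------------


def er_gene_score(expression: pd.DataFrame) -> pd.Series:
    """Per-case unweighted mean of the ER-group genes ESR1, PGR, BCL2, SCUBE2.

    ``expression`` is genes x cases on a normalized log scale; all four gene
    rows must be present.
    """
    missing = [g for g in ER_GENES if g not in expression.index]
    if missing:
        raise KeyError(f"missing ER-group gene row(s): {missing}")
    return expression.loc[list(ER_GENES)].mean(axis=0)


def math_score(vaf_list) -> float:
    """Mutant-allele tumor heterogeneity: MAD of the mutant-allele
    fractions divided by their median (plain ratio, no scale constant)."""
    v = np.asarray(vaf_list, dtype=float)
    if v.size < 3:
        raise ValueError("MATH score needs >= 3 mutant-allele fractions")
    med = float(np.median(v))
    if med == 0:
        raise ValueError("median allele fraction is 0; MATH undefined")
    mad = float(np.median(np.abs(v - med)))
    return mad / med


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


def km_logrank(times, events, group_labels):
    """Kaplan-Meier curves per group and the two-sided log-rank test.

    Returns ``(curves, statistic, p)`` where ``curves`` maps each group
    label to a DataFrame of the product-limit estimate at each distinct
    event time.  With a single group the test fields are NaN.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(group_labels)
    if np.any(t <= 0):
        raise ValueError("survival times must be > 0")
    if e.sum() == 0:
        raise ValueError("no events in any group; log-rank undefined")
    curves = {}
    for lab in np.unique(g):
        kmf = KaplanMeierFitter()
        kmf.fit(t[g == lab], e[g == lab])
        event_times = np.unique(t[(g == lab) & (e == 1)])
        surv = kmf.survival_function_at_times(event_times)
        curves[lab] = pd.DataFrame({"time": event_times,
                                    "survival": surv.to_numpy()})
    labs = np.unique(g)
    if len(labs) == 1:
        return curves, float("nan"), float("nan")
    if len(labs) == 2:
        res = logrank_test(t[g == labs[0]], t[g == labs[1]],
                           e[g == labs[0]], e[g == labs[1]])
    else:
        res = multivariate_logrank_test(t, g, e)
    return curves, float(res.test_statistic), float(res.p_value)


def _apply_stratum(t, e, x, stratum: str):
    if stratum == "entire":
        return t, e, x
    if stratum == "0-3y":
        e = np.where(t > LANDMARK_MONTHS, 0, e)
        t = np.minimum(t, LANDMARK_MONTHS)
        return t, e, x
    if stratum == ">3y":
        keep = t > LANDMARK_MONTHS
        return t[keep] - LANDMARK_MONTHS, e[keep], x[keep]
    raise ValueError(f"unknown stratum {stratum!r}")


def cox_hr(times, events, group, covariates: pd.DataFrame | None = None,
           stratum: str = "entire") -> SurvivalComparison:
    """Cox proportional-hazards ratio for admixed (group=1) vs pure (group=0).

    ``stratum`` selects the follow-up window: the early stratum censors all
    follow-up at 36 months; the late stratum is a landmark analysis of the
    cases still at risk at 36 months with the time origin shifted there.
    Efron tie handling; Wald 95% CI.  The log-rank p reported alongside is
    computed on the same stratum-restricted data.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    x = np.asarray(group, dtype=float)
    idx = np.arange(len(t))
    t, e, keep_idx = _apply_stratum(t, e, idx, stratum)
    x = x[keep_idx]
    if e.sum() == 0:
        raise ValueError(f"no events in stratum {stratum!r}; model undefined")
    df = pd.DataFrame({"time": t, "event": e, "admixed": x})
    if covariates is not None:
        cov = covariates.iloc[keep_idx].reset_index(drop=True)
        df = pd.concat([df, cov], axis=1)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    hr = float(np.exp(cph.params_["admixed"]))
    ci = cph.confidence_intervals_.loc["admixed"]
    lo, hi = float(np.exp(ci.iloc[0])), float(np.exp(ci.iloc[1]))
    res = logrank_test(t[x == 0], t[x == 1], e[x == 0], e[x == 1])
    return SurvivalComparison(stratum=stratum, hazard_ratio=hr,
                              ci_low=lo, ci_high=hi,
                              logrank_p=float(res.p_value),
                              n=len(t), n_events=int(e.sum()))


# ---------------------------------------------------------------------------
# cohort assembly and reporting
# ---------------------------------------------------------------------------


def build_cohort_table(scores: pd.DataFrame, admixture: pd.DataFrame,
                       clinical: pd.DataFrame) -> pd.DataFrame:
    """Join slide scores, admixture proportions and clinical data on case_id
    and assign iLumA% quartiles (Q1 = most admixed)."""
    scores = scores.rename(columns={"slide_id": "case_id"})
    df = scores.merge(admixture, on="case_id", how="inner")
    df = df.merge(clinical, on="case_id", how="inner")
    df["quartile"] = assign_quartiles(df["iluma_pct"].to_numpy())
    return df


def quartile_table(cohort: pd.DataFrame, binary_features: list[str],
                   continuous_features: list[str]) -> pd.DataFrame:
    """Feature-by-quartile summary with Q1-vs-Q4 p and ordinal trend p.

    Binary features are summarized as percent positive per quartile;
    continuous features as means.
    """
    rows = []
    q = cohort["quartile"].to_numpy()
    for feat, kind in [(f, "binary") for f in binary_features] + [
            (f, "continuous") for f in continuous_features]:
        v = cohort[feat].to_numpy(dtype=float)
        summ = {}
        for lab in ("Q1", "Q2", "Q3", "Q4"):
            vals = v[q == lab]
            summ[lab] = 100.0 * vals.mean() if kind == "binary" else vals.mean()
        _, p_q1q4 = q1_vs_q4_test(v, q, kind)
        _, p_trend = trend_test(v, q)
        rows.append({"feature": feat, "type": kind, **summ,
                     "p_q1_vs_q4": p_q1q4, "p_trend": p_trend})
    return pd.DataFrame(rows)
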