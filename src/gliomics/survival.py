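"""Prognostic statistics on a cohort feature table.

The pipeline mirrors standard imaging-biomarker practice: Pearson
correlations between PET and MRI feature columns (robust when r > 0.75 and
p < 0.05), median dichotomization of survival endpoints with two-sample
t-tests, ROC cutoff selection by Youden's J, Kaplan-Meier curves with
log-rank comparison, and univariate / multivariate Cox proportional-hazards
models (Efron tie handling). Sphericity enters Cox models per 0.1 increase
so its hazard ratio reads "per tenth".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

log = logging.getLogger("gliomics")

ROBUST_R_CUT = 0.75
ALPHA = 0.05
SPHERICITY_SCALE = 0.1  # HR per tenth of sphericity


@dataclass
class SurvivalResult:
    variable: str
    hr: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    n_events: int
    scale_note: str = ""
    converged: bool = True


@dataclass
class RocResult:
    variable: str
    cutoff: float
    auc: float
    sensitivity: float
    specificity: float
    endpoint: str


def _endpoint_cols(endpoint: str) -> tuple[str, str]:
    if endpoint not in ("os", "pfs"):
        raise ValueError("endpoint must be 'os' or 'pfs'")
    return f"{endpoint}_months", f"{endpoint}_event"


def correlate_features(table: pd.DataFrame, pet_vars: list[str],
                       mri_vars: list[str]) -> pd.DataFrame:
    """Pearson r and two-sided p for every (PET, MRI) feature pair.

    Rows with either value missing are dropped pairwise; cells with fewer
    than 3 complete pairs or a constant column are reported as missing.
    Pairs with r > 0.75 and p < 0.05 are flagged robust.
    """
    rows = []
    for pv in pet_vars:
        for mv in mri_vars:
            sub = table[[pv, mv]].dropna()
            r = p = np.nan
            if len(sub) >= 3 and sub[pv].nunique() > 1 and sub[mv].nunique() > 1:
                r, p = stats.pearsonr(sub[pv], sub[mv])
            rows.append({"pet_var": pv, "mri_var": mv, "r": r, "p": p,
                         "n": len(sub),
                         "robust": bool(r > ROBUST_R_CUT and p < ALPHA) if np.isfinite(r) else False})
    return pd.DataFrame(rows)


def dichotomize_and_test(table: pd.DataFrame, endpoint: str,
                         features: list[str], welch: bool = True) -> pd.DataFrame:
    """Split patients at the endpoint's median time and t-test each feature.

    Groups are "<= median" vs "> median" (ties at the median fall in the
    lower group). Welch's unequal-variance t-test by default; normality per
    feature is checked with a Kolmogorov-Smirnov test and flagged, not
    enforced. Constant features report p as missing.
    """
    time_col, _ = _endpoint_cols(endpoint)
    med = table[time_col].median()
    low = table[table[time_col] <= med]
    high = table[table[time_col] > med]
    if len(low) < 2 or len(high) < 2:
        raise ValueError("median split leaves a group with < 2 patients")
    rows = []
    for f in features:
        a, b = low[f].dropna(), high[f].dropna()
        if a.nunique() <= 1 and b.nunique() <= 1 and a.iloc[0] == b.iloc[0]:
            p = np.nan
        else:
            p = stats.ttest_ind(a, b, equal_var=not welch).pvalue
        pooled = pd.concat([a, b])
        ks_p = np.nan
        if pooled.std(ddof=0) > 0:
            ks_p = stats.kstest((pooled - pooled.mean()) / pooled.std(ddof=0), "norm").pvalue
        rows.append({"feature": f, "endpoint_median": med,
                     "mean_low": a.mean(), "sd_low": a.std(), "n_low": len(a),
                     "mean_high": b.mean(), "sd_high": b.std(), "n_high": len(b),
                     "p": p, "ks_normality_p": ks_p})
    return pd.DataFrame(rows)


def roc_curve_points(values: np.ndarray, positive: np.ndarray):
    """Empirical ROC for the rule "positive if value >= threshold".

    Returns (thresholds, sensitivity, specificity) over all distinct data
    values plus the all-positive/all-negative extremes, sorted so the curve
    runs from (FPR 0) to (FPR 1).
    """
    values = np.asarray(values, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    n_pos, n_neg = positive.sum(), (~positive).sum()
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be non-empty")
    thresholds = np.concatenate([[np.inf], np.unique(values)[::-1]])
    sens = np.array([(values[positive] >= t).mean() for t in thresholds])
    spec = np.array([(values[~positive] < t).mean() for t in thresholds])
    return thresholds, sens, spec


def roc_cutoff(table: pd.DataFrame, positive: str | np.ndarray, feature: str,
               endpoint: str = "os") -> RocResult:
    """AUC (trapezoidal over the empirical ROC) and the Youden-optimal cutoff.

    ``positive`` is a boolean column name or array marking the poor-prognosis
    class. Among thresholds tied on Youden's J the lowest wins; the reported
    cutoff is the midpoint between that threshold and the next lower observed
    value, i.e. it separates the observed groups.
    """
    values = table[feature].to_numpy(dtype=float)
    pos = table[positive].to_numpy(dtype=bool) if isinstance(positive, str) else np.asarray(positive, bool)
    thresholds, sens, spec = roc_curve_points(values, pos)
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens, fpr))
    j = sens + spec - 1.0
    finite = np.isfinite(thresholds)
    best_j = j[finite].max()
    tied = np.where(finite & (j >= best_j - 1e-12))[0]
    i = tied[np.argmin(thresholds[tied])]
    thr = thresholds[i]
    below = values[values < thr]
    cutoff = float((thr + below.max()) / 2.0) if below.size else float(thr)
    return RocResult(variable=feature, cutoff=cutoff, auc=auc,
                     sensitivity=float(sens[i]), specificity=float(spec[i]),
                     endpoint=endpoint)


def km_logrank(table: pd.DataFrame, endpoint: str, group: str | np.ndarray):
    """Kaplan-Meier curves per group and the two-sided log-rank p.

    Returns (curves, p) where ``curves`` maps group label to the fitted
    KaplanMeierFitter. Both groups must contain at least one event.
    """
    time_col, event_col = _endpoint_cols(endpoint)
    g = table[group].to_numpy() if isinstance(group, str) else np.asarray(group)
    levels = np.unique(g)
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {len(levels)}")
    curves = {}
    for lev in levels:
        sub = table[g == lev]
        if len(sub) == 0 or not sub[event_col].any():
            raise ValueError(f"group {lev!r} is empty or has no events")
        kmf = KaplanMeierFitter(label=str(lev))
        kmf.fit(sub[time_col], event_observed=sub[event_col].astype(bool))
        curves[lev] = kmf
    a, b = (table[g == lev] for lev in levels)
    res = logrank_test(a[time_col], b[time_col],
                       event_observed_A=a[event_col].astype(bool),
                       event_observed_B=b[event_col].astype(bool))
    return curves, float(res.p_value)


def _prepare_cox_frame(table: pd.DataFrame, covariates: list[str],
                       time_col: str, event_col: str) -> tuple[pd.DataFrame, dict[str, str]]:
    df = pd.DataFrame({time_col: table[time_col], event_col: table[event_col].astype(bool)})
    notes: dict[str, str] = {}
    for c in covariates:
        col = table[c]
        if col.dtype == bool or col.dtype == object:
            df[c] = col.astype(float) if col.dtype == bool else pd.factorize(col)[0].astype(float)
        elif "sphericity" in c:
            df[c] = col / SPHERICITY_SCALE
            notes[c] = "per tenth"
        else:
            df[c] = col.astype(float)
    return df.dropna(), notes


def _fit_cox(table: pd.DataFrame, endpoint: str, covariates: list[str]) -> list[SurvivalResult]:
    time_col, event_col = _endpoint_cols(endpoint)
    df, notes = _prepare_cox_frame(table, covariates, time_col, event_col)
    n_events = int(df[event_col].sum())
    if n_events < 10 * len(covariates):
        log.warning("Cox fit on %s: %d events for %d covariate(s); below the "
                    "~10 events-per-covariate guideline", endpoint, n_events, len(covariates))
    try:
        cph = CoxPHFitter()
        cph.fit(df, duration_col=time_col, event_col=event_col)
    except Exception as exc:  # report non-convergence per model, keep running
        log.warning("Cox model (%s ~ %s) failed: %s", endpoint, covariates, exc)
        return [SurvivalResult(variable=c, hr=np.nan, ci_low=np.nan, ci_high=np.nan,
                               p=np.nan, n=len(df), n_events=n_events,
                               scale_note=notes.get(c, ""), converged=False)
                for c in covariates]
    summ = cph.summary
    return [SurvivalResult(
        variable=c,
        hr=float(summ.loc[c, "exp(coef)"]),
        ci_low=float(summ.loc[c, "exp(coef) lower 95%"]),
        ci_high=float(summ.loc[c, "exp(coef) upper 95%"]),
        p=float(summ.loc[c, "p"]),
        n=len(df), n_events=n_events,
        scale_note=notes.get(c, "")) for c in covariates]


def cox_models(table: pd.DataFrame, endpoint: str,
               univariate: list[str] | None = None,
               multivariate: list[str] | None = None,
               ) -> dict[str, list[SurvivalResult]]:
    """Univariate fits per listed variable plus one multivariate fit.

    Hazard ratios come with Wald 95% CIs and p-values; sphericity columns are
    rescaled to per-0.1 units. Non-converging models are reported with NaN
    estimates rather than aborting the run.
    """
    out: dict[str, list[SurvivalResult]] = {"univariate": [], "multivariate": []}
    for var in univariate or []:
        out["univariate"].extend(_fit_cox(table, endpoint, [var]))
    if multivariate:
        out["multivariate"] = _fit_cox(table, endpoint, multivariate)
    return out
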