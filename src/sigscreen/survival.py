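"""Survival statistics: two-sample log-rank, Kaplan-Meier, Cox models, Harrell's c.

The two-sample log-rank statistic is computed directly from the
observed-vs-expected event table (the screen evaluates it tens of
thousands of times inside the permutation null, where per-call overhead
dominates); Kaplan-Meier, Nelson-Aalen, Cox fits and the concordance index
delegate to lifelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.utils import concordance_index as _lifelines_concordance
from scipy import stats


def _two_group_masks(groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = pd.unique(pd.Series(groups))
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 group labels, got {list(labels)}")
    g1 = np.asarray(groups) == labels[0]
    return g1, ~g1


def logrank_two_groups(times, events, groups) -> tuple[float, float]:
    """Two-sample log-rank test: returns (chi-square statistic, two-sided P).

    Standard 1-df chi-square from the observed-vs-expected event counts of
    group 1 summed over distinct event times, with the hypergeometric
    variance. Both groups must be non-empty and at least one event must
    occur.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    g1, g2 = _two_group_masks(np.asarray(groups))
    if g1.sum() == 0 or g2.sum() == 0:
        raise ValueError("both groups must be non-empty")
    if events.sum() == 0:
        raise ValueError("log-rank undefined with zero events")

    event_times = np.unique(times[events == 1])
    # at-risk counts: number with time >= t, per group
    order = np.argsort(times)
    ts = times[order]
    g1s = g1[order]
    n_total = len(ts)
    # index of first subject with time >= t
    first_at_risk = np.searchsorted(ts, event_times, side="left")
    n_at_risk = n_total - first_at_risk
    cum_g1 = np.concatenate([[0], np.cumsum(g1s)])
    n1_at_risk = g1.sum() - cum_g1[first_at_risk]
    # event counts at each event time, per group
    d_total = np.zeros(len(event_times))
    d1 = np.zeros(len(event_times))
    idx = np.searchsorted(event_times, times[events == 1])
    np.add.at(d_total, idx, 1)
    np.add.at(d1, idx, (g1[events == 1]).astype(float))

    with np.errstate(divide="ignore", invalid="ignore"):
        expected = d_total * n1_at_risk / n_at_risk
        var = (
            d_total
            * (n1_at_risk / n_at_risk)
            * (1 - n1_at_risk / n_at_risk)
            * (n_at_risk - d_total)
            / np.where(n_at_risk > 1, n_at_risk - 1, 1.0)
        )
    var = np.where(n_at_risk > 1, var, 0.0)
    observed_minus_expected = (d1 - expected).sum()
    total_var = var.sum()
    if total_var <= 0:
        return 0.0, 1.0
    chi2 = observed_minus_expected**2 / total_var
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def km_curve(times, events) -> pd.DataFrame:
    """Product-limit survival estimate as a step function.

    Returns a DataFrame with columns ``time`` and ``survival``; the first
    row is (0, 1) and the curve is right-continuous.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("need at least one subject")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    out = pd.DataFrame({"time": sf.index.to_numpy(float), "survival": sf.iloc[:, 0].to_numpy(float)})
    if out.iloc[0]["time"] != 0.0:
        out = pd.concat([pd.DataFrame({"time": [0.0], "survival": [1.0]}), out], ignore_index=True)
    return out


@dataclass(frozen=True)
class CoxResult:
    """Hazard-ratio estimate for a (possibly adjusted) binary group term."""

    hr: float
    ci_low: float
    ci_high: float
    p: float
    coef: float
    se: float
    converged: bool
    n_used: int
    n_dropped_missing: int = 0


def _fit_cox(df: pd.DataFrame, term: str) -> CoxResult:
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except (ConvergenceError, np.linalg.LinAlgError) as exc:
        del exc  # monotone likelihood / singular information: flag, don't raise
        return CoxResult(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, False, len(df))
    coef = float(cph.params_[term])
    se = float(cph.standard_errors_[term])
    if not np.isfinite(coef) or not np.isfinite(se) or se > 50:
        return CoxResult(np.nan, np.nan, np.nan, np.nan, coef, se, False, len(df))
    z = coef / se
    p = float(2 * stats.norm.sf(abs(z)))
    return CoxResult(
        hr=float(np.exp(coef)),
        ci_low=float(np.exp(coef - 1.96 * se)),
        ci_high=float(np.exp(coef + 1.96 * se)),
        p=p,
        coef=coef,
        se=se,
        converged=True,
        n_used=len(df),
    )


def cox_univariate(groups, times, events) -> CoxResult:
    """Cox PH fit of survival on a binary group indicator (Efron ties).

    ``groups`` may be 0/1 or two string labels (the second label in sorted
    order codes 1, i.e. HR is for that level vs the other). Monotone
    likelihood is reported as ``converged=False`` rather than raised.
    """
    x = _binary_code(groups)
    events = np.asarray(events, dtype=int)
    if len(np.unique(x)) != 2:
        raise ValueError("both covariate levels must be present")
    for level in (0, 1):
        if events[x == level].sum() == 0:
            raise ValueError("need at least one event in each group")
    df = pd.DataFrame({"time": np.asarray(times, float), "event": events, "group": x})
    return _fit_cox(df, "group")


def cox_multivariate(groups, covariates: pd.DataFrame, times, events) -> CoxResult:
    """Adjusted hazard ratio for the group term.

    Categorical covariates are dummy-coded (first level dropped);
    all-missing columns are dropped; rows with any missing covariate are
    excluded complete-case (the count is reported on the result). A
    rank-deficient design raises, naming the collinear columns.
    """
    x = _binary_code(groups)
    df = pd.DataFrame(
        {"time": np.asarray(times, float), "event": np.asarray(events, int), "group": x}
    )
    cov = covariates.reset_index(drop=True).copy()
    cov = cov.dropna(axis=1, how="all")
    if len(cov.columns):
        cat_cols = [c for c in cov.columns if not pd.api.types.is_numeric_dtype(cov[c])]
        cov = pd.get_dummies(cov, columns=cat_cols, drop_first=True, dtype=float)
        design = pd.concat([df.reset_index(drop=True), cov], axis=1)
    else:
        design = df.reset_index(drop=True)
    n_before = len(design)
    design = design.dropna()
    n_dropped = n_before - len(design)
    model_cols = [c for c in design.columns if c not in ("time", "event")]
    X = design[model_cols].to_numpy(float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        collinear = _collinear_columns(X, model_cols)
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")
    result = _fit_cox(design, "group")
    return replace(result, n_dropped_missing=n_dropped)


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    full_rank = np.linalg.matrix_rank(X)
    return [
        names[j]
        for j in range(X.shape[1])
        if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == full_rank
    ]


def _binary_code(groups) -> np.ndarray:
    arr = np.asarray(groups)
    if arr.dtype.kind in "biuf":
        return arr.astype(float)
    labels = sorted(pd.unique(pd.Series(arr)))
    if len(labels) > 2:
        raise ValueError(f"expected a binary group variable, got {labels}")
    return (arr == labels[-1]).astype(float)


def concordance_index(risk, times, events) -> float:
    """Harrell's c for a risk score (higher risk = earlier failure expected).

    Comparable pairs follow the usual censoring rule (pairs whose smaller
    time is censored are skipped); tied risk contributes 1/2.
    """
    risk = np.asarray(risk, dtype=float)
    try:
        return float(_lifelines_concordance(np.asarray(times, float), -risk, np.asarray(events, int)))
    except ZeroDivisionError as exc:
        raise ValueError("no comparable pairs for concordance index") from exc
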