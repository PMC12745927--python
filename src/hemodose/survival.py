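"""Survival-analysis stage: Kaplan–Meier, log-rank, Cox models, corrections.

The cohort table carries one row per patient with covariates, blood-dose
metrics (Gy, so Cox coefficients on dose covariates are per-Gy log hazard
ratios) and, per endpoint (e.g. LRC, DMFS, OS), an event indicator and a
time in days.  Fitting is delegated to lifelines; this module adds the
quartile-contrast log-rank design (top 25% vs bottom 25% of a metric,
middle half discarded), a score test at the null computed with the
Breslow convention (which reduces exactly to the log-rank statistic for a
single binary covariate without ties), explicit handling of degenerate
covariates, and standard multiple-testing corrections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test, proportional_hazard_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "KaplanMeierCurve",
    "CoxFit",
    "kaplan_meier",
    "quartile_logrank",
    "cox_fit",
    "cox_score_test",
    "ph_check",
    "adjust_pvalues",
]


@dataclass(frozen=True)
class KaplanMeierCurve:
    """Right-continuous product-limit survival estimate, S(0) = 1."""

    times: np.ndarray
    survival: np.ndarray
    all_censored: bool = False

    def at(self, t: float | np.ndarray) -> np.ndarray | float:
        """Evaluate S(t) (right-continuous step lookup)."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        padded = np.concatenate([[1.0], self.survival])
        result = padded[idx]
        return float(result) if np.isscalar(t) else result

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "survival": self.survival})


def kaplan_meier(times: Sequence[float], events: Sequence[int]) -> KaplanMeierCurve:
    """Product-limit survival estimator.

    An all-censored input yields the valid (flagged) estimate S ≡ 1.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("times must be non-empty")
    if np.any(times <= 0):
        raise ValueError("all times must be positive")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("event indicators must be 0 or 1")
    fitter = KaplanMeierFitter()
    fitter.fit(times, event_observed=events)
    sf = fitter.survival_function_
    timeline = sf.index.to_numpy(dtype=float)
    survival = sf.iloc[:, 0].to_numpy(dtype=float)
    keep = timeline > 0  # drop the S(0)=1 anchor row; `at` re-adds it
    return KaplanMeierCurve(
        times=timeline[keep], survival=survival[keep], all_censored=not events.any()
    )


def quartile_logrank(
    values: Sequence[float], times: Sequence[float], events: Sequence[int]
) -> tuple[float, float]:
    """Log-rank test contrasting the top and bottom quartiles of a metric.

    Patients are split at the 25th and 75th percentiles of ``values``; the
    middle half is discarded and a two-group log-rank test (χ², 1 df)
    compares the extremes.  Returns ``(statistic, p)``.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if values.size < 8:
        raise ValueError(f"need at least 8 patients for a quartile contrast, got {values.size}")
    q25, q75 = np.quantile(values, [0.25, 0.75])
    if q25 == q75:
        raise ValueError("degenerate quartile split: 25th and 75th percentiles coincide")
    low = values <= q25
    high = values >= q75
    result = logrank_test(times[low], times[high], events[low], events[high])
    return float(result.test_statistic), float(result.p_value)


@dataclass
class CoxFit:
    """Result of a Cox proportional-hazards fit.

    ``summary`` has one row per model term with columns
    ``coef, hr, ci_lower, ci_upper, p`` (HR = exp(coef), per-Gy for dose
    covariates entered in Gy).  ``score_test`` is the χ² score statistic of
    the global null β = 0 under the Breslow convention.
    """

    summary: pd.DataFrame
    n_used: int
    n_events: int
    n_excluded: int
    converged: bool
    duration_col: str
    event_col: str
    score_test: float = np.nan
    score_test_p: float = np.nan
    diagnostics: str = ""
    dropped_terms: tuple[str, ...] = ()
    _fitter: CoxPHFitter | None = field(default=None, repr=False)
    _data: pd.DataFrame | None = field(default=None, repr=False)


def _design_matrix(
    table: pd.DataFrame, covariates: Sequence[str], categorical: Sequence[str]
) -> pd.DataFrame:
    """Complete-case design matrix with dummy-coded categoricals."""
    design = pd.DataFrame(index=table.index)
    for name in covariates:
        if name in categorical:
            dummies = pd.get_dummies(
                table[name].astype("category"), prefix=name, drop_first=True, dtype=float
            )
            design = design.join(dummies)
        else:
            design[name] = pd.to_numeric(table[name], errors="coerce")
    return design


def cox_score_test(
    design: pd.DataFrame | np.ndarray, times: np.ndarray, events: np.ndarray
) -> tuple[float, float]:
    """Score test of the global null β = 0 for the Cox partial likelihood.

    Uses the Breslow tie convention: each event contributes the deviation
    of its covariates from the risk-set mean to the score, and the
    risk-set covariance to the information.  For one binary covariate with
    no tied event times, U²/I is exactly the two-group log-rank χ².
    """
    x = np.asarray(design, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    order = np.argsort(times)[::-1]  # descending: suffix sums become prefix sums
    x, times, events = x[order], times[order], events[order]

    n, k = x.shape
    cum_n = np.arange(1, n + 1, dtype=float)
    cum_x = np.cumsum(x, axis=0)
    cum_xx = np.cumsum(x[:, :, None] * x[:, None, :], axis=0)

    # Risk set of an event = everyone with time >= the event time; with ties
    # that is the full tied block, so index the cumulative sums at the last
    # position of each tied block.
    last_in_block = np.r_[times[1:] != times[:-1], True]
    candidates = np.where(last_in_block, np.arange(n), n)
    block_end = np.minimum.accumulate(candidates[::-1])[::-1]

    score = np.zeros(k)
    information = np.zeros((k, k))
    event_rows = np.nonzero(events == 1)[0]
    for i in event_rows:
        j = block_end[i]
        m = cum_n[j]
        mean = cum_x[j] / m
        score += x[i] - mean
        information += cum_xx[j] / m - np.outer(mean, mean)
    try:
        statistic = float(score @ np.linalg.solve(information, score))
    except np.linalg.LinAlgError:
        return np.nan, np.nan
    p = float(stats.chi2.sf(statistic, df=k))
    return statistic, p


def cox_fit(
    table: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: Sequence[str],
    categorical: Sequence[str] = (),
) -> CoxFit:
    """Fit a Cox proportional-hazards model (complete-case, Wald inference).

    Categorical covariates are dummy-coded against their first level;
    ordinal staging variables should be passed as numeric columns to obtain
    a single trend hazard ratio.  Zero-variance terms are reported with
    coefficient 0 / HR 1 rather than breaking the fit; non-convergence is
    flagged on the returned :class:`CoxFit` instead of raising.
    """
    design = _design_matrix(table, covariates, categorical)
    frame = design.copy()
    frame["_time"] = pd.to_numeric(table[duration_col], errors="coerce")
    frame["_event"] = pd.to_numeric(table[event_col], errors="coerce")
    complete = frame.dropna()
    n_excluded = len(frame) - len(complete)
    n_events = int(complete["_event"].sum())
    if n_events < 2:
        raise ValueError(f"need at least 2 events among complete cases, got {n_events}")

    terms = [c for c in complete.columns if c not in ("_time", "_event")]
    degenerate = [t for t in terms if complete[t].nunique() <= 1]
    active = [t for t in terms if t not in degenerate]

    rows: dict[str, dict[str, float]] = {
        t: {"coef": 0.0, "hr": 1.0, "ci_lower": 1.0, "ci_upper": 1.0, "p": 1.0}
        for t in degenerate
    }
    converged = True
    diagnostics = ""
    fitter = None
    if active:
        fitter = CoxPHFitter()
        fit_frame = complete[active + ["_time", "_event"]]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fitter.fit(fit_frame, duration_col="_time", event_col="_event")
            for t in active:
                rows[t] = {
                    "coef": float(fitter.params_[t]),
                    "hr": float(np.exp(fitter.params_[t])),
                    "ci_lower": float(np.exp(fitter.confidence_intervals_.loc[t].iloc[0])),
                    "ci_upper": float(np.exp(fitter.confidence_intervals_.loc[t].iloc[1])),
                    "p": float(fitter.summary.loc[t, "p"]),
                }
        except (ConvergenceError, np.linalg.LinAlgError, ValueError) as err:
            converged = False
            diagnostics = f"{type(err).__name__}: {err}"
            fitter = None
            for t in active:
                rows[t] = {
                    "coef": np.nan,
                    "hr": np.nan,
                    "ci_lower": np.nan,
                    "ci_upper": np.nan,
                    "p": np.nan,
                }

    if active:
        score_stat, score_p = cox_score_test(
            complete[active], complete["_time"].to_numpy(), complete["_event"].to_numpy()
        )
    else:
        score_stat, score_p = np.nan, np.nan

    summary = pd.DataFrame.from_dict(rows, orient="index").loc[terms]
    summary.index.name = "covariate"
    return CoxFit(
        summary=summary,
        n_used=len(complete),
        n_events=n_events,
        n_excluded=n_excluded,
        converged=converged,
        duration_col=duration_col,
        event_col=event_col,
        score_test=score_stat,
        score_test_p=score_p,
        diagnostics=diagnostics,
        dropped_terms=tuple(degenerate),
        _fitter=fitter,
        _data=complete if fitter is not None else None,
    )


def ph_check(fit: CoxFit, min_events: int = 3) -> dict[str, float]:
    """Proportional-hazards check via scaled Schoenfeld residuals vs time.

    Returns a per-covariate p-value; NaN marks terms for which the check is
    not applicable (degenerate covariate, failed fit, or too few events).
    """
    result: dict[str, float] = {t: np.nan for t in fit.summary.index}
    if fit._fitter is None or fit._data is None or fit.n_events < min_events:
        return result
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        test = proportional_hazard_test(fit._fitter, fit._data, time_transform="rank")
    p_values = test.summary["p"]
    for term in p_values.index.get_level_values(0).unique():
        value = p_values.loc[term]
        result[term] = float(value.iloc[0] if hasattr(value, "iloc") else value)
    return result


_ADJUST_METHODS = {"bonferroni": "bonferroni", "holm": "holm", "bh": "fdr_bh"}


def adjust_pvalues(p_values: Sequence[float], method: str) -> np.ndarray:
    """Multiple-testing adjustment: Bonferroni, Holm, or Benjamini–Hochberg.

    Returns adjusted p-values clipped to 1, in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in _ADJUST_METHODS:
        raise ValueError(f"method must be one of {sorted(_ADJUST_METHODS)}, got {method!r}")
    return multipletests(p, method=_ADJUST_METHODS[method])[1]
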