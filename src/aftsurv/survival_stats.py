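"""Nonparametric survival statistics: Kaplan-Meier curves, the logrank test,
censoring-adjusted prediction error, Harrell's concordance index, and
bootstrap percentile confidence intervals.

These are the evaluation primitives of the package.  The Kaplan-Meier
estimator here is also reused by :mod:`aftsurv.imputation` on model
residuals, which is why ``km_estimate`` accepts arbitrary real-valued
"times" (a residual scale has no natural origin).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "KMCurve",
    "LogrankResult",
    "PerformanceReport",
    "km_estimate",
    "km_survival_at",
    "km_masses",
    "logrank_test",
    "ipcw_rmse",
    "harrell_c",
    "bootstrap_ci",
]

#: weights larger than this are capped in the IPCW error (censoring-survival
#: left limit below 1e-8 makes the estimator numerically undefined)
MAX_IPCW_WEIGHT = 1e8


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate of a survival function.

    Attributes
    ----------
    times : distinct times at which at least one event occurred, increasing.
    n_risk : number at risk just before each event time (censored
        observations tied with an event time count as at risk).
    n_event : number of events at each event time.
    survival : the Kaplan-Meier estimate S(t) at each event time.
    greenwood_se : Greenwood standard error of S(t) at each event time.
    """

    times: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray
    survival: np.ndarray
    greenwood_se: np.ndarray

    def survival_at(self, t: float) -> float:
        """Right-continuous step evaluation S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def survival_before(self, t: float) -> float:
        """Left limit S(t-): the step value just before ``t``."""
        idx = np.searchsorted(self.times, t, side="left") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.times,
                "n_risk": self.n_risk,
                "n_event": self.n_event,
                "survival": self.survival,
                "se": self.greenwood_se,
            }
        )


@dataclass(frozen=True)
class LogrankResult:
    """Two-group logrank test.

    ``observed`` and ``expected`` are per-group event counts O_g and E_g;
    the statistic is (O_1 - E_1)^2 / Var(O_1 - E_1) referred to chi^2(1).
    """

    statistic: float
    pvalue: float
    observed: np.ndarray
    expected: np.ndarray


@dataclass
class PerformanceReport:
    """Test-set evaluation of one model: IPCW-RMSE (years), Harrell's
    c-index, and the two LPS logrank tests, each with a bootstrap
    percentile confidence interval in ``ci`` (measure -> (lower, upper));
    a logrank entry is None when the LPS split was degenerate."""

    rmse: float
    c_index: float
    logrank_lps2: "LogrankResult | None"
    logrank_lps5: "LogrankResult | None"
    ci: dict

    def to_dict(self) -> dict:
        def lr(r):
            return None if r is None else {
                "statistic": r.statistic,
                "pvalue": r.pvalue,
                "observed": r.observed.tolist(),
                "expected": r.expected.tolist(),
            }

        return {
            "rmse": self.rmse,
            "c_index": self.c_index,
            "logrank_lps2": lr(self.logrank_lps2),
            "logrank_lps5": lr(self.logrank_lps5),
            "ci": {k: list(v) for k, v in self.ci.items()},
        }


def _as_surv_arrays(times, events):
    t = np.asarray(times, dtype=float)
    d = np.asarray(events)
    if t.ndim != 1 or d.shape != t.shape:
        raise ValueError("times and events must be 1-d arrays of equal length")
    if t.size == 0:
        raise ValueError("empty survival data")
    if not np.all(np.isin(d, (0, 1))):
        raise ValueError("events must be binary (0/1)")
    return t, d.astype(int)


def km_estimate(times: Sequence[float], events: Sequence[int]) -> KMCurve:
    """Kaplan-Meier product-limit estimator with Greenwood variance.

    Censored observations leave the risk set after their time; ties between
    events and censorings at the same time keep the censored subjects in the
    risk set for that time (the usual convention).
    """
    t, d = _as_surv_arrays(times, events)
    order = np.argsort(t, kind="stable")
    t, d = t[order], d[order]

    uniq, first_idx = np.unique(t, return_index=True)
    n = t.size
    # at risk just before each unique time = n - (# observations strictly earlier)
    n_risk_all = n - first_idx
    d_all = np.add.reduceat(d, first_idx)

    has_event = d_all > 0
    ev_times = uniq[has_event]
    n_risk = n_risk_all[has_event]
    n_event = d_all[has_event]

    frac = 1.0 - n_event / n_risk
    survival = np.cumprod(frac)
    # Greenwood: Var S(t) = S(t)^2 * sum_{f<=t} d/(n(n-d))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = n_event / (n_risk * (n_risk - n_event).astype(float))
        var = survival**2 * np.cumsum(terms)
    se = np.sqrt(var)
    se[survival == 0.0] = 0.0  # 0 * inf at the terminal event
    return KMCurve(ev_times, n_risk, n_event, survival, se)


def km_survival_at(curve: KMCurve, t: float) -> tuple[float, float]:
    """Evaluate (S(t), Greenwood SE) as a right-continuous step function."""
    if t <= 0:
        raise ValueError("t must be positive")
    idx = np.searchsorted(curve.times, t, side="right") - 1
    if idx < 0:
        return 1.0, 0.0
    return float(curve.survival[idx]), float(curve.greenwood_se[idx])


def km_masses(curve: KMCurve) -> tuple[np.ndarray, np.ndarray, float]:
    """Probability masses of the KM distribution at its event times.

    Returns ``(times, masses, tail)`` where ``tail`` is the survival
    probability left beyond the last event time (nonzero when the largest
    observation is censored).
    """
    if curve.times.size == 0:
        return curve.times, np.array([]), 1.0
    prev = np.concatenate([[1.0], curve.survival[:-1]])
    masses = prev - curve.survival
    return curve.times, masses, float(curve.survival[-1])


def logrank_test(times, events, group) -> LogrankResult:
    """Two-sample logrank test with the hypergeometric variance.

    ``group`` is a binary vector; the statistic sums observed-minus-expected
    events over the pooled distinct event times and is compared to chi^2(1).
    No events anywhere gives statistic 0, p-value 1.
    """
    t, d = _as_surv_arrays(times, events)
    g = np.asarray(group).astype(int)
    if g.shape != t.shape or not np.all(np.isin(g, (0, 1))):
        raise ValueError("group must be a binary vector matching times")
    if g.min() == g.max():
        raise ValueError("both groups must be non-empty")

    order = np.argsort(t, kind="stable")
    t, d, g = t[order], d[order], g[order]
    uniq, first_idx = np.unique(t, return_index=True)
    n = t.size

    n_f = n - first_idx
    # at risk in group 1 just before each unique time
    g1_later = np.cumsum(g[::-1])[::-1]  # of indices >= i
    n1_f = g1_later[first_idx]
    d_f = np.add.reduceat(d, first_idx)
    d1_f = np.add.reduceat(d * g, first_idx)

    keep = d_f > 0
    n_f, n1_f, d_f, d1_f = n_f[keep], n1_f[keep], d_f[keep], d1_f[keep]

    p1 = n1_f / n_f
    o_minus_e_1 = float(np.sum(d1_f - d_f * p1))
    with np.errstate(divide="ignore", invalid="ignore"):
        var_terms = d_f * p1 * (1.0 - p1) * (n_f - d_f) / (n_f - 1.0)
    var_terms = np.where(n_f > 1, var_terms, 0.0)
    var = float(np.sum(var_terms))

    O1, E1 = float(np.sum(d1_f)), float(np.sum(d_f * p1))
    O_total = float(np.sum(d_f))
    observed = np.array([O_total - O1, O1])
    expected = np.array([O_total - E1, E1])

    if var <= 0.0:
        return LogrankResult(0.0, 1.0, observed, expected)
    stat = o_minus_e_1**2 / var
    return LogrankResult(stat, float(stats.chi2.sf(stat, df=1)), observed, expected)


def ipcw_rmse(times, events, predictions) -> float:
    """Root mean squared prediction error, inverse-probability-of-censoring
    weighted.

    Each uncensored squared error (y_i - yhat_i)^2 is divided by the left
    limit of the Kaplan-Meier estimate of the *censoring* distribution at
    y_i (the censoring KM uses 1 - delta as its event indicator).  With no
    censoring all weights are one and this reduces to the plain RMSE.
    """
    t, d = _as_surv_arrays(times, events)
    yhat = np.asarray(predictions, dtype=float)
    if yhat.shape != t.shape:
        raise ValueError("predictions must match times in length")
    if np.any(yhat <= 0):
        raise ValueError("predictions must be positive survival times")
    if d.sum() == 0:
        raise ValueError("need at least one uncensored observation")

    cens_km = km_estimate(t, 1 - d)
    sc = np.array([cens_km.survival_before(ti) for ti in t])
    unc = d == 1
    w = np.zeros_like(t)
    small = sc[unc] < 1.0 / MAX_IPCW_WEIGHT
    if np.any(small):
        warnings.warn(
            "censoring-survival left limit below 1e-8 for some uncensored "
            "observations; IPCW weight capped at 1e8",
            RuntimeWarning,
            stacklevel=2,
        )
    w[unc] = 1.0 / np.maximum(sc[unc], 1.0 / MAX_IPCW_WEIGHT)
    return float(np.sqrt(np.mean(w * (t - yhat) ** 2)))


def harrell_c(times, events, predictions) -> float:
    """Harrell's concordance index.

    Over ordered pairs (i, j), i != j, counts pairs with delta_i = 1 and
    y_i < y_j where the predictions agree (yhat_i < yhat_j, strict: tied
    predictions score zero), divided by the number of such comparable pairs.
    """
    t, d = _as_surv_arrays(times, events)
    yhat = np.asarray(predictions, dtype=float)
    if yhat.shape != t.shape:
        raise ValueError("predictions must match times in length")

    comparable = (d[:, None] == 1) & (t[:, None] < t[None, :])
    denom = int(comparable.sum())
    if denom == 0:
        raise ValueError("no comparable pairs (denominator of c-index is zero)")
    concordant = comparable & (yhat[:, None] < yhat[None, :])
    return float(concordant.sum() / denom)


def bootstrap_ci(
    measure: Callable[..., float],
    arrays: Sequence[np.ndarray],
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap interval for a measure of (times, events, ...).

    Patients (rows) are resampled jointly with replacement ``n_boot`` times;
    the 100*alpha/2 and 100*(1-alpha/2) percentiles of the recomputed
    measure form the interval.  Resamples on which the measure is undefined
    (raises or returns NaN) are redrawn; if more than half of the draws
    fail, an error is raised.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    arrays = [np.asarray(a) for a in arrays]
    n = arrays[0].shape[0]
    if any(a.shape[0] != n for a in arrays):
        raise ValueError("all arrays must share the first dimension")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    values = np.empty(n_boot)
    failures = 0
    i = 0
    while i < n_boot:
        idx = rng.integers(0, n, size=n)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                v = measure(*(a[idx] for a in arrays))
        except (ValueError, ZeroDivisionError):
            v = np.nan
        if np.isnan(v):
            failures += 1
            if failures > n_boot / 2 and failures > 10:
                raise RuntimeError(
                    "bootstrap measure undefined in more than half of resamples"
                )
            continue
        values[i] = v
        i += 1
    lo, hi = np.percentile(values, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)
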