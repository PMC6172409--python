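"""Survival association and clinical-covariate comparison.

Patients are dichotomized at the mean expression of a gene (ties to "high"),
compared with the Kaplan-Meier product-limit estimator and the two-group
log-rank test, and summarized by the survival rate at a clinical horizon
(default five years = 1825 days).  Clinical indicator tables are compared
between subtypes with the Pearson chi-square test (no continuity correction).

The Kaplan-Meier and log-rank implementations follow the standard
conventions — at tied times events are processed before censorings, and the
log-rank variance is the hypergeometric form; both are cross-checked against
lifelines in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import InputError

FIVE_YEARS_DAYS = 1825.0


def mean_split(expr: pd.Series) -> pd.Series:
    """Split samples into high/low at the mean; values equal to the mean go high."""
    if len(expr) < 2:
        raise InputError("need >= 2 samples to split")
    mean = float(expr.mean())
    labels = pd.Series(np.where(expr >= mean, "high", "low"),
                       index=expr.index, name="group")
    if labels.nunique() < 2:
        raise InputError("mean split produced a single group (constant expression?)")
    return labels


@dataclass
class KmCurve:
    """Product-limit estimate: one row per distinct event time."""

    table: pd.DataFrame  # columns: time, n_at_risk, n_events, survival

    @property
    def times(self) -> np.ndarray:
        return self.table["time"].to_numpy()

    @property
    def survival(self) -> np.ndarray:
        return self.table["survival"].to_numpy()


def km_curve(times: np.ndarray, events: np.ndarray) -> KmCurve:
    """Kaplan-Meier estimator; ties: events before censorings at equal times."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise InputError("empty survival input")
    if (times <= 0).any():
        raise InputError("times must be > 0")
    if not np.isin(events, (0, 1)).all():
        raise InputError("events must be 0/1")
    order = np.lexsort((1 - events, times))  # time asc, events first at ties
    times, events = times[order], events[order]
    rows = []
    s = 1.0
    n_at_risk = len(times)
    i = 0
    while i < len(times):
        t = times[i]
        d = int(events[(times == t)].sum())
        removed = int((times == t).sum())
        if d > 0:
            s *= 1.0 - d / n_at_risk
            rows.append({"time": t, "n_at_risk": n_at_risk, "n_events": d, "survival": s})
        n_at_risk -= removed
        i += removed
    return KmCurve(pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"]))


def survival_rate_at(km: KmCurve, horizon: float) -> float:
    """S at the last event time <= horizon; 1.0 before the first event."""
    if horizon <= 0:
        raise InputError("horizon must be > 0")
    mask = km.times <= horizon
    if not mask.any():
        return 1.0
    return float(km.survival[mask][-1])


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank: chi-square (1 df) and p.

    O - E for group A accumulated over distinct event times with the
    hypergeometric variance.
    """
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, int)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, int)
    if ta.size == 0 or tb.size == 0:
        raise InputError("both groups must be nonempty")
    if ea.sum() + eb.sum() == 0:
        raise InputError("log-rank undefined with no events")
    event_times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        n_a = int((ta >= t).sum())
        n_b = int((tb >= t).sum())
        d_a = int(((ta == t) & (ea == 1)).sum())
        d_b = int(((tb == t) & (eb == 1)).sum())
        n = n_a + n_b
        d = d_a + d_b
        if n < 2 or n_a == 0 or n_b == 0:
            continue
        e_a = d * n_a / n
        o_minus_e += d_a - e_a
        var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1) if n > 1 else 0.0
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def logrank_by_group(times: pd.Series, events: pd.Series, groups: pd.Series) -> tuple[float, float]:
    """Convenience wrapper: log-rank between the two levels of ``groups``."""
    levels = list(pd.unique(groups.dropna()))
    if len(levels) != 2:
        raise InputError("log-rank wrapper needs exactly two groups")
    a = groups == levels[0]
    b = groups == levels[1]
    return logrank_test(times[a], events[a], times[b], events[b])


def chisq_clinical(table: np.ndarray | pd.DataFrame) -> tuple[float, int, float]:
    """Pearson chi-square on an r x c contingency table, no continuity correction."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise InputError("contingency table must be at least 2x2")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise InputError("zero marginal in contingency table")
    chi2, p, df, _ = stats.chi2_contingency(arr, correction=False)
    return float(chi2), int(df), float(p)


def gene_survival(expr: pd.Series, times: pd.Series, events: pd.Series,
                  horizon: float = FIVE_YEARS_DAYS) -> dict:
    """Mean-split survival readout for one gene.

    Returns the log-rank chi-square/p and per-group survival rates at the
    horizon, on the samples shared by expression and survival input.
    """
    common = expr.index.intersection(times.index)
    groups = mean_split(expr.loc[common])
    hi = groups == "high"
    lo = ~hi
    chi2, p = logrank_test(times.loc[common][hi], events.loc[common][hi],
                           times.loc[common][lo], events.loc[common][lo])
    out = {"chi2": chi2, "p": p, "n_high": int(hi.sum()), "n_low": int(lo.sum())}
    for name, mask in (("high", hi), ("low", lo)):
        km = km_curve(times.loc[common][mask].to_numpy(),
                      events.loc[common][mask].to_numpy())
        out[f"rate_{name}"] = survival_rate_at(km, horizon)
    return out
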