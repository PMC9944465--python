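"""Clinical outcome statistics: response rates, Kaplan-Meier survival,
Mantel-Cox log-rank with Mantel-Haenszel hazard ratio, and contingency tests.

Response rates follow the standard solid-tumor conventions: the objective
response rate is (CR+PR) and the disease control rate (CR+PR+SD), both over
the response-evaluable patients (NE excluded from the denominator).  Median
survival is the first time the product-limit curve drops to 0.5 or below.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import RESPONSE_CATEGORIES, ClinicalTable

__all__ = [
    "ResponseSummary",
    "SurvivalCurve",
    "LogRankResult",
    "response_rates",
    "kaplan_meier",
    "logrank_and_hr",
    "contingency_test",
]


@dataclass
class ResponseSummary:
    counts: dict[str, int]
    n_total: int
    n_evaluable: int  # excludes NE
    orr_percent: float | None  # 100 * (CR+PR) / evaluable
    dcr_percent: float | None  # 100 * (CR+PR+SD) / evaluable

    def as_row(self) -> dict:
        row = {f"n_{cat}": self.counts.get(cat, 0) for cat in RESPONSE_CATEGORIES}
        row["n_total"] = self.n_total
        row["n_evaluable"] = self.n_evaluable
        row["orr_percent"] = None if self.orr_percent is None else round(self.orr_percent, 2)
        row["dcr_percent"] = None if self.dcr_percent is None else round(self.dcr_percent, 2)
        return row


@dataclass
class SurvivalCurve:
    """Product-limit estimate evaluated at the distinct event times."""

    event_times: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    censor_times: np.ndarray
    median: float | None

    def survival_at(self, t: float) -> float:
        s = 1.0
        for time, surv in zip(self.event_times, self.survival):
            if time <= t:
                s = surv
            else:
                break
        return s


@dataclass
class LogRankResult:
    chi_square: float
    p_value: float
    hazard_ratio: float | None
    ci_low: float | None
    ci_high: float | None
    median_by_group: tuple[float | None, float | None]
    observed: tuple[float, float] = field(default=(0.0, 0.0))
    expected: tuple[float, float] = field(default=(0.0, 0.0))


def response_rates(responses: Iterable[str] | ClinicalTable) -> ResponseSummary:
    """ORR/DCR over response-evaluable patients (NE excluded)."""
    if isinstance(responses, ClinicalTable):
        responses = list(responses.data["response"])
    responses = [str(r).strip().upper() for r in responses]
    bad = set(responses) - set(RESPONSE_CATEGORIES)
    if bad:
        raise ValueError(f"unknown response codes {sorted(bad)}; allowed {RESPONSE_CATEGORIES}")
    if not responses:
        raise ValueError("no responses")
    counts = {cat: responses.count(cat) for cat in RESPONSE_CATEGORIES}
    n_total = len(responses)
    n_eval = n_total - counts["NE"]
    if n_eval == 0:
        return ResponseSummary(counts, n_total, 0, None, None)
    orr = 100.0 * (counts["CR"] + counts["PR"]) / n_eval
    dcr = 100.0 * (counts["CR"] + counts["PR"] + counts["SD"]) / n_eval
    return ResponseSummary(counts, n_total, n_eval, orr, dcr)


def kaplan_meier(times: Sequence[float], events: Sequence[bool]) -> SurvivalCurve:
    """Product-limit estimator; censored subjects leave the risk set without
    dropping the curve.  Median = first time S(t) <= 0.5, None if never."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if len(t) != len(e):
        raise ValueError("times and events differ in length")
    if (t < 0).any():
        raise ValueError("negative survival times")
    order = np.argsort(t, kind="mergesort")
    t, e = t[order], e[order]
    event_times = np.unique(t[e])
    at_risk, n_events, survival = [], [], []
    s = 1.0
    for tt in event_times:
        n_risk = int((t >= tt).sum())
        d = int(((t == tt) & e).sum())
        s *= 1.0 - d / n_risk
        at_risk.append(n_risk)
        n_events.append(d)
        survival.append(s)
    survival_arr = np.asarray(survival)
    median = None
    hit = np.nonzero(survival_arr <= 0.5)[0] if len(survival_arr) else []
    if len(hit):
        median = float(event_times[hit[0]])
    return SurvivalCurve(
        event_times=event_times,
        at_risk=np.asarray(at_risk),
        n_events=np.asarray(n_events),
        survival=survival_arr,
        censor_times=np.unique(t[~e]),
        median=median,
    )


def logrank_and_hr(
    group1: tuple[Sequence[float], Sequence[bool]],
    group2: tuple[Sequence[float], Sequence[bool]],
    alpha: float = 0.05,
) -> LogRankResult:
    """Mantel-Cox log-rank test and Mantel-Haenszel hazard ratio.

    At each distinct event time the observed group-1 deaths are compared with
    their hypergeometric expectation given the risk sets; chi2 =
    (O1-E1)^2/V.  HR = (O1/E1)/(O2/E2) with a normal CI on the log scale,
    se = sqrt(1/E1 + 1/E2).  A group with zero events leaves the HR
    undefined (with a warning); the log-rank statistic is still reported.
    """
    t1 = np.asarray(group1[0], dtype=float)
    e1 = np.asarray(group1[1], dtype=bool)
    t2 = np.asarray(group2[0], dtype=float)
    e2 = np.asarray(group2[1], dtype=bool)
    if len(t1) == 0 or len(t2) == 0:
        raise ValueError("both groups must be non-empty")
    event_times = np.unique(np.concatenate([t1[e1], t2[e2]]))
    O1 = E1 = V = 0.0
    for tt in event_times:
        n1 = float((t1 >= tt).sum())
        n2 = float((t2 >= tt).sum())
        n = n1 + n2
        d1 = float(((t1 == tt) & e1).sum())
        d2 = float(((t2 == tt) & e2).sum())
        d = d1 + d2
        if n == 0 or d == 0:
            continue
        O1 += d1
        E1 += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    O_total = float(e1.sum() + e2.sum())
    O2 = O_total - O1
    E2 = O_total - E1
    if V > 0:
        chi2 = (O1 - E1) ** 2 / V
        p = float(stats.chi2.sf(chi2, df=1))
    else:
        chi2, p = 0.0, 1.0
    hr = ci_low = ci_high = None
    if e1.sum() == 0 or e2.sum() == 0:
        warnings.warn("a group has zero events; hazard ratio undefined", stacklevel=2)
    elif E1 > 0 and E2 > 0 and O2 > 0:
        hr = (O1 / E1) / (O2 / E2)
        z = stats.norm.ppf(1 - alpha / 2)
        se = math.sqrt(1.0 / E1 + 1.0 / E2)
        ci_low = hr * math.exp(-z * se)
        ci_high = hr * math.exp(z * se)
    km1 = kaplan_meier(t1, e1)
    km2 = kaplan_meier(t2, e2)
    return LogRankResult(
        chi_square=float(chi2),
        p_value=p,
        hazard_ratio=hr,
        ci_low=ci_low,
        ci_high=ci_high,
        median_by_group=(km1.median, km2.median),
        observed=(O1, O2),
        expected=(E1, E2),
    )


def contingency_test(
    table: Sequence[Sequence[int]],
    method: Literal["fisher", "chi2", "auto"] = "auto",
    yates: bool = False,
) -> tuple[float | None, float]:
    """Fisher's exact (two-sided) or chi-squared test on a 2x2 table.

    ``auto`` picks Fisher when any expected count is below 5.  A zero margin
    makes the table degenerate: p = 1.  Returns (statistic, p); the statistic
    is None for Fisher (odds ratio is not the reported quantity here).
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2) or (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        raise ValueError("expected a 2x2 table of non-negative integers")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return None, 1.0
    if method == "auto":
        expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()
        method = "fisher" if (expected < 5).any() else "chi2"
    if method == "fisher":
        _, p = stats.fisher_exact(arr, alternative="two-sided")
        return None, float(p)
    if method == "chi2":
        chi2, p, _, _ = stats.chi2_contingency(arr, correction=yates)
        return float(chi2), float(p)
    raise ValueError(f"unknown method {method!r}")
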