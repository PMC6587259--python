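"""Statistical kernel shared by the pipeline stages.

Contingency tests, the exact binomial test, Welch's t and Pearson
correlation are thin, explicitly-parameterized wrappers around scipy so
that every module applies identical conventions (no continuity
correction for the 2x2 chi-square, point-probability two-sided rule for
the binomial, Satterthwaite degrees of freedom).  The survival machinery
-- Kaplan-Meier product-limit curves, the two-group log-rank test and a
univariate Cox proportional-hazards fit with Breslow tie handling -- is
implemented here directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import (
    ConvergenceError,
    DesignError,
    InsufficientDataError,
    ParameterError,
)

__all__ = [
    "SurvivalRecord",
    "chi_square_2x2",
    "fisher_exact_2x2",
    "binomial_two_sided",
    "welch_t",
    "pearson",
    "km_curve",
    "logrank",
    "cox_univariate",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """Follow-up of one sample: time in months, event flag, group/covariate.

    ``event`` is 1 for death/progression and 0 for censoring.  ``group``
    may be a categorical label (log-rank) or a numeric covariate (Cox).
    """

    sample: str
    time: float
    event: int
    group: object = None

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ParameterError(f"negative follow-up time for {self.sample!r}")
        if self.event not in (0, 1):
            raise ParameterError(f"event flag must be 0/1, got {self.event!r}")


def chi_square_2x2(a: int, b: int, c: int, d: int, continuity: bool = False):
    """Pearson chi-square for the 2x2 table [[a, b], [c, d]].

    Defaults to *no* Yates continuity correction: the uncorrected
    statistic N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) on 1 df.

    Returns (statistic, p).
    """
    cells = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in cells):
        raise ParameterError("2x2 cells must be non-negative integers")
    a, b, c, d = (int(x) for x in cells)
    n = a + b + c + d
    margins = ((a + b), (c + d), (a + c), (b + d))
    if any(m == 0 for m in margins):
        raise ParameterError("degenerate 2x2 table: a zero margin")
    if continuity:
        num = n * max(abs(a * d - b * c) - n / 2.0, 0.0) ** 2
    else:
        num = n * (a * d - b * c) ** 2
    stat = num / (margins[0] * margins[1] * margins[2] * margins[3])
    return stat, float(sps.chi2.sf(stat, 1))


def fisher_exact_2x2(a: int, b: int, c: int, d: int, side: str = "two-sided") -> float:
    """Exact hypergeometric p for [[a, b], [c, d]].

    ``side``: "greater" (odds ratio > 1, i.e. row 1 enriched for column
    1), "less", or "two-sided" (point-probability rule).
    """
    if side not in ("two-sided", "greater", "less"):
        raise ParameterError(f"unknown side {side!r}")
    return float(sps.fisher_exact([[a, b], [c, d]], alternative=side)[1])


def binomial_two_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial test: sum of outcome probabilities <= P(k)."""
    if not 0 <= k <= n:
        raise ParameterError(f"need 0 <= k <= n, got k={k}, n={n}")
    if n == 0:
        return 1.0
    return float(sps.binomtest(int(k), int(n), p0).pvalue)


def welch_t(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    pooled: bool = False,
):
    """Welch's (default) or pooled-variance t-test.

    Returns (t, df, p).  ``alternative`` is "two-sided", "greater" (mean
    of x greater) or "less".  Two zero-variance samples with equal means
    return t=0, p=1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InsufficientDataError("each sample needs >= 2 observations")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, float(x.size + y.size - 2), 1.0
    res = sps.ttest_ind(x, y, equal_var=pooled, alternative=alternative)
    return float(res.statistic), float(res.df), float(res.pvalue)


def pearson(x: Sequence[float], y: Sequence[float]):
    """Pearson correlation with the t-transform p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ParameterError("x and y must have equal length")
    if x.size < 3:
        raise InsufficientDataError("Pearson correlation needs n >= 3")
    if x.var() == 0 or y.var() == 0:
        raise InsufficientDataError("correlation undefined for a constant vector")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def _as_survival_arrays(records: Sequence[SurvivalRecord]):
    time = np.array([r.time for r in records], dtype=float)
    event = np.array([r.event for r in records], dtype=int)
    return time, event


def km_curve(records: Sequence[SurvivalRecord]):
    """Kaplan-Meier product-limit estimate.

    Returns a dict of aligned arrays: ``time`` (distinct event times,
    ascending), ``survival`` (S(t) just after each event time),
    ``at_risk`` and ``events``.  S(0)=1 is implicit.
    """
    if not records:
        raise InsufficientDataError("no survival records")
    time, event = _as_survival_arrays(records)
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    out_t, out_s, out_n, out_d = [], [], [], []
    s = 1.0
    for t in np.unique(time[event == 1]):
        n_at_risk = int(np.sum(time >= t))
        d = int(np.sum((time == t) & (event == 1)))
        s *= 1.0 - d / n_at_risk
        out_t.append(float(t))
        out_s.append(s)
        out_n.append(n_at_risk)
        out_d.append(d)
    return {
        "time": np.array(out_t),
        "survival": np.array(out_s),
        "at_risk": np.array(out_n),
        "events": np.array(out_d),
    }


def logrank(records: Sequence[SurvivalRecord]):
    """Two-group log-rank test.

    Records must carry exactly two distinct group labels.  Tied event
    times are pooled.  Returns (statistic, p) on 1 df.
    """
    groups = sorted({r.group for r in records}, key=str)
    if len(groups) != 2:
        raise DesignError(f"log-rank needs exactly 2 groups, got {len(groups)}")
    time, event = _as_survival_arrays(records)
    g1 = np.array([r.group == groups[0] for r in records], dtype=bool)
    if g1.all() or (~g1).all():
        raise DesignError("one group is empty")
    if event.sum() == 0:
        raise InsufficientDataError("no events observed")
    obs = 0.0
    exp = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = int(((time == t) & (event == 1)).sum())
        d1 = int(((time == t) & (event == 1) & g1).sum())
        obs += d1
        exp += d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    stat = (obs - exp) ** 2 / var
    return float(stat), float(sps.chi2.sf(stat, 1))


def cox_univariate(
    records: Sequence[SurvivalRecord],
    max_iter: int = 50,
    tol: float = 1e-9,
):
    """Univariate Cox proportional-hazards fit by Newton-Raphson.

    The partial likelihood uses Breslow tie handling.  ``group`` on each
    record is interpreted as a numeric covariate.  Returns a dict with
    ``beta``, ``hazard_ratio`` (exp(beta)), ``se`` and the Wald ``p``.
    """
    time, event = _as_survival_arrays(records)
    x = np.array([float(r.group) for r in records])
    if event.sum() < 2:
        raise InsufficientDataError("Cox fit needs >= 2 events")
    if np.ptp(x) == 0:
        raise DesignError("covariate is constant")
    # center for numerical stability; beta is unchanged
    x = x - x.mean()
    order = np.argsort(time, kind="stable")
    time, event, x = time[order], event[order], x[order]
    event_times = np.unique(time[event == 1])

    beta = 0.0
    for _ in range(max_iter):
        w = np.exp(beta * x)
        score = 0.0
        info = 0.0
        for t in event_times:
            at_risk = time >= t
            s0 = w[at_risk].sum()
            s1 = (w[at_risk] * x[at_risk]).sum()
            s2 = (w[at_risk] * x[at_risk] ** 2).sum()
            dead = (time == t) & (event == 1)
            d = dead.sum()
            score += x[dead].sum() - d * s1 / s0
            info += d * (s2 / s0 - (s1 / s0) ** 2)
        if info <= 0:
            raise ConvergenceError("non-positive information in Cox fit")
        step = score / info
        beta += step
        if abs(step) < tol:
            se = 1.0 / np.sqrt(info)
            z = beta / se
            return {
                "beta": float(beta),
                "hazard_ratio": float(np.exp(beta)),
                "se": float(se),
                "p": float(2 * sps.norm.sf(abs(z))),
                "iterations": _ + 1,
            }
    raise ConvergenceError(
        f"Cox fit did not converge in {max_iter} iterations (last step {step:.3g})"
    )
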