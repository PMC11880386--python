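"""Survival statistics from their defining formulas.

Kaplan-Meier product-limit estimation, the two-group log-rank test, and a
binary-covariate Cox proportional-hazards model (Newton maximization of
the partial likelihood, Breslow ties by default, Efron optional). The
implementations are deliberately self-contained so each can be checked
against lifelines in the test suite; the conventions follow the standard
ones for overall-survival analyses:

* event = 1 means death observed, 0 means censored at that time;
* subjects censored at an event time remain at risk for that event;
* the Cox confidence interval is the 95% Wald interval exp(b +/- 1.96 se).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

__all__ = ["KMCurve", "CoxResult", "km_estimate", "logrank_test", "cox_binary"]


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate: steps at event times only.

    Arrays are aligned per distinct event time; ``survival`` is the
    estimate just after that time. Censored times reduce later at-risk
    counts without contributing a step.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t): the step function evaluated at time t."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class CoxResult:
    hr: float
    ci_low: float
    ci_high: float
    log_hr: float
    se: float
    p: float
    n_iter: int
    ties: str


def _as_arrays(times, events, groups=None):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.ndim != 1 or t.shape != e.shape:
        raise ValueError("times and events must be equal-length 1-d arrays")
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise ValueError("times must be finite and >= 0")
    if not np.all(np.isin(e, (0, 1))):
        raise ValueError("events must be 0 (censored) or 1 (death)")
    if groups is None:
        return t, e
    g = np.asarray(groups, dtype=int)
    if g.shape != t.shape or not np.all(np.isin(g, (0, 1))):
        raise ValueError("groups must be a binary vector matching times")
    if g.min() == g.max():
        raise ValueError("both groups must be non-empty")
    return t, e, g


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimate S(t) = prod (1 - d_i/n_i)."""
    t, e = _as_arrays(times, events)
    if len(t) == 0:
        raise ValueError("at least one sample is required")
    event_times = np.unique(t[e == 1])
    surv = []
    at_risk = []
    d_out = []
    s = 1.0
    for ti in event_times:
        n_i = int(np.sum(t >= ti))
        d_i = int(np.sum((t == ti) & (e == 1)))
        s *= 1.0 - d_i / n_i
        surv.append(s)
        at_risk.append(n_i)
        d_out.append(d_i)
    return KMCurve(times=event_times, survival=np.array(surv),
                   at_risk=np.array(at_risk, dtype=int),
                   events=np.array(d_out, dtype=int))


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p) with 1 df.

    At each pooled event time the observed group-1 events are compared
    with their hypergeometric expectation; the statistic is
    (sum O - sum E)^2 / sum V.
    """
    t, e, g = _as_arrays(times, events, groups)
    if e.sum() == 0:
        raise ValueError("log-rank test requires at least one event")
    o_minus_e = 0.0
    var = 0.0
    for ti in np.unique(t[e == 1]):
        at_risk = t >= ti
        n = int(at_risk.sum())
        n1 = int((at_risk & (g == 1)).sum())
        d = int(((t == ti) & (e == 1)).sum())
        d1 = int(((t == ti) & (e == 1) & (g == 1)).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        raise ValueError("log-rank variance is zero; groups are not comparable")
    chi2 = o_minus_e**2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def _cox_derivatives(beta: float, t, e, g, ties: str) -> tuple[float, float, float]:
    """(log partial likelihood, score, information) at beta."""
    loglik = 0.0
    score = 0.0
    info = 0.0
    r = math.exp(beta)
    for ti in np.unique(t[e == 1]):
        at_risk = t >= ti
        dead = (t == ti) & (e == 1)
        d = int(dead.sum())
        d1 = int((dead & (g == 1)).sum())
        n1 = int((at_risk & (g == 1)).sum())
        n0 = int(at_risk.sum()) - n1
        if ties == "breslow":
            for _ in range(d):
                s0 = n0 + n1 * r
                s1 = n1 * r
                loglik -= math.log(s0)
                score -= s1 / s0
                info += s1 / s0 * (1 - s1 / s0)
            loglik += d1 * beta
            score += d1
        else:  # efron: downweight the tied deaths' own risk scores
            tied_s0 = (d - d1) + d1 * r
            tied_s1 = d1 * r
            for k in range(d):
                s0 = n0 + n1 * r - (k / d) * tied_s0
                s1 = n1 * r - (k / d) * tied_s1
                loglik -= math.log(s0)
                score -= s1 / s0
                info += s1 / s0 * (1 - s1 / s0)
            loglik += d1 * beta
            score += d1
    return loglik, score, info


def cox_binary(
    times,
    events,
    groups,
    ties: Literal["breslow", "efron"] = "breslow",
    max_iter: int = 100,
    tol: float = 1e-10,
) -> CoxResult:
    """Cox proportional-hazards fit for a single binary covariate.

    Newton maximization of the partial likelihood; the hazard ratio is
    exp(beta) for group 1 versus group 0, with the 95% Wald interval.
    Raises when the likelihood is monotone (all events ordered by group),
    in which case the hazard ratio is not estimable.
    """
    t, e, g = _as_arrays(times, events, groups)
    if e.sum() == 0:
        raise ValueError("Cox fit requires at least one event")
    if ties not in ("breslow", "efron"):
        raise ValueError(f"unknown tie handling {ties!r}")

    beta = 0.0
    for it in range(1, max_iter + 1):
        _, score, info = _cox_derivatives(beta, t, e, g, ties)
        if info <= 0:
            raise ValueError("zero information; hazard ratio not estimable")
        step = score / info
        beta += step
        if abs(beta) > 50:
            raise ValueError(
                "monotone partial likelihood (|log HR| diverging); the hazard "
                "ratio is not estimable from these data"
            )
        if abs(step) < tol:
            _, _, info = _cox_derivatives(beta, t, e, g, ties)
            se = 1.0 / math.sqrt(info)
            z = beta / se
            return CoxResult(
                hr=math.exp(beta),
                ci_low=math.exp(beta - 1.96 * se),
                ci_high=math.exp(beta + 1.96 * se),
                log_hr=beta,
                se=se,
                p=float(2 * stats.norm.sf(abs(z))),
                n_iter=it,
                ties=ties,
            )
    raise ValueError(f"Newton iteration did not converge in {max_iter} steps")
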