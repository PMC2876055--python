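"""Survival machinery: Kaplan-Meier, log-rank and Cox proportional hazards.

Everything here is implemented directly from the estimating equations —
the product-limit estimator with Greenwood's variance, the Mantel-Haenszel
(log-rank) two-group test, and the Cox partial likelihood maximized by
Newton-Raphson with the Efron correction for tied event times (Breslow
available).  Times are in months throughout; "5-year survival" is the KM
estimate at 60 months.  Censorings recorded at an event time are treated
as still at risk for that event (censored-after-event convention).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


def _as_arrays(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty survival input")
    if t.shape != e.shape:
        raise ValueError("times and events must have equal length")
    if (t < 0).any():
        raise ValueError("survival times must be >= 0")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("events must be binary")
    return t, e


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KMFit:
    """Right-continuous product-limit fit over the distinct event times."""

    times: np.ndarray          # distinct event times (deaths only)
    survival: np.ndarray       # S(t) just after each event time
    variance: np.ndarray       # Greenwood variance of S(t)
    n_at_risk: np.ndarray
    n_events: np.ndarray
    t_max: float               # largest observed time (event or censoring)

    def survival_at(self, t: float) -> float:
        return survival_at(self, t)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "variance": self.variance,
                "at_risk": self.n_at_risk,
                "events": self.n_events,
            }
        )


def km_fit(times, events) -> KMFit:
    """Product-limit estimator with Greenwood variance."""
    t, e = _as_arrays(times, events)
    event_times = np.unique(t[e == 1])
    surv, var, risks, deaths = [], [], [], []
    s = 1.0
    greenwood = 0.0
    for tau in event_times:
        n_risk = int((t >= tau).sum())
        d = int(((t == tau) & (e == 1)).sum())
        s *= (n_risk - d) / n_risk
        if n_risk > d:
            greenwood += d / (n_risk * (n_risk - d))
        else:
            greenwood = np.inf  # S hits 0; variance degenerate
        surv.append(s)
        var.append(s * s * greenwood if np.isfinite(greenwood) else 0.0)
        risks.append(n_risk)
        deaths.append(d)
    return KMFit(
        times=event_times,
        survival=np.array(surv),
        variance=np.array(var),
        n_at_risk=np.array(risks, dtype=int),
        n_events=np.array(deaths, dtype=int),
        t_max=float(t.max()),
    )


def survival_at(fit: KMFit, t_months: float) -> float:
    """Step-function value of S at ``t_months`` (right-continuous)."""
    if t_months < 0:
        raise ValueError("time must be >= 0")
    if t_months > fit.t_max:
        warnings.warn(
            f"t={t_months} exceeds the largest observed time {fit.t_max}; "
            "returning the last estimate",
            stacklevel=2,
        )
    idx = np.searchsorted(fit.times, t_months, side="right") - 1
    return 1.0 if idx < 0 else float(fit.survival[idx])


# ---------------------------------------------------------------------------
# log-rank test
# ---------------------------------------------------------------------------

@dataclass
class LogRankResult:
    chi_square: float
    p_value: float
    observed: tuple[float, float]   # events per group
    expected: tuple[float, float]
    df: int = 1


def logrank_test(times, events, groups) -> LogRankResult:
    """Two-group Mantel-Haenszel log-rank test.

    Builds the 2x2 table at every distinct event time; the statistic is
    (O1 - E1)^2 / V with hypergeometric variance V, chi-square with 1 df.
    """
    t, e = _as_arrays(times, events)
    g = np.asarray(groups)
    labels = np.unique(g)
    if labels.size != 2:
        raise ValueError(f"exactly 2 groups required, got {labels.size}")
    in1 = g == labels[0]
    if in1.all() or not in1.any():
        raise ValueError("each group must be non-empty")

    o1 = e1 = v = 0.0
    for tau in np.unique(t[e == 1]):
        at_risk = t >= tau
        n = at_risk.sum()
        n1 = (at_risk & in1).sum()
        d = ((t == tau) & (e == 1)).sum()
        d1 = ((t == tau) & (e == 1) & in1).sum()
        o1 += d1
        e1 += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    total_events = float((e == 1).sum())
    if v == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2 = (o1 - e1) ** 2 / v
        p = float(stats.chi2.sf(chi2, df=1))
    return LogRankResult(
        chi_square=float(chi2),
        p_value=p,
        observed=(float(o1), total_events - float(o1)),
        expected=(float(e1), total_events - float(e1)),
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

class CoxConvergenceError(RuntimeError):
    pass


@dataclass
class CoxFit:
    beta: np.ndarray
    hazard_ratio: np.ndarray
    se: np.ndarray
    wald_p: np.ndarray
    covariates: list[str]
    converged: bool
    ties: str
    n_used: int
    n_events: int
    log_likelihood: float

    def summary(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "covariate": self.covariates,
                "beta": self.beta,
                "HR": self.hazard_ratio,
                "se": self.se,
                "p": self.wald_p,
            }
        )


def _cox_loglik(beta, t, e, x, ties):
    """Partial log-likelihood, gradient and information (Efron or Breslow)."""
    n, p = x.shape
    eta = x @ beta
    w = np.exp(eta)
    order = np.argsort(-t)  # decreasing time: cumulative sums give risk sets
    ts, es, xs, ws = t[order], e[order], x[order], w[order]
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))

    cum_w = 0.0
    cum_wx = np.zeros(p)
    cum_wxx = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:
            cum_w += ws[j]
            cum_wx += ws[j] * xs[j]
            cum_wxx += ws[j] * np.outer(xs[j], xs[j])
            j += 1
        dead = [m for m in range(i, j) if es[m] == 1]
        d = len(dead)
        if d:
            xd = xs[dead]
            wd = ws[dead]
            ll += eta[order][dead].sum()
            s_w = wd.sum()
            s_wx = (wd[:, None] * xd).sum(0)
            s_wxx = np.einsum("m,mi,mj->ij", wd, xd, xd)
            for l in range(d):
                frac = l / d if ties == "efron" else 0.0
                denom = cum_w - frac * s_w
                num = cum_wx - frac * s_wx
                num2 = cum_wxx - frac * s_wxx
                ll -= np.log(denom)
                mu = num / denom
                grad_term = mu
                info += num2 / denom - np.outer(mu, mu)
                grad -= grad_term
            grad += xd.sum(0)
        i = j
    return ll, grad, info


def cox_fit(
    times,
    events,
    covariates,
    names: list[str] | None = None,
    ties: str = "efron",
    max_iter: int = 50,
    tol: float = 1e-9,
) -> CoxFit:
    """Cox proportional-hazards fit by Newton-Raphson.

    ``covariates`` is an (n, p) array (a single covariate may be 1-D).
    Rows with a NaN covariate are dropped (complete-case, count logged).
    Raises :class:`CoxConvergenceError` on non-convergence or monotone
    likelihood (complete separation), ValueError on constant covariates.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    t, e = _as_arrays(times, events)
    x = np.asarray(covariates, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if names is None:
        names = [f"x{i}" for i in range(x.shape[1])]
    keep = ~np.isnan(x).any(axis=1)
    if not keep.all():
        logger.info("cox_fit: dropped %d rows with unknown covariates", int((~keep).sum()))
    t, e, x = t[keep], e[keep], x[keep]
    if e.sum() < 1:
        raise ValueError("at least one event is required")
    if np.any(np.ptp(x, axis=0) == 0):
        raise ValueError("constant covariate in Cox model")
    x = x - x.mean(axis=0)  # centring; betas unchanged, better conditioning

    beta = np.zeros(x.shape[1])
    ll_old = -np.inf
    for _ in range(max_iter):
        ll, grad, info = _cox_loglik(beta, t, e, x, ties)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise CoxConvergenceError("singular information matrix") from exc
        # step-halving if the likelihood does not improve
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, _, _ = _cox_loglik(cand, t, e, x, ties)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2
        beta = beta + scale * step
        # scale-invariant separation guard: a unit-SD effect beyond exp(50)
        # means the partial likelihood is monotone
        if np.abs(beta * x.std(axis=0)).max() > 50:
            raise CoxConvergenceError("monotone likelihood / complete separation")
        if np.max(np.abs(grad)) < tol or abs(ll - ll_old) < tol * (abs(ll) + 1):
            break
        ll_old = ll
    else:
        raise CoxConvergenceError(f"no convergence in {max_iter} iterations")

    ll, grad, info = _cox_loglik(beta, t, e, x, ties)
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2 * stats.norm.sf(np.abs(z))
    return CoxFit(
        beta=beta,
        hazard_ratio=np.exp(beta),
        se=se,
        wald_p=p,
        covariates=list(names),
        converged=True,
        ties=ties,
        n_used=int(len(t)),
        n_events=int(e.sum()),
        log_likelihood=float(ll),
    )
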