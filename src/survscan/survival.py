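"""Survival-analysis primitives: Kaplan–Meier, log-rank, binary Cox, BH FDR.

These are own implementations (not wrappers) because the cutpoint scan
needs to fit thousands of two-group Cox models per cohort: the scan-facing
entry point is a batch Newton–Raphson that maximises the Cox partial
likelihood for many dichotomisations of the same cohort simultaneously.

For a single binary covariate x in {0, 1} with coefficient beta and
r = exp(beta), the risk-score sums over a risk set reduce to counts of the
high group, so the Efron-corrected partial log-likelihood at an event time
with d tied events (s of them in the high group, n1 of n at risk in the
high group) is

    s*beta - sum_{l=0}^{d-1} log( phi_l ),   phi_l = R - (l/d) * D

with R = (n - n1) + n1*r and D = (d - s) + s*r. Since d(a*r)/dbeta = a*r,
the score and observed information per Efron term are mu_l and
mu_l*(1 - mu_l) with mu_l = phi_l' / phi_l — the same algebra as a
Bernoulli mean, which the implementation below exploits. Breslow's
approximation is the l/d -> 0 special case with multiplicity d.

The score test evaluated at beta = 0 is the log-rank statistic on tie-free
data; with ties the two differ only in the variance convention
(hypergeometric for the log-rank proper, model-based for the Cox score).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

Z_95 = float(stats.norm.ppf(0.975))  # 1.959963984540054

#: |beta| bound used to flag a monotone partial likelihood
BETA_CAP = 15.0


@dataclass
class SurvivalSample:
    """One subject: follow-up time, event indicator, binary group label."""

    time: float
    event: int
    group: int

    def __post_init__(self):
        if self.time < 0:
            raise ValueError("time must be >= 0")
        if self.event not in (0, 1) or self.group not in (0, 1):
            raise ValueError("event and group must be 0 or 1")


@dataclass
class KMCurve:
    """Product-limit estimate over the distinct event times of one group."""

    times: np.ndarray         # strictly increasing distinct event times
    survival: np.ndarray      # S(t) at each event time, non-increasing
    greenwood_se: np.ndarray
    at_risk: np.ndarray       # n at risk just before each event time
    n_events: np.ndarray      # events at each time
    n: int = 0                # group size

    def survival_at(self, t: float) -> float:
        """S(t), right-continuous step function with S(0) = 1."""
        k = np.searchsorted(self.times, t, side="right")
        return 1.0 if k == 0 else float(self.survival[k - 1])


@dataclass
class CoxFit:
    """Two-group Cox proportional-hazards fit (high vs low)."""

    beta: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    wald_p: float
    score_chi2: float
    score_p: float
    converged: bool
    n: int
    n_events: int


def _as_arrays(time, event, group=None):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.ndim != 1 or event.shape != time.shape:
        raise ValueError("time and event must be 1-D arrays of equal length")
    if np.any(time < 0):
        raise ValueError("times must be >= 0")
    if not np.isin(event, [0, 1]).all():
        raise ValueError("event indicators must be 0 or 1")
    if group is None:
        return time, event
    group = np.asarray(group, dtype=int)
    if group.shape != time.shape or not np.isin(group, [0, 1]).all():
        raise ValueError("group must be a 0/1 array matching time")
    return time, event, group


def km_estimate(time, event) -> KMCurve:
    """Kaplan–Meier estimator with Greenwood standard errors.

    Censoring times tied with an event time leave the risk set after the
    event (events first). When the last risk set is exhausted (S reaches 0)
    the Greenwood SE is reported as 0.
    """
    time, event = _as_arrays(time, event)
    n = time.size
    if n == 0:
        raise ValueError("km_estimate requires at least one sample")
    order = np.argsort(time, kind="stable")
    ts, es = time[order], event[order]
    etimes = np.unique(ts[es == 1])
    if etimes.size == 0:
        return KMCurve(times=etimes, survival=np.empty(0), greenwood_se=np.empty(0),
                       at_risk=np.empty(0, int), n_events=np.empty(0, int), n=n)
    first = np.searchsorted(ts, etimes, side="left")
    at_risk = n - first
    ev_pos = np.flatnonzero(es == 1)
    d = np.bincount(np.searchsorted(etimes, ts[ev_pos]), minlength=etimes.size)
    surv = np.cumprod(1.0 - d / at_risk)
    with np.errstate(divide="ignore", invalid="ignore"):
        gw = np.cumsum(np.where(at_risk > d, d / (at_risk * (at_risk - d)), np.inf))
        se = surv * np.sqrt(gw)
    se = np.where(surv == 0.0, 0.0, se)
    return KMCurve(times=etimes, survival=surv, greenwood_se=se,
                   at_risk=at_risk.astype(int), n_events=d.astype(int), n=n)


def _event_tables(time, event, G):
    """Per-event-time risk tables shared by log-rank and the Cox batch.

    G is a (n_models, n) boolean group matrix. Returns distinct event times,
    events d and risk-set size nrisk per time (1-D), plus per-model high-group
    events s and high-group at-risk counts n1 (2-D, models x times).
    """
    order = np.argsort(time, kind="stable")
    ts, es = time[order], event[order]
    Gs = G[:, order]
    etimes = np.unique(ts[es == 1])
    if etimes.size == 0:
        raise ValueError("no events in the data")
    first = np.searchsorted(ts, etimes, side="left")
    nrisk = ts.size - first
    # suffix sums give the high-group size of each risk set
    suffix = np.concatenate(
        [np.cumsum(Gs[:, ::-1], axis=1)[:, ::-1],
         np.zeros((G.shape[0], 1), dtype=int)], axis=1)
    n1 = suffix[:, first]
    ev_pos = np.flatnonzero(es == 1)
    key = np.searchsorted(etimes, ts[ev_pos])
    d = np.bincount(key, minlength=etimes.size)
    # events are contiguous in `key`; reduceat sums tied events per time
    starts = np.concatenate([[0], np.cumsum(d)[:-1]])
    s = np.add.reduceat(Gs[:, ev_pos].astype(int), starts, axis=1)
    return etimes, d, nrisk, s, n1


def logrank_test(time, event, group):
    """Two-group log-rank test; returns (chi2, p) with 1 df."""
    time, event, group = _as_arrays(time, event, group)
    if group.min() == group.max():
        raise ValueError("log-rank test requires both groups non-empty")
    if event.sum() == 0:
        raise ValueError("log-rank test requires at least one event")
    _, d, nrisk, s, n1 = _event_tables(time, event, group[None, :])
    s, n1 = s[0], n1[0]
    frac = n1 / nrisk
    expected = d * frac
    with np.errstate(divide="ignore", invalid="ignore"):
        var = d * frac * (1 - frac) * (nrisk - d) / (nrisk - 1)
    var = np.where(nrisk > 1, var, 0.0)
    v = var.sum()
    if v <= 0:
        return 0.0, 1.0
    chi2 = float((s.sum() - expected.sum()) ** 2 / v)
    return chi2, float(stats.chi2.sf(chi2, 1))


def _cox_batch(time, event, G, ties="efron", max_iter=50, tol=1e-9):
    """Newton–Raphson Cox fits for many dichotomisations at once.

    Returns a dict of per-model arrays (beta, se, score_chi2, converged, ...).
    Models with an empty group are the caller's responsibility to exclude.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    etimes, d, nrisk, s, n1 = _event_tables(time, event, G)
    m = G.shape[0]
    K = etimes.size
    if ties == "efron":
        idx = np.repeat(np.arange(K), d)
        frac = np.concatenate([np.arange(dk) / dk for dk in d])
        w = np.ones(idx.size)
    else:
        idx = np.arange(K)
        frac = np.zeros(K)
        w = d.astype(float)
    n0 = (nrisk - n1)[:, idx]          # models x rows, low group at risk
    n1r = n1[:, idx].astype(float)
    s0 = (d - s)[:, idx]               # low-group tied events
    s1 = s[:, idx].astype(float)
    S_tot = s.sum(axis=1).astype(float)

    def loglik_parts(beta):
        r = np.exp(beta)[:, None]
        phi = (n0 + n1r * r) - frac[None, :] * (s0 + s1 * r)
        dphi = (n1r - frac[None, :] * s1) * r
        mu = dphi / phi
        ll = S_tot * beta - (w[None, :] * np.log(phi)).sum(axis=1)
        U = S_tot - (w[None, :] * mu).sum(axis=1)
        info = (w[None, :] * mu * (1.0 - mu)).sum(axis=1)
        return ll, U, info

    beta = np.zeros(m)
    ll, U0, I0 = loglik_parts(beta)
    U, info = U0.copy(), I0.copy()
    converged = np.zeros(m, dtype=bool)
    for _ in range(max_iter):
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(info > 1e-12, U / np.maximum(info, 1e-300),
                            np.sign(U) * 1.0)
        step = np.where(converged, 0.0, step)
        new = np.clip(beta + step, -BETA_CAP, BETA_CAP)
        ll_new, U_new, I_new = loglik_parts(new)
        # step-halving for any model whose partial log-likelihood decreased
        for _h in range(30):
            worse = ~converged & (ll_new < ll - 1e-12)
            if not worse.any():
                break
            new = np.where(worse, np.clip(beta + (new - beta) / 2.0,
                                          -BETA_CAP, BETA_CAP), new)
            ll_new, U_new, I_new = loglik_parts(new)
        delta = np.abs(new - beta)
        beta, ll, U, info = new, ll_new, U_new, I_new
        converged |= delta < tol
        if converged.all():
            break
    # a capped beta signals a monotone likelihood, not convergence
    monotone = np.abs(beta) >= BETA_CAP - 1e-6
    converged &= ~monotone
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.where(info > 0, 1.0 / np.sqrt(np.maximum(info, 1e-300)), np.inf)
        score_chi2 = np.where(I0 > 0, U0 ** 2 / np.maximum(I0, 1e-300), 0.0)
        wald_chi2 = np.where(np.isfinite(se), (beta / se) ** 2, 0.0)
    return {
        "beta": beta,
        "se": se,
        "score_chi2": score_chi2,
        "score_p": stats.chi2.sf(score_chi2, 1),
        "wald_p": stats.chi2.sf(wald_chi2, 1),
        "converged": converged,
        "n_events": int(d.sum()),
    }


def cox_binary_fit(time, event, group, ties="efron", max_iter=50,
                   tol=1e-9) -> CoxFit:
    """Cox proportional-hazards fit for a single binary covariate.

    Newton–Raphson from beta = 0 with step-halving; Efron tie handling by
    default. The score test is evaluated at beta = 0 (the log-rank statistic
    on tie-free data); Wald SE comes from the inverse observed information.
    A monotone likelihood (all events ordered by group) is flagged with
    ``converged=False`` and beta capped at +/-15; HR and CI are then
    unreliable by construction.
    """
    time, event, group = _as_arrays(time, event, group)
    if group.min() == group.max():
        raise ValueError("cox_binary_fit requires both groups non-empty")
    if event.sum() == 0:
        raise ValueError("cox_binary_fit requires at least one event")
    res = _cox_batch(time, event, group[None, :], ties=ties,
                     max_iter=max_iter, tol=tol)
    beta = float(res["beta"][0])
    se = float(res["se"][0])
    with np.errstate(over="ignore"):
        ci_low = float(np.exp(beta - Z_95 * se)) if np.isfinite(se) else 0.0
        ci_high = float(np.exp(beta + Z_95 * se)) if np.isfinite(se) else np.inf
    return CoxFit(
        beta=beta,
        se=se,
        hr=float(np.exp(beta)),
        ci_low=ci_low,
        ci_high=ci_high,
        wald_p=float(res["wald_p"][0]),
        score_chi2=float(res["score_chi2"][0]),
        score_p=float(res["score_p"][0]),
        converged=bool(res["converged"][0]),
        n=int(time.size),
        n_events=int(event.sum()),
    )


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1, mapped back to the
    input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-D array")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q
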