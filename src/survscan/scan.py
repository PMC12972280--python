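"""Quartile-band optimal-cutpoint scan.

The core procedure: enumerate every distinct observed expression value
between the lower and upper quartiles as a candidate dichotomisation
threshold (high = expression strictly above the cutoff), fit a two-group
Cox model at each, adjust the scan's score p-values with Benjamini–
Hochberg, select the lowest-p cutoff, and call the finding significant only
when the best cutoff satisfies raw p < alpha (0.05) and q <= fdr_max (0.20)
concurrently. Because the minimum is taken over many highly correlated
tests, the raw best p is anti-conservative; the joint rule is what keeps
the procedure honest (quantified in :mod:`survscan.simulate`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CohortDataset
from .survival import CoxFit, KMCurve, Z_95, _cox_batch, bh_fdr, km_estimate

DEFAULT_ALPHA = 0.05
DEFAULT_FDR_MAX = 0.20
MIN_SCAN_N = 8


@dataclass
class CutpointResult:
    """One scanned cutoff: group sizes, Cox fit, raw p and q-value."""

    cutoff: float
    n_low: int
    n_high: int
    fit: CoxFit
    p: float
    q: float


@dataclass
class ScanResult:
    cohort_name: str
    gene_id: str
    results: list
    best: int
    significant: bool
    alpha: float = DEFAULT_ALPHA
    fdr_max: float = DEFAULT_FDR_MAX

    @property
    def best_result(self) -> CutpointResult:
        return self.results[self.best]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append({
                "cutoff": r.cutoff, "n_low": r.n_low, "n_high": r.n_high,
                "beta": r.fit.beta, "hr": r.fit.hr, "ci_low": r.fit.ci_low,
                "ci_high": r.fit.ci_high, "p": r.p, "q": r.q,
                "converged": int(r.fit.converged),
            })
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        b = self.best_result
        return {
            "cohort_name": self.cohort_name,
            "gene_id": self.gene_id,
            "alpha": self.alpha,
            "fdr_max": self.fdr_max,
            "n_cutoffs": len(self.results),
            "significant": bool(self.significant),
            "best": {
                "cutoff": b.cutoff, "n_low": b.n_low, "n_high": b.n_high,
                "hr": b.fit.hr, "ci_low": b.fit.ci_low, "ci_high": b.fit.ci_high,
                "beta": b.fit.beta, "se": b.fit.se,
                "p": b.p, "q": b.q, "converged": b.fit.converged,
                "n": b.fit.n, "n_events": b.fit.n_events,
            },
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)


def candidate_cutoffs(expr, quartile_method: str = "linear") -> np.ndarray:
    """Distinct observed expression values in the quartile band [Q1, Q3).

    Dichotomising at a returned value v (high = expr > v) always leaves both
    groups non-empty: v itself falls in the low group and values above Q3 in
    the high group. Quartiles use linear interpolation by default
    (``numpy.quantile`` conventions are accepted for ``quartile_method``).
    """
    expr = np.asarray(expr, dtype=float)
    if expr.size < MIN_SCAN_N:
        raise ValueError(f"cutoff scan requires n >= {MIN_SCAN_N}, got {expr.size}")
    if np.all(expr == expr[0]):
        raise ValueError("all expression values are equal; no cutoffs to scan")
    q1, q3 = np.quantile(expr, [0.25, 0.75], method=quartile_method)
    values = np.unique(expr)
    cand = values[(values >= q1) & (values < q3)]
    if cand.size < 2:
        raise ValueError(
            f"fewer than 2 distinct expression values in the quartile band "
            f"[{q1!r}, {q3!r})"
        )
    return cand


def significance_call(best: CutpointResult, alpha: float = DEFAULT_ALPHA,
                      fdr_max: float = DEFAULT_FDR_MAX) -> bool:
    """Concurrent rule: raw p below alpha AND q-value at most fdr_max."""
    return bool(best.p < alpha and best.q <= fdr_max)


def scan_cutoffs(cohort: CohortDataset, alpha: float = DEFAULT_ALPHA,
                 fdr_max: float = DEFAULT_FDR_MAX, ties: str = "efron",
                 quartile_method: str = "linear") -> ScanResult:
    """Fit one two-group Cox model per candidate cutoff and pick the best.

    The ranking p is the score (log-rank) p from each fit; q-values are
    BH-adjusted across the scan (one gene, one cohort). Non-converged fits
    (monotone likelihoods) stay in the result table, flagged, but cannot be
    selected as best. Ties on the minimum p resolve to the smaller cutoff.
    """
    cuts = candidate_cutoffs(cohort.expr, quartile_method=quartile_method)
    if cohort.n_events == 0:
        raise ValueError("cutoff scan requires at least one observed event")
    G = cohort.expr[None, :] > cuts[:, None]
    res = _cox_batch(cohort.os_time, cohort.os_event, G, ties=ties)
    p = res["score_p"]
    q = bh_fdr(p)
    n_high = G.sum(axis=1)
    results = []
    for i, cut in enumerate(cuts):
        beta = float(res["beta"][i])
        se = float(res["se"][i])
        fit = CoxFit(
            beta=beta, se=se, hr=float(np.exp(beta)),
            ci_low=float(np.exp(beta - Z_95 * se)) if np.isfinite(se) else 0.0,
            ci_high=float(np.exp(beta + Z_95 * se)) if np.isfinite(se) else np.inf,
            wald_p=float(res["wald_p"][i]),
            score_chi2=float(res["score_chi2"][i]),
            score_p=float(p[i]),
            converged=bool(res["converged"][i]),
            n=cohort.n, n_events=cohort.n_events,
        )
        results.append(CutpointResult(
            cutoff=float(cut), n_low=int(cohort.n - n_high[i]),
            n_high=int(n_high[i]), fit=fit, p=float(p[i]), q=float(q[i]),
        ))
    conv = np.asarray(res["converged"], dtype=bool)
    if not conv.any():
        raise ValueError("no cutoff produced a converged Cox fit")
    # argmin over converged fits; cuts ascending, so the first minimum is
    # the smaller cutoff on ties
    masked = np.where(conv, p, np.inf)
    best = int(np.argmin(masked))
    sig = significance_call(results[best], alpha=alpha, fdr_max=fdr_max)
    return ScanResult(
        cohort_name=cohort.cohort_name, gene_id=cohort.gene_id,
        results=results, best=best, significant=sig,
        alpha=alpha, fdr_max=fdr_max,
    )


def subgroup_scan(cohort: CohortDataset, stratum: str, level: str,
                  **scan_kwargs) -> ScanResult:
    """Run the scan inside one stratum level (quartile band recomputed there)."""
    if stratum not in cohort.strata:
        raise KeyError(f"unknown stratum {stratum!r}; "
                       f"available: {sorted(cohort.strata)}")
    col = np.asarray(cohort.strata[stratum], dtype=object)
    mask = col == str(level)
    if not mask.any():
        raise ValueError(f"level {level!r} not present in stratum {stratum!r}")
    if mask.sum() < MIN_SCAN_N:
        raise ValueError(
            f"subgroup {stratum!r}={level!r} has only {int(mask.sum())} "
            f"samples; scan requires >= {MIN_SCAN_N}"
        )
    sub = cohort.select(mask)
    sub.cohort_name = f"{cohort.cohort_name}[{stratum}={level}]"
    return scan_cutoffs(sub, **scan_kwargs)


def km_at_best(cohort: CohortDataset, scan: ScanResult):
    """Kaplan–Meier curves of the high/low groups at the selected cutoff."""
    cut = scan.best_result.cutoff
    high = cohort.expr > cut
    km_high = km_estimate(cohort.os_time[high], cohort.os_event[high])
    km_low = km_estimate(cohort.os_time[~high], cohort.os_event[~high])
    return km_high, km_low


def km_curve_frame(curve: KMCurve) -> pd.DataFrame:
    return pd.DataFrame({
        "time": curve.times, "at_risk": curve.at_risk,
        "events": curve.n_events, "survival": curve.survival,
        "se": curve.greenwood_se,
    })
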