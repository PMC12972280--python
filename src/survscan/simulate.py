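"""Synthetic cohorts with the statistical structure the scan assumes.

The generator draws log-normal expression values, labels samples "high"
when expression exceeds the quantile at ``true_cutoff_pct`` (the sharp
latent cutpoint the scan tries to recover), and draws survival times under
proportional hazards: the low group's hazard is ``baseline_hazard`` and the
high group's is ``baseline_hazard * hr`` (exponential by default; a Weibull
shape option keeps the hazard ratio exact). Censoring is an independent
exponential clock capped at an administrative follow-up horizon.

Default condition: n = 200 samples, expression around a mean of ~1000
(matching the mean-1000 scaling of the real-data path), time in months with
a low-group hazard of 0.015/month (median OS near 4 years), censoring rate
0.01/month and a 120-month administrative cap — roughly two thirds of
subjects experience the event. The null model (``hr = 1`` or
``true_cutoff_pct = None``) makes expression pure noise with respect to
survival.

Two Monte-Carlo experiments quantify the scan's operating characteristics:
:func:`type1_error_experiment` measures how often the minimum raw p over
the scan falls below 0.05 under the null (the minimum-p inflation that the
joint p < alpha AND FDR rule is there to tame), and
:func:`recovery_experiment` measures cutoff and hazard-ratio recovery under
a real effect (where minimum-p selection biases the fitted HR away from 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import CohortDataset
from .scan import scan_cutoffs
from .survival import logrank_test
from .tumor_normal import GroupedExpression

DEFAULT_SEED = 20250627


@dataclass
class SimConfig:
    """Parameters of one synthetic cohort."""

    n: int = 200
    true_cutoff_pct: float | None = 0.5   # None => null model
    hr: float = 1.0
    baseline_hazard: float = 0.015        # events per month, low group
    censor_rate: float = 0.01             # censoring events per month
    admin_time: float = 120.0             # administrative follow-up cap
    expr_logmean: float = float(np.log(1000.0))
    expr_logsd: float = 1.0
    weibull_shape: float = 1.0            # 1 => exponential
    effect: str = "threshold"             # or "linear" (misspecification study)
    strata_spec: dict | None = None       # name -> {level: probability}
    seed: int = DEFAULT_SEED

    def __post_init__(self):
        if self.n < 8:
            raise ValueError("n must be >= 8")
        if self.hr <= 0:
            raise ValueError("hr must be > 0")
        if self.baseline_hazard <= 0 or self.censor_rate <= 0:
            raise ValueError("hazard rates must be > 0")
        if self.admin_time <= 0:
            raise ValueError("admin_time must be > 0")
        if self.weibull_shape <= 0:
            raise ValueError("weibull_shape must be > 0")
        if self.true_cutoff_pct is not None and not 0 < self.true_cutoff_pct < 1:
            raise ValueError("true_cutoff_pct must be in (0, 1) or None")
        if self.effect not in ("threshold", "linear"):
            raise ValueError("effect must be 'threshold' or 'linear'")


def _ph_times(rng, cum_hazard_rate, shape):
    """Event times with cumulative hazard H(t) = rate * t**shape."""
    u = rng.random(cum_hazard_rate.size)
    return (-np.log(u) / cum_hazard_rate) ** (1.0 / shape)


def simulate_cohort(cfg: SimConfig) -> CohortDataset:
    """Draw one cohort; bit-reproducible for a fixed seed."""
    rng = np.random.default_rng(cfg.seed)
    expr = rng.lognormal(cfg.expr_logmean, cfg.expr_logsd, cfg.n)
    if cfg.effect == "linear":
        z = (np.log(expr) - cfg.expr_logmean) / cfg.expr_logsd
        rel_hazard = np.exp(np.log(cfg.hr) * z)
    elif cfg.true_cutoff_pct is None:
        rel_hazard = np.ones(cfg.n)
    else:
        cut = np.quantile(expr, cfg.true_cutoff_pct)
        rel_hazard = np.where(expr > cut, cfg.hr, 1.0)
    surv = _ph_times(rng, cfg.baseline_hazard * rel_hazard, cfg.weibull_shape)
    cens = np.minimum(rng.exponential(1.0 / cfg.censor_rate, cfg.n),
                      cfg.admin_time)
    os_time = np.minimum(surv, cens)
    os_event = (surv <= cens).astype(int)
    strata = {}
    if cfg.strata_spec:
        for name, levels in cfg.strata_spec.items():
            labels = list(levels)
            probs = np.asarray([levels[k] for k in labels], dtype=float)
            probs = probs / probs.sum()
            strata[name] = rng.choice(np.asarray(labels, dtype=object),
                                      size=cfg.n, p=probs)
    return CohortDataset(
        sample_ids=[f"S{i + 1:05d}" for i in range(cfg.n)],
        expr=expr, os_time=os_time, os_event=os_event, strata=strata,
        cohort_name="synthetic", gene_id="GENE",
    )


def _child_seeds(seed: int, reps: int) -> np.ndarray:
    # independent per-replicate streams, kept below 2**31
    return np.random.SeedSequence(seed).generate_state(reps) % (2 ** 31 - 1)


@dataclass
class Type1ErrorResult:
    raw_rate: float        # fraction of replicates with min raw p < alpha
    corrected_rate: float  # fraction called significant by the joint rule
    reps: int
    alpha: float


def type1_error_experiment(reps: int, cfg: SimConfig,
                           seed: int = DEFAULT_SEED,
                           alpha: float = 0.05) -> Type1ErrorResult:
    """Null-model false-positive rates of the scan, raw vs corrected."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if cfg.hr != 1.0 and cfg.true_cutoff_pct is not None:
        raise ValueError("type-1-error experiment requires a null config (hr = 1)")
    raw = corrected = 0
    for s in _child_seeds(seed, reps):
        scan = scan_cutoffs(simulate_cohort(replace(cfg, seed=int(s))))
        if scan.best_result.p < alpha:
            raw += 1
        if scan.significant:
            corrected += 1
    return Type1ErrorResult(raw_rate=raw / reps, corrected_rate=corrected / reps,
                            reps=reps, alpha=alpha)


@dataclass
class RecoveryResult:
    median_abs_pct_error: float   # |recovered cutoff percentile - truth|, median
    hr_sign_correct_rate: float   # fraction with fitted HR on the true side of 1
    median_hr_estimate: float
    reps: int


def recovery_experiment(reps: int, cfg: SimConfig,
                        seed: int = DEFAULT_SEED) -> RecoveryResult:
    """How well the scan recovers a true sharp cutpoint and its hazard ratio."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if cfg.true_cutoff_pct is None:
        raise ValueError("recovery experiment requires a true cutoff")
    pct_err, sign_ok, hrs = [], [], []
    for s in _child_seeds(seed, reps):
        cohort = simulate_cohort(replace(cfg, seed=int(s)))
        best = scan_cutoffs(cohort).best_result
        pct = float(np.mean(cohort.expr <= best.cutoff))
        pct_err.append(abs(pct - cfg.true_cutoff_pct))
        sign_ok.append((best.fit.hr > 1.0) == (cfg.hr > 1.0))
        hrs.append(best.fit.hr)
    return RecoveryResult(
        median_abs_pct_error=float(np.median(pct_err)),
        hr_sign_correct_rate=float(np.mean(sign_ok)),
        median_hr_estimate=float(np.median(hrs)),
        reps=reps,
    )


def median_cutoff_logrank_p(cohort: CohortDataset) -> float:
    """Log-rank p at the single median cutoff (the no-scan comparator)."""
    group = (cohort.expr > np.median(cohort.expr)).astype(int)
    _, p = logrank_test(cohort.os_time, cohort.os_event, group)
    return p


def simulate_tumor_normal(n_tumor: int, n_normal: int, log_shift: float,
                          seed: int = DEFAULT_SEED,
                          logmean: float = float(np.log(1000.0)),
                          logsd: float = 1.0) -> GroupedExpression:
    """Log-normal tumor/normal groups; tumor log-mean shifted by ``log_shift``."""
    if n_tumor < 1 or n_normal < 1:
        raise ValueError("group sizes must be >= 1")
    rng = np.random.default_rng(seed)
    tumor = rng.lognormal(logmean + log_shift, logsd, n_tumor)
    normal = rng.lognormal(logmean, logsd, n_normal)
    return GroupedExpression(tumor_values=tumor, normal_values=normal)
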