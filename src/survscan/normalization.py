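"""Count normalization, per-sample rescaling and sample-level QC.

RNA-seq counts are depth-corrected with median-of-ratios size factors
(the size-factor step of the DESeq normalization: each sample's factor is
the median, over genes, of the ratio of its count to the gene's geometric
mean across samples). A second scaling step then sets every sample's mean
expression to a fixed target (1000 by default) so that samples from
different batches are directly comparable.

Array samples additionally pass duplicate removal (identical expression
vectors keep only their first occurrence) and an outlier filter that keeps
a sample only if each of its QC metrics lies inside the central 95% band
(mean +/- 1.96 SD) of that metric over all samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass
class SizeFactors:
    sample_ids: list
    factors: np.ndarray

    def __post_init__(self):
        self.factors = np.asarray(self.factors, dtype=float)
        if self.factors.shape != (len(self.sample_ids),):
            raise ValueError("one factor per sample required")
        if np.any(~np.isfinite(self.factors)) or np.any(self.factors <= 0):
            raise ValueError("size factors must be finite and > 0")


@dataclass
class QCReport:
    """Per-sample QC metric values, per-metric bounds and the keep decision."""

    sample_ids: list
    metric_names: list
    values: np.ndarray          # samples x metrics
    bounds: np.ndarray          # metrics x 2 (low, high)
    kept: np.ndarray            # bool per sample

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.sample_ids,
                          columns=self.metric_names)
        df.insert(0, "kept", self.kept.astype(int))
        df.index.name = "sample_id"
        return df

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for name, (lo, hi) in zip(self.metric_names, self.bounds):
                fh.write(f"# bounds\t{name}\t{lo!r}\t{hi!r}\n")
            self.to_frame().to_csv(fh, sep="\t")


def deseq_size_factors(counts: ExpressionMatrix) -> SizeFactors:
    """Median-of-ratios size factors.

    Geometric means are computed in log space over genes with strictly
    positive counts in every sample; genes touching zero are skipped, the
    strict convention of the reference count-normalization method.
    """
    if counts.mode != "counts":
        raise ValueError(f"size factors require counts mode, got {counts.mode!r}")
    v = counts.values
    allpos = np.all(v > 0, axis=1)
    if not allpos.any():
        raise ValueError("no gene with positive counts in all samples; "
                         "cannot compute size factors")
    logv = np.log(v[allpos])
    log_geomean = logv.mean(axis=1)
    # ratio of sample count to gene geometric mean, median over usable genes
    factors = np.exp(np.median(logv - log_geomean[:, None], axis=0))
    return SizeFactors(sample_ids=list(counts.sample_ids), factors=factors)


def apply_size_factors(counts: ExpressionMatrix, sf: SizeFactors) -> ExpressionMatrix:
    if list(counts.sample_ids) != list(sf.sample_ids):
        if set(counts.sample_ids) != set(sf.sample_ids):
            raise ValueError("sample sets of matrix and size factors differ")
        order = [sf.sample_ids.index(s) for s in counts.sample_ids]
        factors = sf.factors[order]
    else:
        factors = sf.factors
    return ExpressionMatrix(
        gene_ids=list(counts.gene_ids),
        sample_ids=list(counts.sample_ids),
        values=counts.values / factors[None, :],
        mode="normalized",
    )


def scale_to_target_mean(m: ExpressionMatrix, target: float = 1000.0) -> ExpressionMatrix:
    """Rescale each sample so its mean expression over genes equals ``target``."""
    if target <= 0:
        raise ValueError("target mean must be positive")
    means = m.values.mean(axis=0)
    bad = np.flatnonzero(means <= 0)
    if bad.size:
        raise ValueError(
            f"sample {m.sample_ids[bad[0]]!r} has non-positive mean expression"
        )
    return ExpressionMatrix(
        gene_ids=list(m.gene_ids),
        sample_ids=list(m.sample_ids),
        values=m.values * (target / means)[None, :],
        mode="normalized",
    )


def detect_duplicates(m: ExpressionMatrix, rel_tol: float = 0.0):
    """Find samples with identical expression vectors.

    Returns ``(kept, removed)`` sample-id lists; within each group of equal
    columns only the first (in column order) is kept. Equality is exact by
    default; ``rel_tol`` > 0 rounds to that relative resolution first.
    """
    v = m.values
    if rel_tol > 0:
        scale = np.maximum(np.abs(v).max(axis=0), 1.0)
        v = np.round(v / scale / rel_tol) * rel_tol * scale
    seen = {}
    kept, removed = [], []
    for j, sid in enumerate(m.sample_ids):
        key = v[:, j].tobytes()
        if key in seen:
            removed.append(sid)
            log.info("detect_duplicates: %s identical to %s; removed",
                     sid, seen[key])
        else:
            seen[key] = sid
            kept.append(sid)
    return kept, removed


def qc_outlier_filter(metrics: pd.DataFrame, coverage: float = 0.95) -> QCReport:
    """Keep samples whose every metric lies inside the central ``coverage`` band.

    Bounds per metric are mean +/- z*SD in a single pass, with z the normal
    quantile enclosing ``coverage`` central mass (1.95996 at 0.95). A sample
    failing any metric is excluded. Zero-variance metrics cannot exclude
    anyone (bounds collapse to the constant; logged).
    """
    if not 0 < coverage < 1:
        raise ValueError("coverage must be in (0, 1)")
    if metrics.shape[0] < 3:
        raise ValueError("QC filter requires at least 3 samples")
    values = metrics.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("QC metrics must be finite")
    z = stats.norm.ppf(0.5 + coverage / 2.0)
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    lo, hi = mean - z * sd, mean + z * sd
    for k in np.flatnonzero(sd == 0):
        log.info("qc_outlier_filter: metric %r has zero variance; "
                 "all samples kept for it", metrics.columns[k])
    within = (values >= lo[None, :]) & (values <= hi[None, :])
    within[:, sd == 0] = True
    kept = within.all(axis=1)
    return QCReport(
        sample_ids=[str(s) for s in metrics.index],
        metric_names=[str(c) for c in metrics.columns],
        values=values,
        bounds=np.column_stack([lo, hi]),
        kept=kept,
    )


def normalize_counts_pipeline(counts: ExpressionMatrix,
                              target: float = 1000.0) -> ExpressionMatrix:
    """Median-of-ratios depth correction followed by mean-``target`` scaling."""
    return scale_to_target_mean(apply_size_factors(counts, deseq_size_factors(counts)),
                                target)
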