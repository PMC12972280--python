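"""Reading, validation and joining of expression matrices and clinical tables.

Expression matrices are delimited text (TSV or CSV, chosen by file
extension), first column gene identifiers, header row sample identifiers.
Clinical tables carry one row per sample with overall-survival time, the
event indicator (1 = death observed, 0 = censored) and any number of extra
columns, which become stratification covariates.

Sample identifiers are matched by exact string equality; no barcode
truncation or other canonicalisation is applied implicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MODES = ("counts", "intensity", "normalized")

#: explicit category used for absent stratification values; such samples are
#: excluded from that stratum's subgroup analyses but kept in the overall one
MISSING_CATEGORY = "missing"


def _sep_for(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix with axis labels.

    ``mode`` records what the values are: raw RNA-seq ``counts``, array
    ``intensity`` values, or ``normalized`` output of the normalization
    pipeline. Counts must be non-negative; all values must be finite.
    """

    gene_ids: list
    sample_ids: list
    values: np.ndarray
    mode: str = "counts"

    def __post_init__(self):
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.values.size == 0:
            raise ValueError("empty expression matrix")
        for name, labels in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dupes = pd.Index(labels)[pd.Index(labels).duplicated()].unique().tolist()
            if dupes:
                raise ValueError(f"duplicate {name} identifiers: {dupes}")
        if not np.all(np.isfinite(self.values)):
            g, s = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        if self.mode == "counts" and np.any(self.values < 0):
            g, s = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative count at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def gene_values(self, gene_id: str) -> np.ndarray:
        if gene_id not in self.gene_ids:
            raise KeyError(f"gene {gene_id!r} not present in expression matrix")
        return self.values[self.gene_ids.index(gene_id)]

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(self.gene_ids, list(sample_ids),
                                self.values[:, idx], self.mode)


@dataclass
class ClinicalTable:
    """Per-sample overall-survival records plus optional strata columns."""

    sample_ids: list
    os_time: np.ndarray
    os_event: np.ndarray
    strata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.os_time = np.asarray(self.os_time, dtype=float)
        self.os_event = np.asarray(self.os_event)
        n = len(self.sample_ids)
        if len(set(self.sample_ids)) != n:
            dupes = pd.Index(self.sample_ids)
            raise ValueError(
                f"duplicate sample identifiers: {dupes[dupes.duplicated()].unique().tolist()}"
            )
        if self.os_time.shape != (n,) or self.os_event.shape != (n,):
            raise ValueError("os_time/os_event length must match sample_ids")
        if np.any(~np.isfinite(self.os_time)) or np.any(self.os_time < 0):
            raise ValueError("os_time must be finite and >= 0")
        if not np.isin(self.os_event, [0, 1]).all():
            bad = sorted(set(np.asarray(self.os_event).tolist()) - {0, 1})
            raise ValueError(f"os_event must be 0 or 1; found {bad}")
        self.os_event = self.os_event.astype(int)
        for name, col in self.strata.items():
            col = np.asarray(col, dtype=object)
            if col.shape != (n,):
                raise ValueError(f"stratum {name!r} length mismatch")
            col = np.where(pd.isna(col), MISSING_CATEGORY, col.astype(str))
            self.strata[name] = col.astype(object)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class CohortDataset:
    """One gene's expression joined with survival outcomes for one cohort."""

    sample_ids: list
    expr: np.ndarray
    os_time: np.ndarray
    os_event: np.ndarray
    strata: dict = field(default_factory=dict)
    cohort_name: str = ""
    gene_id: str = ""

    def __post_init__(self):
        self.expr = np.asarray(self.expr, dtype=float)
        self.os_time = np.asarray(self.os_time, dtype=float)
        self.os_event = np.asarray(self.os_event, dtype=int)
        n = len(self.sample_ids)
        if n < 1:
            raise ValueError("cohort must contain at least one sample")
        for arr in (self.expr, self.os_time, self.os_event):
            if arr.shape != (n,):
                raise ValueError("all cohort arrays must have equal length")
        if not np.all(np.isfinite(self.expr)):
            raise ValueError("expression values must be finite")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def n_events(self) -> int:
        return int(self.os_event.sum())

    def select(self, mask) -> "CohortDataset":
        mask = np.asarray(mask, dtype=bool)
        return CohortDataset(
            sample_ids=[s for s, m in zip(self.sample_ids, mask) if m],
            expr=self.expr[mask],
            os_time=self.os_time[mask],
            os_event=self.os_event[mask],
            strata={k: v[mask] for k, v in self.strata.items()},
            cohort_name=self.cohort_name,
            gene_id=self.gene_id,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"sample_id": self.sample_ids, "expr": self.expr,
             "os_time": self.os_time, "os_event": self.os_event}
        )
        for k, v in self.strata.items():
            df[k] = v
        return df


def read_expression_matrix(path, mode: str = "counts") -> ExpressionMatrix:
    """Read a genes x samples matrix from TSV/CSV text.

    The first column holds gene identifiers, the header row sample
    identifiers. Any cell that does not parse as a finite decimal number
    (including ``NA``) is an error naming the offending gene and sample.
    """
    raw = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise ValueError(f"empty expression matrix in {path}")
    dupes = raw.index[raw.index.duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate gene identifiers in {path}: {dupes}")
    # numpy's string->float conversion is correctly rounded (pandas'
    # to_numeric is not), so full-precision round trips stay exact
    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        try:
            values[:, j] = raw[col].to_numpy(dtype=float)
        except (ValueError, TypeError):
            for i, cell in enumerate(raw[col]):
                try:
                    float(cell)
                except (ValueError, TypeError):
                    raise ValueError(
                        f"malformed numeric cell at gene {raw.index[i]!r}, "
                        f"sample {col!r} in {path}: {cell!r}"
                    ) from None
            raise
    bad = np.argwhere(~np.isfinite(values))
    if bad.size:
        g, s = bad[0]
        raise ValueError(
            f"malformed numeric cell at gene {raw.index[g]!r}, "
            f"sample {raw.columns[s]!r} in {path}: {raw.iloc[g, s]!r}"
        )
    return ExpressionMatrix(
        gene_ids=raw.index.tolist(),
        sample_ids=[str(c) for c in raw.columns],
        values=values,
        mode=mode,
    )


def write_expression_matrix(m: ExpressionMatrix, path) -> None:
    df = m.to_frame()
    df.index.name = "gene_id"
    # 17 significant digits guarantee an exact float64 round trip
    df.to_csv(path, sep=_sep_for(path), float_format="%.17g")


REQUIRED_CLINICAL = ("sample_id", "os_time", "os_event")


def read_clinical_table(path) -> ClinicalTable:
    """Read a clinical table; extra columns become strata covariates."""
    df = pd.read_csv(path, sep=_sep_for(path), dtype={"sample_id": str})
    missing = [c for c in REQUIRED_CLINICAL if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table {path} missing required columns {missing}")
    strata_cols = [c for c in df.columns if c not in REQUIRED_CLINICAL]
    return ClinicalTable(
        sample_ids=df["sample_id"].tolist(),
        os_time=pd.to_numeric(df["os_time"], errors="raise").to_numpy(),
        os_event=pd.to_numeric(df["os_event"], errors="raise").to_numpy(),
        strata={c: df[c].to_numpy(dtype=object) for c in strata_cols},
    )


def write_clinical_table(clin: ClinicalTable, path) -> None:
    df = pd.DataFrame(
        {"sample_id": clin.sample_ids, "os_time": clin.os_time,
         "os_event": clin.os_event}
    )
    for k, v in clin.strata.items():
        df[k] = v
    df.to_csv(path, sep=_sep_for(path), index=False)


def join_cohort(expr: ExpressionMatrix, clin: ClinicalTable, gene_id: str,
                cohort_name: str) -> CohortDataset:
    """Inner-join one gene's expression with the clinical table.

    Samples present on only one side are dropped (count logged). The output
    order is the clinical-table order restricted to the intersection, which
    makes the join deterministic regardless of expression column order.
    """
    if gene_id not in expr.gene_ids:
        raise KeyError(f"gene {gene_id!r} not present in expression matrix")
    expr_pos = {s: i for i, s in enumerate(expr.sample_ids)}
    keep = [i for i, s in enumerate(clin.sample_ids) if s in expr_pos]
    if not keep:
        raise ValueError(
            f"no overlapping samples between expression matrix and clinical "
            f"table for cohort {cohort_name!r}"
        )
    n_dropped = (clin.n_samples - len(keep)) + (expr.n_samples - len(keep))
    if n_dropped:
        log.info("join_cohort %s: dropped %d unmatched sample(s)",
                 cohort_name, n_dropped)
    gene_row = expr.values[expr.gene_ids.index(gene_id)]
    sample_ids = [clin.sample_ids[i] for i in keep]
    keep = np.asarray(keep, dtype=int)
    return CohortDataset(
        sample_ids=sample_ids,
        expr=gene_row[[expr_pos[s] for s in sample_ids]],
        os_time=clin.os_time[keep],
        os_event=clin.os_event[keep],
        strata={k: v[keep] for k, v in clin.strata.items()},
        cohort_name=cohort_name,
        gene_id=gene_id,
    )


def filter_cohorts(cohorts, source: str):
    """Apply the cohort-size inclusion rule.

    RNA-seq cohorts are kept only with more than 100 samples; array cohorts
    need at least 30. Dropped cohorts are logged.
    """
    if source not in ("rnaseq", "array"):
        raise ValueError("source must be 'rnaseq' or 'array'")
    kept = []
    for c in cohorts:
        ok = c.n > 100 if source == "rnaseq" else c.n >= 30
        if ok:
            kept.append(c)
        else:
            log.info("filter_cohorts: dropped %s (n=%d, source=%s)",
                     c.cohort_name, c.n, source)
    return kept
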