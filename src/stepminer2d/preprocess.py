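"""Cohort-level cleaning rules applied before any pair is fitted.

Matrices are plain pandas DataFrames, features on the rows and samples on
the columns (methylation: CpG sites x samples, beta in [0,1] with NaN for
missing; expression: genes x samples, non-negative).  Sample columns of the
two matrices must already be intersected and identically ordered (see
:func:`stepminer2d.io.intersect_samples`).

Site filters, applied in order and each with a strict inequality:

1. drop CpG sites whose annotated gene is absent from the expression
   matrix (or that have no annotation at all);
2. drop sites with a missing-data fraction greater than 1%;
3. drop sites whose beta value is below 0.01 in more than 95% of samples
   (essentially-unmethylated probes carry no dichotomizable signal).

Expression is made log-scale by replacing each gene's zero entries with
the smallest positive value of that gene across samples, then taking
logarithms (base 2 by default; the rank-based bivariate fit is invariant
to the base, only reported thresholds change).  Genes that are zero in
every sample are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError
from .step2d import PairedSeries

__all__ = ["FilterReport", "filter_sites", "transform_expression", "build_pairs"]

MISSING_FRACTION_MAX = 0.01
NEAR_ZERO_BETA = 0.01
NEAR_ZERO_SAMPLE_FRACTION = 0.95


@dataclass
class FilterReport:
    """Per-rule bookkeeping for the site filters and pair construction."""

    n_input_sites: int = 0
    removed_gene_absent: list = field(default_factory=list)
    removed_missing: list = field(default_factory=list)
    removed_near_zero: list = field(default_factory=list)
    dropped_all_zero_genes: list = field(default_factory=list)
    excluded_small_pairs: list = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        removed = (
            len(self.removed_gene_absent) + len(self.removed_missing) + len(self.removed_near_zero)
        )
        return self.n_input_sites - removed

    def summary(self) -> str:
        return "\n".join(
            [
                f"sites in                      {self.n_input_sites}",
                f"removed: gene absent/unannot. {len(self.removed_gene_absent)}",
                f"removed: >1% missing          {len(self.removed_missing)}",
                f"removed: beta<0.01 in >95%    {len(self.removed_near_zero)}",
                f"sites retained                {self.n_retained}",
                f"all-zero genes dropped        {len(self.dropped_all_zero_genes)}",
                f"pairs excluded (<4 samples)   {len(self.excluded_small_pairs)}",
            ]
        )


def _check_annotation(annot: pd.DataFrame) -> pd.Series:
    if annot.shape[1] < 2:
        raise InvalidInputError("annotation needs (cpg_id, gene_id) columns")
    cpg, gene = annot.iloc[:, 0].astype(str), annot.iloc[:, 1].astype(str)
    if cpg.duplicated().any():
        dup = cpg[cpg.duplicated()].iloc[0]
        raise InvalidInputError(f"CpG {dup!r} annotated to more than one gene")
    return pd.Series(gene.values, index=cpg.values)


def filter_sites(
    meth: pd.DataFrame,
    expr: pd.DataFrame,
    annot: pd.DataFrame,
    report: FilterReport | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the three site filters; returns the filtered matrix and a report."""
    if list(meth.columns) != list(expr.columns):
        raise InvalidInputError("sample columns must be intersected and identically ordered first")
    report = report or FilterReport()
    report.n_input_sites = meth.shape[0]
    cpg_to_gene = _check_annotation(annot)

    gene_of = cpg_to_gene.reindex(meth.index)
    absent = gene_of.isna() | ~gene_of.isin(expr.index)
    report.removed_gene_absent = meth.index[absent].tolist()
    kept = meth.loc[~absent]

    missing_frac = kept.isna().mean(axis=1)
    rule2 = missing_frac > MISSING_FRACTION_MAX
    report.removed_missing = kept.index[rule2].tolist()
    kept = kept.loc[~rule2]

    near_zero_frac = (kept < NEAR_ZERO_BETA).mean(axis=1)  # NaN compares False: counts as not-near-zero
    rule3 = near_zero_frac > NEAR_ZERO_SAMPLE_FRACTION
    report.removed_near_zero = kept.index[rule3].tolist()
    kept = kept.loc[~rule3]
    return kept, report


def transform_expression(
    expr: pd.DataFrame, log_base: float = 2.0, report: FilterReport | None = None
) -> tuple[pd.DataFrame, FilterReport]:
    """Zero-replacement by per-gene minimum positive value, then log transform."""
    report = report or FilterReport()
    values = expr.to_numpy(dtype=float)
    if np.nanmin(values) < 0:
        raise InvalidInputError("expression matrix contains negative values")
    all_zero = ~(values > 0).any(axis=1)
    report.dropped_all_zero_genes = expr.index[all_zero].tolist()
    expr = expr.loc[~all_zero]
    values = values[~all_zero]
    with np.errstate(invalid="ignore"):
        min_pos = np.nanmin(np.where(values > 0, values, np.nan), axis=1)
    filled = np.where(values == 0, min_pos[:, None], values)
    logged = np.log(filled) / np.log(log_base)
    return pd.DataFrame(logged, index=expr.index, columns=expr.columns), report


def build_pairs(
    meth: pd.DataFrame,
    expr_log: pd.DataFrame,
    annot: pd.DataFrame,
    report: FilterReport | None = None,
    min_samples: int = 4,
) -> tuple[list[PairedSeries], FilterReport]:
    """One :class:`PairedSeries` per retained CpG site.

    ``x`` is the annotated gene's log expression, ``y`` the site's beta
    values; samples with a missing beta (or expression) value are dropped
    from that pair only.  Pairs left with fewer than ``min_samples``
    samples are excluded and logged.
    """
    report = report or FilterReport()
    cpg_to_gene = _check_annotation(annot)
    pairs: list[PairedSeries] = []
    samples = np.asarray(meth.columns)
    for cpg in meth.index:
        gene = cpg_to_gene.get(cpg)
        if gene is None or gene not in expr_log.index:
            raise InvalidInputError(f"site {cpg!r} not annotated to a gene in the expression matrix")
        y = meth.loc[cpg].to_numpy(dtype=float)
        x = expr_log.loc[gene].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < min_samples:
            report.excluded_small_pairs.append(cpg)
            continue
        pairs.append(
            PairedSeries(x=x[ok], y=y[ok], ids=tuple(samples[ok].tolist()), x_id=str(gene), y_id=str(cpg))
        )
    return pairs, report
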