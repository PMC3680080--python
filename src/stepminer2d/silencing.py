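"""One-sided hypergeometric test for methylation-driven gene silencing.

Once a CpG/gene pair has been dichotomized — methylation into
methylated/unmethylated, expression into high/low — the data reduce to
counts in four quadrants.  Under the silencing hypothesis ("methylated
implies low expression") the methylated-AND-high-expression quadrant should
be depleted.  With N samples, R methylated (right margin), U
high-expression (upper margin) and K in the upper-right quadrant, the count
k in that quadrant under independence follows a hypergeometric law
conditional on the margins,

    p(k) = C(U, k) * C(N-U, R-k) / C(N, R),

and the one-sided p-value is P(k <= K) = sum_{k=0}^{K} p(k).  Depletion of
the upper-right quadrant drives the p-value down.  Fisher-exact and
chi-square tests on the same table are two-sided in nature and do not
target this direction, which is why a directional test is used.

A complementary direction filter discards tables where the upper-right
count exceeds the lower-left count by more than a fraction (default 10%) of
N — configurations that contradict silencing outright, whatever the
p-value.  Multiple testing over many pairs is controlled by Bonferroni.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .exceptions import InvalidInputError
from .step2d import PairedSeries, StepFit2D, StepMiner2D

__all__ = [
    "QuadrantCounts",
    "AssociationResult",
    "quadrant_counts",
    "hypergeom_pvalue",
    "direction_filter",
    "bonferroni_significant",
    "test_pair",
]


@dataclass(frozen=True)
class QuadrantCounts:
    """2x2 table of dichotomized sample counts.

    Left/right = unmethylated/methylated; upper/lower = high/low
    expression.  Derived margins: ``R`` methylated, ``U`` high expression,
    ``K`` the upper-right (methylated and high) count under test.
    """

    n_total: int
    upper_left: int
    upper_right: int
    lower_left: int
    lower_right: int

    def __post_init__(self):
        quads = (self.upper_left, self.upper_right, self.lower_left, self.lower_right)
        if any(q < 0 for q in quads):
            raise InvalidInputError("quadrant counts must be non-negative")
        if sum(quads) != self.n_total:
            raise InvalidInputError(
                f"quadrant counts sum to {sum(quads)}, expected n_total={self.n_total}"
            )

    @property
    def R(self) -> int:
        return self.upper_right + self.lower_right

    @property
    def U(self) -> int:
        return self.upper_left + self.upper_right

    @property
    def K(self) -> int:
        return self.upper_right


def quadrant_counts(x, y, threshold_x: float, threshold_y: float) -> QuadrantCounts:
    """Count samples per quadrant.

    ``x`` is expression (upper = x > threshold_x), ``y`` methylation
    (right = y > threshold_y); values exactly on a threshold fall on the
    low/unmethylated side.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or x.size != y.size:
        raise InvalidInputError("x and y must be non-empty and equal-length")
    if not (np.isfinite(threshold_x) and np.isfinite(threshold_y)):
        raise InvalidInputError("thresholds must be finite")
    if np.isnan(x).any() or np.isnan(y).any():
        raise InvalidInputError("pairs must be complete (no NaN) when counting quadrants")
    high = x > threshold_x
    meth = y > threshold_y
    return QuadrantCounts(
        n_total=int(x.size),
        upper_left=int(np.sum(high & ~meth)),
        upper_right=int(np.sum(high & meth)),
        lower_left=int(np.sum(~high & ~meth)),
        lower_right=int(np.sum(~high & meth)),
    )


def _log_comb(n, k):
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def hypergeom_pvalue(counts: QuadrantCounts) -> float:
    """P(k <= K) under the margin-conditional hypergeometric null.

    The sum runs over the support [max(0, R+U-N), K]; terms are
    accumulated in log space (log-gamma binomials + rescaled exp sum), so
    the tail stays accurate well beyond N = 1e5.  Equals 1 exactly when
    K = min(R, U), i.e. the table carries no depletion evidence at all.
    """
    n, r, u, k = counts.n_total, counts.R, counts.U, counts.K
    if r > n or u > n:
        raise InvalidInputError("margins exceed the total count")
    if k >= min(r, u):
        return 1.0
    lo = max(0, r + u - n)
    ks = np.arange(lo, k + 1, dtype=float)
    if ks.size == 0:
        return 0.0
    log_terms = _log_comb(u, ks) + _log_comb(n - u, r - ks) - _log_comb(n, r)
    m = log_terms.max()
    return float(min(1.0, np.exp(m) * np.exp(log_terms - m).sum()))


def direction_filter(counts: QuadrantCounts, fraction: float = 0.1) -> bool:
    """True (= exclude the pair) iff UR - LL exceeds ``fraction`` of N, strictly.

    An excess of methylated-and-high over unmethylated-and-low samples of
    this size is flatly incompatible with methylation silencing the gene.
    """
    if not 0.0 <= fraction <= 1.0:
        raise InvalidInputError("fraction must lie in [0, 1]")
    return (counts.upper_right - counts.lower_left) > fraction * counts.n_total


def bonferroni_significant(p_values, alpha: float = 0.01) -> np.ndarray:
    """Boolean flags: p_i < alpha / m, with m the number of tests submitted."""
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        raise InvalidInputError("no p-values supplied")
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise InvalidInputError("p-values must lie in [0, 1]")
    return p < alpha / p.size


@dataclass(frozen=True)
class AssociationResult:
    """Outcome of the silencing test for one (CpG, gene) pair in one cohort slice.

    ``group_label`` is ``"pan"`` for the pooled test or the group's name;
    ``testable`` is False when the slice is too small to test (p-value is
    then NaN).  ``significant`` is filled in only after a multiple-testing
    pass over the whole screen (None until then).
    """

    cpg_id: str
    gene_id: str
    group_label: str
    threshold_x: float
    threshold_y: float
    counts: QuadrantCounts | None
    p_value: float
    direction_excluded: bool
    testable: bool = True
    significant: bool | None = None

    def with_significance(self, cutoff: float) -> "AssociationResult":
        sig = self.testable and not self.direction_excluded and self.p_value < cutoff
        return dataclasses.replace(self, significant=bool(sig))


def _slice_result(x, y, thr_x, thr_y, cpg_id, gene_id, label, fraction) -> AssociationResult:
    if x.size < 2:
        return AssociationResult(
            cpg_id=cpg_id, gene_id=gene_id, group_label=label,
            threshold_x=thr_x, threshold_y=thr_y, counts=None,
            p_value=float("nan"), direction_excluded=False, testable=False,
        )
    counts = quadrant_counts(x, y, thr_x, thr_y)
    return AssociationResult(
        cpg_id=cpg_id, gene_id=gene_id, group_label=label,
        threshold_x=thr_x, threshold_y=thr_y, counts=counts,
        p_value=hypergeom_pvalue(counts),
        direction_excluded=direction_filter(counts, fraction),
    )


def test_pair(
    pairs: PairedSeries,
    fit: StepFit2D,
    groups=None,
    *,
    cpg_id: str | None = None,
    gene_id: str | None = None,
    direction_fraction: float = 0.1,
    refit_per_group: bool = False,
    grid_size: int = 50,
) -> list[AssociationResult]:
    """Silencing test for one pair: pan-cohort, plus one result per group.

    Per-group tests reuse the pan-cohort thresholds by default
    (``refit_per_group=False``); with refitting, each group gets its own
    bivariate fit, and groups where that fit is impossible (degenerate or
    too small) are marked untestable.
    """
    if fit.threshold_x is None or fit.threshold_y is None:
        raise InvalidInputError("fit carries no data-scale thresholds")
    cpg = cpg_id if cpg_id is not None else (pairs.y_id or "cpg")
    gene = gene_id if gene_id is not None else (pairs.x_id or "gene")
    results = [
        _slice_result(pairs.x, pairs.y, fit.threshold_x, fit.threshold_y,
                      cpg, gene, "pan", direction_fraction)
    ]
    if groups is None:
        return results
    groups = np.asarray(groups)
    if groups.size != pairs.n:
        raise InvalidInputError("group labels must align with the paired samples")
    for label in sorted(set(groups.tolist()), key=str):
        sel = groups == label
        gx, gy = pairs.x[sel], pairs.y[sel]
        thr_x, thr_y = fit.threshold_x, fit.threshold_y
        if refit_per_group:
            try:
                gfit = StepMiner2D(gx, gy).fit(grid_size=min(grid_size, max(2, gx.size)))
                if gfit.threshold_x is None or gfit.threshold_y is None:
                    raise InvalidInputError("no thresholds in group refit")
                thr_x, thr_y = gfit.threshold_x, gfit.threshold_y
            except ValueError:  # degenerate or too-small group slice
                results.append(AssociationResult(
                    cpg_id=cpg, gene_id=gene, group_label=str(label),
                    threshold_x=float("nan"), threshold_y=float("nan"), counts=None,
                    p_value=float("nan"), direction_excluded=False, testable=False,
                ))
                continue
        results.append(
            _slice_result(gx, gy, thr_x, thr_y, cpg, gene, str(label), direction_fraction)
        )
    return results
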