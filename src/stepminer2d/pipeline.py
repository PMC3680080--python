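"""End-to-end silencing screen over a methylation/expression cohort.

:class:`SilencingScreen` is the top-level model object: built from the
matrix triple (methylation, expression, annotation) plus optional group
labels, its :meth:`~SilencingScreen.fit` runs

    intersect samples -> site filters -> expression log transform ->
    per-pair bivariate step fit -> silencing tests (pan + per group) ->
    Bonferroni over all submitted pairs

and returns a :class:`SilencingResults` carrying one
:class:`~stepminer2d.silencing.AssociationResult` per (pair, group slice),
a tidy results frame, and the filter/intersection reports.  The whole run
is a pure function of (inputs, config).

Bonferroni uses m = the number of pairs submitted to the screen —
direction-filtered pairs still count toward m, and each group slice is its
own family of the same m tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import io as smio
from .exceptions import InvalidInputError
from .preprocess import FilterReport, build_pairs, filter_sites, transform_expression
from .silencing import AssociationResult, test_pair
from .step2d import StepMiner2D

__all__ = ["RunConfig", "SilencingScreen", "SilencingResults", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Tunable constants of the screen, defaulting to the standard analysis values."""

    grid_size: int = 50
    alpha: float = 0.01
    direction_fraction: float = 0.1
    log_base: float = 2.0
    per_group_threshold_mode: str = "pan"  # "pan" | "refit"
    seed: int | None = None
    meth_path: str | None = None
    expr_path: str | None = None
    annot_path: str | None = None
    groups_path: str | None = None
    out_path: str | None = None

    def __post_init__(self):
        if self.grid_size < 2:
            raise InvalidInputError("grid_size must be >= 2")
        if not 0.0 < self.alpha < 1.0:
            raise InvalidInputError("alpha must lie in (0, 1)")
        if not 0.0 <= self.direction_fraction <= 1.0:
            raise InvalidInputError("direction_fraction must lie in [0, 1]")
        if self.per_group_threshold_mode not in ("pan", "refit"):
            raise InvalidInputError("per_group_threshold_mode must be 'pan' or 'refit'")


_RESULT_COLUMNS = [
    "cpg_id", "gene_id", "group", "n", "snr", "threshold_expr", "threshold_beta",
    "upper_left", "upper_right", "lower_left", "lower_right",
    "p_value", "direction_excluded", "testable", "significant",
]


@dataclass
class SilencingResults:
    """Results of a fitted screen."""

    results: list[AssociationResult]
    fits: dict
    config: RunConfig
    n_pairs: int
    filter_report: FilterReport
    intersection: smio.IntersectionReport | None = None
    unfit_pairs: list = field(default_factory=list)

    @property
    def bonferroni_cutoff(self) -> float:
        return self.config.alpha / self.n_pairs if self.n_pairs else float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            fit = self.fits.get(r.cpg_id)
            c = r.counts
            rows.append({
                "cpg_id": r.cpg_id,
                "gene_id": r.gene_id,
                "group": r.group_label,
                "n": c.n_total if c else 0,
                "snr": fit.snr if fit else np.nan,
                "threshold_expr": r.threshold_x,
                "threshold_beta": r.threshold_y,
                "upper_left": c.upper_left if c else np.nan,
                "upper_right": c.upper_right if c else np.nan,
                "lower_left": c.lower_left if c else np.nan,
                "lower_right": c.lower_right if c else np.nan,
                "p_value": r.p_value,
                "direction_excluded": r.direction_excluded,
                "testable": r.testable,
                "significant": r.significant,
            })
        return pd.DataFrame(rows, columns=_RESULT_COLUMNS)

    def significant_pairs(self, group: str = "pan") -> list[str]:
        return [r.cpg_id for r in self.results if r.group_label == group and r.significant]

    def summary(self) -> str:
        df = self.to_frame()
        pan = df[df.group == "pan"]
        lines = [
            "Methylation-silencing screen",
            "=" * 44,
            f"  pairs tested            {self.n_pairs}",
            f"  alpha / Bonferroni m    {self.config.alpha} / {self.n_pairs}",
            f"  direction-filtered      {int(pan.direction_excluded.sum())}",
            f"  significant (pan)       {int(pan.significant.fillna(False).sum())}",
        ]
        for g in sorted(set(df.group) - {"pan"}):
            sub = df[df.group == g]
            lines.append(f"  significant ({g:<8})   {int(sub.significant.fillna(False).sum())}")
        return "\n".join(lines)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")


class SilencingScreen:
    """Screen model over a full cohort.

    Parameters
    ----------
    meth, expr : DataFrame
        Methylation (beta) and raw expression matrices, features x samples.
    annot : DataFrame
        Two columns (cpg_id, gene_id).
    groups : Series, optional
        sample id -> group label; enables per-group testing.
    config : RunConfig
    """

    def __init__(self, meth, expr, annot, groups=None, config: RunConfig = RunConfig()):
        self.config = config
        self.meth_raw = meth
        self.expr_raw = expr
        self.annot = annot
        self.groups = groups
        self.intersection = None

    @classmethod
    def from_files(cls, config: RunConfig) -> "SilencingScreen":
        if not (config.meth_path and config.expr_path and config.annot_path):
            raise InvalidInputError("config must provide methylation, expression and annotation paths")
        meth = smio.read_matrix(config.meth_path, "methylation")
        expr = smio.read_matrix(config.expr_path, "expression")
        annot = smio.read_annotation(config.annot_path)
        groups = smio.read_groups(config.groups_path) if config.groups_path else None
        return cls(meth, expr, annot, groups=groups, config=config)

    def fit(self) -> SilencingResults:
        cfg = self.config
        meth, expr, self.intersection = smio.intersect_samples(self.meth_raw, self.expr_raw)
        report = FilterReport()
        meth, report = filter_sites(meth, expr, self.annot, report)
        expr_log, report = transform_expression(expr, log_base=cfg.log_base, report=report)
        # a gene dropped as all-zero may orphan its sites: re-filter against the log matrix
        meth, _ = filter_sites(meth, expr_log, self.annot, FilterReport())
        pairs, report = build_pairs(meth, expr_log, self.annot, report)

        group_arr = None
        if self.groups is not None:
            g = self.groups.reindex(meth.columns)
            if g.isna().any():
                missing = g.index[g.isna()][0]
                raise InvalidInputError(f"sample {missing!r} has no group label")
            group_arr = g

        results: list[AssociationResult] = []
        fits: dict = {}
        unfit = []
        for p in pairs:
            try:
                fit = StepMiner2D.from_pairs(p).fit(grid_size=cfg.grid_size)
            except ValueError as err:
                unfit.append((p.y_id, str(err)))
                continue
            if fit.threshold_x is None or fit.threshold_y is None:
                unfit.append((p.y_id, "thresholds unavailable (too few samples for the grid)"))
                continue
            fits[p.y_id] = fit
            pg = None
            if group_arr is not None:
                pg = group_arr.reindex(list(p.ids)).to_numpy()
            results.extend(
                test_pair(
                    p, fit, groups=pg,
                    cpg_id=p.y_id, gene_id=p.x_id,
                    direction_fraction=cfg.direction_fraction,
                    refit_per_group=(cfg.per_group_threshold_mode == "refit"),
                    grid_size=cfg.grid_size,
                )
            )

        n_pairs = len(fits)
        cutoff = cfg.alpha / n_pairs if n_pairs else float("nan")
        results = [r.with_significance(cutoff) for r in results]
        return SilencingResults(
            results=results,
            fits=fits,
            config=cfg,
            n_pairs=n_pairs,
            filter_report=report,
            intersection=self.intersection,
            unfit_pairs=unfit,
        )


def run_pipeline(config: RunConfig) -> SilencingResults:
    """File-to-file orchestration: read inputs, fit the screen, write the results TSV."""
    screen = SilencingScreen.from_files(config)
    res = screen.fit()
    if config.out_path:
        res.write(config.out_path)
    return res
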