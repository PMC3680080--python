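"""Synthetic cohorts with the statistical structure the method assumes.

The fitting and testing machinery is exercised against generated data whose
ground truth is known by construction.  The generator emulates what the
method sees in a multi-cancer methylation/expression cohort:

* methylation beta values in [0, 1] with a bimodal marginal — a low
  (unmethylated) Beta component and a high (methylated) one;
* expression that is bimodal on the log scale (Gaussian mixture on log2
  units, exponentiated to RPKM-like raw values for the cohort matrices);
* the silencing structure: a methylated sample draws its expression from
  the low mode, an unmethylated sample from the high mode with some
  probability and otherwise from the low mode (unmethylated genes may be
  off for other reasons);
* multi-group cohorts where the methylation-expression association holds
  in every group, in a subset of groups, only through between-group
  composition, or not at all — plus planted targets for each
  preprocessing filter.

Default cohort: 992 samples in five groups of 313/227/208/129/115,
mirroring a five-cancer-type pan-cancer design.  Every generated object
travels with ground-truth labels so oracle tests never re-infer structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError
from .step2d import PairedSeries

__all__ = [
    "Uniform",
    "Gaussian",
    "TwoDelta",
    "BetaMixture",
    "GaussianMixture",
    "SilencingSpec",
    "IndependentSpec",
    "GroupSpec",
    "CohortSpec",
    "Cohort",
    "gen_univariate",
    "gen_pair",
    "gen_cohort",
    "DEFAULT_GROUPS",
]


# ---------------------------------------------------------------- marginals


@dataclass(frozen=True)
class Uniform:
    low: float = 0.0
    high: float = 1.0

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if not self.high > self.low:
            raise InvalidInputError("uniform needs high > low")
        return rng.uniform(self.low, self.high, n)


@dataclass(frozen=True)
class Gaussian:
    mu: float = 0.0
    sigma: float = 1.0

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.sigma <= 0:
            raise InvalidInputError("gaussian needs sigma > 0")
        return rng.normal(self.mu, self.sigma, n)


@dataclass(frozen=True)
class TwoDelta:
    """Balanced (or weighted) two-point mixture with optional jitter.

    With ``noise_sd=0`` this is the extreme bimodal case whose step-fit
    SNR is unbounded.
    """

    locs: tuple = (0.0, 1.0)
    weights: tuple = (0.5, 0.5)
    noise_sd: float = 0.0

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        _check_weights(self.weights, len(self.locs))
        comp = rng.choice(len(self.locs), size=n, p=np.asarray(self.weights))
        out = np.asarray(self.locs, float)[comp]
        if self.noise_sd > 0:
            out = out + rng.normal(0.0, self.noise_sd, n)
        return out


@dataclass(frozen=True)
class BetaMixture:
    """Mixture of Beta distributions; natural support for methylation values."""

    weights: tuple = (0.6, 0.4)
    shapes: tuple = ((2.0, 30.0), (15.0, 4.0))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        comp = self.components(rng, n)
        return self.sample_given(rng, comp)

    def components(self, rng: np.random.Generator, n: int) -> np.ndarray:
        _check_weights(self.weights, len(self.shapes))
        return rng.choice(len(self.shapes), size=n, p=np.asarray(self.weights))

    def sample_given(self, rng: np.random.Generator, comp: np.ndarray) -> np.ndarray:
        out = np.empty(comp.size)
        for c, (a, b) in enumerate(self.shapes):
            sel = comp == c
            out[sel] = rng.beta(a, b, int(sel.sum()))
        return out

    @property
    def component_means(self) -> np.ndarray:
        return np.array([a / (a + b) for a, b in self.shapes])


@dataclass(frozen=True)
class GaussianMixture:
    """Gaussian mixture, used for log-scale expression."""

    weights: tuple = (0.5, 0.5)
    components: tuple = ((2.0, 0.8), (6.0, 0.8))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        _check_weights(self.weights, len(self.components))
        comp = rng.choice(len(self.components), size=n, p=np.asarray(self.weights))
        return self.sample_given(rng, comp)

    def sample_given(self, rng: np.random.Generator, comp: np.ndarray) -> np.ndarray:
        out = np.empty(comp.size)
        for c, (m, s) in enumerate(self.components):
            sel = comp == c
            out[sel] = rng.normal(m, s, int(sel.sum()))
        return out


def _check_weights(weights, k):
    w = np.asarray(weights, float)
    if w.size != k or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
        raise InvalidInputError("mixture weights must be non-negative and sum to 1")


def gen_univariate(spec, n: int, seed) -> np.ndarray:
    """Draw n observations from a marginal spec; reproducible for fixed seed."""
    if n < 2:
        raise InvalidInputError("n must be >= 2")
    rng = np.random.default_rng(seed)
    return spec.sample(rng, n)


# ------------------------------------------------------------------- pairs


@dataclass(frozen=True)
class SilencingSpec:
    """Joint law of (log expression, beta) under methylation silencing.

    A fraction of samples is methylated: beta from the high Beta
    component, expression from the low mode.  Unmethylated samples take
    beta from the low component and expression from the high mode with
    probability ``p_high_given_unmeth``, otherwise the low mode.
    """

    frac_methylated: float = 0.4
    p_high_given_unmeth: float = 0.5
    beta_unmeth: tuple = (2.0, 30.0)
    beta_meth: tuple = (15.0, 4.0)
    expr_low: tuple = (2.0, 0.8)
    expr_high: tuple = (6.0, 0.8)

    def __post_init__(self):
        if not (0.0 <= self.frac_methylated <= 1.0 and 0.0 <= self.p_high_given_unmeth <= 1.0):
            raise InvalidInputError("fractions must lie in [0, 1]")

    @property
    def beta_modes(self) -> tuple[float, float]:
        """(unmethylated, methylated) component means on the beta scale."""
        (a1, b1), (a2, b2) = self.beta_unmeth, self.beta_meth
        return a1 / (a1 + b1), a2 / (a2 + b2)

    def draw(self, rng: np.random.Generator, n: int):
        methylated = rng.random(n) < self.frac_methylated
        expr_high = ~methylated & (rng.random(n) < self.p_high_given_unmeth)
        beta = np.where(
            methylated,
            rng.beta(*self.beta_meth, n),
            rng.beta(*self.beta_unmeth, n),
        )
        x = np.where(
            expr_high,
            rng.normal(*self.expr_high, n),
            rng.normal(*self.expr_low, n),
        )
        return x, beta, methylated, expr_high


@dataclass(frozen=True)
class IndependentSpec:
    """Null joint law: the two variables are drawn independently."""

    x_dist: object = field(default_factory=GaussianMixture)
    y_dist: object = field(default_factory=BetaMixture)

    def draw(self, rng: np.random.Generator, n: int):
        y_dist = self.y_dist
        if isinstance(y_dist, BetaMixture):
            comp = y_dist.components(rng, n)
            beta = y_dist.sample_given(rng, comp)
            methylated = comp == int(np.argmax(y_dist.component_means))
        else:
            beta = y_dist.sample(rng, n)
            methylated = beta > np.median(beta)
        if isinstance(self.x_dist, GaussianMixture):
            comp_x = rng.choice(
                len(self.x_dist.components), size=n, p=np.asarray(self.x_dist.weights)
            )
            x = self.x_dist.sample_given(rng, comp_x)
            expr_high = comp_x == int(np.argmax([m for m, _ in self.x_dist.components]))
        else:
            x = self.x_dist.sample(rng, n)
            expr_high = x > np.median(x)
        return x, beta, methylated, expr_high


def gen_pair(spec, n: int, seed) -> tuple[PairedSeries, pd.DataFrame]:
    """One synthetic (expression, methylation) pair plus ground-truth labels.

    The truth frame carries, per sample, the planted ``methylated`` and
    ``expr_high`` indicators (and hence the true quadrant).
    """
    if n < 4:
        raise InvalidInputError("n must be >= 4")
    rng = np.random.default_rng(seed)
    x, y, methylated, expr_high = spec.draw(rng, n)
    ids = tuple(f"s{i:05d}" for i in range(n))
    truth = pd.DataFrame(
        {"methylated": methylated, "expr_high": expr_high},
        index=pd.Index(ids, name="sample_id"),
    )
    return PairedSeries(x=x, y=y, ids=ids, x_id="gene", y_id="cpg"), truth


# ------------------------------------------------------------------ cohort


@dataclass(frozen=True)
class GroupSpec:
    label: str
    n: int
    silencing: bool = True


DEFAULT_GROUPS = (
    GroupSpec("BRCA", 313),
    GroupSpec("COADREAD", 227),
    GroupSpec("KIRC", 208),
    GroupSpec("LUSC", 129),
    GroupSpec("UCEC", 115),
)

SITE_CLASSES = (
    "silenced_all",       # silencing in every group
    "silenced_subset",    # silencing in some groups, independence elsewhere
    "composition",        # association only through between-group composition
    "null",               # independence everywhere
    "high_missing",       # null + >1% injected missing (filter target)
    "near_zero",          # beta < 0.01 in >95% of samples (filter target)
    "unannotated",        # annotated gene absent from the expression matrix
)


@dataclass(frozen=True)
class CohortSpec:
    """Layout of a planted cohort: groups, site-class counts, nuisance rates."""

    groups: tuple = DEFAULT_GROUPS
    n_silenced_all: int = 20
    n_silenced_subset: int = 20
    n_composition: int = 20
    n_null: int = 100
    n_high_missing: int = 5
    n_near_zero: int = 5
    n_unannotated: int = 5
    silencing: SilencingSpec = field(default_factory=SilencingSpec)
    subset_size: int = 2          # groups carrying the association in class silenced_subset
    missing_rate: float = 0.002   # background missing-beta rate (below the 1% filter)
    zero_expr_rate: float = 0.01  # raw expression entries zeroed (detection floor)
    log_base: float = 2.0

    def __post_init__(self):
        if len(self.groups) < 1:
            raise InvalidInputError("need at least one group")
        if not 1 <= self.subset_size <= len(self.groups):
            raise InvalidInputError("subset_size must be in [1, n_groups]")
        for rate in (self.missing_rate, self.zero_expr_rate):
            if not 0.0 <= rate <= 1.0:
                raise InvalidInputError("rates must lie in [0, 1]")


@dataclass
class Cohort:
    """Generated cohort: the three input tables plus full ground truth."""

    meth: pd.DataFrame          # CpG sites x samples, beta in [0,1], NaN = missing
    expr: pd.DataFrame          # genes x samples, raw RPKM-like values
    annot: pd.DataFrame         # columns (cpg_id, gene_id)
    groups: pd.Series           # sample_id -> group label
    site_truth: pd.DataFrame    # per-site class, gene, on-groups, beta modes
    spec: CohortSpec


def _null_site(rng, spec: CohortSpec, n: int):
    ind = IndependentSpec(
        x_dist=GaussianMixture(components=(spec.silencing.expr_low, spec.silencing.expr_high)),
        y_dist=BetaMixture(
            weights=(1 - spec.silencing.frac_methylated, spec.silencing.frac_methylated),
            shapes=(spec.silencing.beta_unmeth, spec.silencing.beta_meth),
        ),
    )
    x, y, _, _ = ind.draw(rng, n)
    return x, y


def gen_cohort(spec: CohortSpec = CohortSpec(), seed=0) -> Cohort:
    """Emit a full planted cohort ready for the end-to-end pipeline.

    Expression is written on the raw scale (``log_base ** logvalue`` with a
    sprinkling of exact zeros) so the preprocessing transform has work to
    do; methylation carries background missingness plus dedicated filter
    targets.  ``site_truth`` records each site's class and, for associated
    classes, the groups carrying the association and the generator's beta
    component means.
    """
    rng = np.random.default_rng(seed)
    groups = list(spec.groups)
    n = sum(g.n for g in groups)
    sample_ids = [f"{g.label}_{i:04d}" for g in groups for i in range(g.n)]
    group_labels = np.array([g.label for g in groups for _ in range(g.n)])
    group_sel = {g.label: group_labels == g.label for g in groups}

    counts = {
        "silenced_all": spec.n_silenced_all,
        "silenced_subset": spec.n_silenced_subset,
        "composition": spec.n_composition,
        "null": spec.n_null,
        "high_missing": spec.n_high_missing,
        "near_zero": spec.n_near_zero,
        "unannotated": spec.n_unannotated,
    }
    sil = spec.silencing
    lo_mode, hi_mode = sil.beta_modes

    meth_rows, expr_rows, truth_rows, annot_rows = [], [], [], []
    site_no = 0
    for klass in SITE_CLASSES:
        for _ in range(counts[klass]):
            site_id = f"cg{site_no:08d}"
            gene_id = f"GENE{site_no:05d}"
            site_no += 1
            y = np.empty(n)
            x = np.empty(n)
            on_groups: tuple = ()
            if klass == "silenced_all":
                xg, yg, _, _ = sil.draw(rng, n)
                x, y = xg, yg
                on_groups = tuple(g.label for g in groups)
            elif klass == "silenced_subset":
                chosen = rng.choice(len(groups), size=spec.subset_size, replace=False)
                on_groups = tuple(groups[i].label for i in sorted(chosen))
                for g in groups:
                    sel = group_sel[g.label]
                    if g.label in on_groups:
                        xg, yg, _, _ = sil.draw(rng, int(sel.sum()))
                    else:
                        xg, yg = _null_site(rng, spec, int(sel.sum()))
                    x[sel], y[sel] = xg, yg
            elif klass == "composition":
                # at least one methylated-tissue group and one unmethylated
                n_meth_groups = int(rng.integers(1, len(groups))) if len(groups) > 1 else 1
                meth_groups = set(
                    groups[i].label
                    for i in rng.choice(len(groups), size=n_meth_groups, replace=False)
                )
                on_groups = tuple(sorted(meth_groups))
                for g in groups:
                    sel = group_sel[g.label]
                    m = int(sel.sum())
                    if g.label in meth_groups:
                        y[sel] = rng.beta(*sil.beta_meth, m)
                        x[sel] = rng.normal(*sil.expr_low, m)
                    else:
                        y[sel] = rng.beta(*sil.beta_unmeth, m)
                        x[sel] = rng.normal(*sil.expr_high, m)
            elif klass in ("null", "high_missing", "unannotated"):
                x, y = _null_site(rng, spec, n)
            elif klass == "near_zero":
                y = rng.uniform(0.0, 0.008, n)
                bump = rng.random(n) < 0.03  # a few quantifiable values, below the 95% bar
                y[bump] = rng.uniform(0.02, 0.2, int(bump.sum()))
                x = rng.normal(*sil.expr_high, n)

            # nuisance: background missing betas; heavy missingness for the filter target
            miss_rate = 0.02 if klass == "high_missing" else spec.missing_rate
            if miss_rate > 0:
                miss = rng.random(n) < miss_rate
                if klass == "high_missing" and miss.mean() <= 0.01:
                    miss[rng.choice(n, size=int(0.02 * n) + 1, replace=False)] = True
                y = y.copy()
                y[miss] = np.nan

            raw = np.power(spec.log_base, x)
            if spec.zero_expr_rate > 0:
                raw = raw.copy()
                raw[rng.random(n) < spec.zero_expr_rate] = 0.0

            meth_rows.append(pd.Series(y, index=sample_ids, name=site_id))
            if klass != "unannotated":
                expr_rows.append(pd.Series(raw, index=sample_ids, name=gene_id))
            annot_rows.append((site_id, gene_id))
            truth_rows.append(
                {
                    "site_id": site_id,
                    "gene_id": gene_id,
                    "klass": klass,
                    "on_groups": ",".join(on_groups),
                    "beta_mode_low": lo_mode,
                    "beta_mode_high": hi_mode,
                }
            )

    meth = pd.DataFrame(meth_rows)
    expr = pd.DataFrame(expr_rows)
    meth.columns.name = expr.columns.name = "sample_id"
    annot = pd.DataFrame(annot_rows, columns=["cpg_id", "gene_id"])
    truth = pd.DataFrame(truth_rows).set_index("site_id")
    return Cohort(
        meth=meth,
        expr=expr,
        annot=annot,
        groups=pd.Series(group_labels, index=sample_ids, name="group"),
        site_truth=truth,
        spec=spec,
    )
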