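"""Bivariate step-function fitting over a rank-space monotone surface.

The univariate procedure in :mod:`~stepminer2d.step1d` views sorted data as
a non-decreasing curve (rank on the x-axis, value on the y-axis) fitted by a
two-level step.  The bivariate extension does the same in one more
dimension.  Given n paired observations (x_k, y_k):

1. Each variable is standardized to zero mean, unit variance (sample sd).
2. Each observation is mapped to its rank pair (i, j) — i the rank of x_k
   among the x's, j the rank of y_k among the y's — with height
   z(i, j) = x~_k + y~_k (the standardized sum).
3. Rank points with no observation take z(i, j) = max_{u<=i, v<=j} z(u, v),
   so the completed surface is non-decreasing along both axes.  A rank cell
   with an empty lower-left prefix takes the global minimum height.
4. The surface is approximated on a G x G grid (G = 50 by default):
   each rank axis is cut into G near-equal-count bins, a cell takes the max
   height of the observations mapped into it, and the monotone fill is
   applied at bin resolution.  Max-aggregation commutes with the lower-left
   max fill, so the binned surface is the exact bin-wise max of the
   full-resolution one.
5. A six-parameter bivariate step function

       f(i,j) = mu11 I(i<=tx, j<=ty) + mu12 I(i>tx, j<=ty)
              + mu21 I(i<=tx, j>ty)  + mu22 I(i>tx, j>ty)

   is fitted by exhaustively maximizing SNR = sum(f - mu_bar)^2 /
   sum(f - z)^2 over all grid splits (tx, ty), mu_bar being the grid mean
   of z.

6. The winning grid split is mapped back to data-scale thresholds: the
   upper rank edge r of bin tx gives threshold_x = (x_(r) + x_(r+1)) / 2,
   and likewise for y.

The optimal SNR measures joint multi-modality: it diverges for two- or
three-delta joint distributions, and for *independent* pairs it approaches
3 (uniform marginals) or ~1.75 (Gaussian marginals) — the same limits as
the 1D fit, because the surface then tends to a separable monotone sheet.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateInputError, InvalidInputError
from .step1d import dichotomize

__all__ = [
    "PairedSeries",
    "Surface",
    "StepFit2D",
    "StepMiner2D",
    "rank_transform",
    "build_surface",
    "fit_step_2d",
    "stepminer2d",
]


@dataclass(frozen=True)
class PairedSeries:
    """Complete paired observations of two variables for one feature pair.

    ``x`` is conventionally the (log) expression of a gene and ``y`` the
    methylation beta value of one of its CpG sites, but the fit is
    symmetric.  Samples with a missing value in either variable must be
    dropped before construction.
    """

    x: np.ndarray
    y: np.ndarray
    ids: tuple = ()
    x_id: str | None = None
    y_id: str | None = None

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float).ravel()
        y = np.asarray(self.y, dtype=float).ravel()
        if x.size != y.size:
            raise InvalidInputError(f"x and y differ in length ({x.size} vs {y.size})")
        if x.size < 4:
            raise InvalidInputError(f"need at least 4 paired observations, got {x.size}")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise InvalidInputError("paired series contains non-finite values")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if self.ids is not None and len(self.ids) not in (0, x.size):
            raise InvalidInputError("ids length does not match series length")

    @property
    def n(self) -> int:
        return self.x.size


def _ranks(values: np.ndarray) -> np.ndarray:
    """Ranks 1..n; ties broken by original sample index (stable sort)."""
    order = np.argsort(values, kind="stable")
    ranks = np.empty(values.size, dtype=np.int64)
    ranks[order] = np.arange(1, values.size + 1)
    return ranks


def rank_transform(pairs: PairedSeries) -> np.ndarray:
    """Per-sample integer rank pairs, shape (n, 2); each column a permutation of 1..n."""
    return np.column_stack([_ranks(pairs.x), _ranks(pairs.y)])


@dataclass(frozen=True)
class Surface:
    """Non-decreasing height surface on a G x G rank-bin grid.

    ``z[b, a]`` is the height of y-bin ``b`` (row), x-bin ``a`` (column),
    origin at (low x, low y).  ``x_bin_edges``/``y_bin_edges`` are the G+1
    cumulative rank cutoffs per axis: bin ``a`` (1-based) covers ranks
    ``edges[a-1]+1 .. edges[a]``.
    """

    grid_size: int
    z: np.ndarray
    x_bin_edges: np.ndarray
    y_bin_edges: np.ndarray
    global_min: float

    def is_monotone(self) -> bool:
        return bool(np.all(np.diff(self.z, axis=0) >= 0) and np.all(np.diff(self.z, axis=1) >= 0))


def _bin_edges(n: int, g: int) -> np.ndarray:
    return np.round(np.linspace(0, n, g + 1)).astype(np.int64)


def _standardize(v: np.ndarray, name: str) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError(f"{name} has zero variance; no ranking is meaningful")
    return (v - v.mean()) / sd


def build_surface(pairs: PairedSeries, grid_size: int = 50) -> Surface:
    """Standardize, rank, bin and monotone-fill the height surface."""
    g = int(grid_size)
    if g < 2:
        raise InvalidInputError("grid_size must be >= 2")
    n = pairs.n
    if n < g:
        warnings.warn(
            f"fewer observations ({n}) than grid cells per axis ({g}); "
            "some bins will be empty and thresholds may be unavailable",
            stacklevel=2,
        )
    xt = _standardize(pairs.x, "x")
    yt = _standardize(pairs.y, "y")
    heights = xt + yt
    global_min = float(heights.min())

    rk = rank_transform(pairs)
    x_edges = _bin_edges(n, g)
    y_edges = _bin_edges(n, g)
    # bin index (0-based) of each rank: first edge >= rank
    bx = np.searchsorted(x_edges, rk[:, 0], side="left") - 1
    by = np.searchsorted(y_edges, rk[:, 1], side="left") - 1

    z = np.full((g, g), global_min)
    np.maximum.at(z, (by, bx), heights)
    # lower-left running max == the 2D recurrence z[b,a] = max(raw, z[b-1,a], z[b,a-1])
    np.maximum.accumulate(z, axis=0, out=z)
    np.maximum.accumulate(z, axis=1, out=z)
    return Surface(grid_size=g, z=z, x_bin_edges=x_edges, y_bin_edges=y_edges, global_min=global_min)


def _grid_search(z: np.ndarray):
    """Exhaustive (tx, ty) search via 2D prefix sums of the centered surface.

    Uses the ANOVA identity noise = SS_total - signal over the G^2 cells;
    signal(tx, ty) = sum_q S_q^2 / n_q with S_q centered block sums.
    """
    g = z.shape[0]
    zc = z - z.mean()
    ss_total = float(np.sum(zc**2))
    c = zc.cumsum(axis=0).cumsum(axis=1)  # c[b, a] = sum over y-bins <= b, x-bins <= a

    tx = np.arange(1, g)[None, :]
    ty = np.arange(1, g)[:, None]
    s11 = c[: g - 1, : g - 1]                       # i<=tx, j<=ty
    s_lowy = c[: g - 1, g - 1][:, None]             # all x, j<=ty
    s_lowx = c[g - 1, : g - 1][None, :]             # i<=tx, all y
    total = c[g - 1, g - 1]
    s12 = s_lowy - s11                              # i>tx, j<=ty
    s21 = s_lowx - s11                              # i<=tx, j>ty
    s22 = total - s11 - s12 - s21

    n11 = (tx * ty).astype(float)
    n12 = ((g - tx) * ty).astype(float)
    n21 = (tx * (g - ty)).astype(float)
    n22 = ((g - tx) * (g - ty)).astype(float)

    signal = s11**2 / n11 + s12**2 / n12 + s21**2 / n21 + s22**2 / n22
    noise = np.maximum(ss_total - signal, 0.0)
    zero = noise <= ss_total * 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(zero, np.inf, signal / np.where(zero, 1.0, noise))
    return signal, noise, snr


@dataclass(frozen=True)
class StepFit2D:
    """Fitted bivariate step function.

    ``tx``/``ty`` are grid-axis split indices in [1, G-1]; ``mu11..mu22``
    the four quadrant means of the fitted function (first digit = x side,
    second = y side; 1 = low, 2 = high); ``threshold_x``/``threshold_y``
    the back-mapped data-scale thresholds (None when fitted from a bare
    surface, or when a bin edge falls outside [1, n-1]).
    """

    tx: int
    ty: int
    mu11: float
    mu12: float
    mu21: float
    mu22: float
    snr: float
    signal: float
    noise: float
    grid_size: int
    threshold_x: float | None = None
    threshold_y: float | None = None
    nobs: int | None = None
    surface: Surface | None = field(default=None, repr=False)

    def recompute_snr(self) -> float:
        """SNR from the stored split and surface via the literal definitions."""
        if self.surface is None:
            raise InvalidInputError("no surface stored with this fit")
        z = self.surface.z
        g = self.grid_size
        f = np.empty_like(z)
        f[: self.ty, : self.tx] = self.mu11
        f[: self.ty, self.tx :] = self.mu12
        f[self.ty :, : self.tx] = self.mu21
        f[self.ty :, self.tx :] = self.mu22
        signal = float(np.sum((f - z.mean()) ** 2))
        noise = float(np.sum((f - z) ** 2))
        return np.inf if noise == 0 else signal / noise

    def dichotomize_x(self, values) -> np.ndarray:
        if self.threshold_x is None:
            raise InvalidInputError("fit carries no x threshold")
        return dichotomize(values, self.threshold_x)

    def dichotomize_y(self, values) -> np.ndarray:
        if self.threshold_y is None:
            raise InvalidInputError("fit carries no y threshold")
        return dichotomize(values, self.threshold_y)

    def summary(self) -> str:
        thr = lambda v: "n/a" if v is None else f"{v:.6g}"
        return "\n".join(
            [
                "Bivariate step fit",
                "=" * 40,
                f"  n observations     {self.nobs if self.nobs is not None else 'n/a'}",
                f"  grid size G        {self.grid_size}",
                f"  grid split (tx,ty) ({self.tx}, {self.ty})",
                f"  quadrant means     mu11={self.mu11:.4g}  mu12={self.mu12:.4g}",
                f"                     mu21={self.mu21:.4g}  mu22={self.mu22:.4g}",
                f"  threshold x        {thr(self.threshold_x)}",
                f"  threshold y        {thr(self.threshold_y)}",
                f"  SNR                {self.snr:.6g}",
            ]
        )

    def plot(self, pairs: PairedSeries | None = None, ax=None):
        """Scatter of the pair with the fitted thresholds as dotted lines."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        if pairs is not None:
            ax.scatter(pairs.y, pairs.x, s=8, alpha=0.5, edgecolors="none")
            ax.set_xlabel(pairs.y_id or "methylation (beta)")
            ax.set_ylabel(pairs.x_id or "expression (log)")
        if self.threshold_y is not None:
            ax.axvline(self.threshold_y, ls=":", color="k")
        if self.threshold_x is not None:
            ax.axhline(self.threshold_x, ls=":", color="k")
        ax.set_title(f"SNR = {self.snr:.3g}")
        return ax


def fit_step_2d(surface: Surface) -> StepFit2D:
    """Exhaustive SNR maximization over all grid splits of a surface.

    Ties broken by larger signal, then smaller tx, then smaller ty.
    Grid-level parameters only; use :func:`stepminer2d` for data-scale
    thresholds.
    """
    z = surface.z
    if z.max() == z.min():
        raise DegenerateInputError("constant surface: signal is zero for every split")
    signal, noise, snr = _grid_search(z)
    # ties detected to relative 1e-10: symmetric surfaces must resolve by the
    # deterministic (signal, tx, ty) rule, not by float noise in the last bits
    if np.isposinf(snr).any():
        mask = np.isposinf(snr)
    else:
        mask = snr >= snr.max() * (1.0 - 1e-10)
    mask = mask & (signal >= signal[mask].max() * (1.0 - 1e-10))
    # tie-break order is (smaller tx, then smaller ty)
    cand = np.argwhere(mask)
    order = np.lexsort((cand[:, 0], cand[:, 1]))  # primary tx (col), secondary ty (row)
    tyi, txi = cand[order[0]]
    tx, ty = int(txi) + 1, int(tyi) + 1
    g = surface.grid_size
    mu11 = float(z[:ty, :tx].mean())
    mu12 = float(z[:ty, tx:].mean())
    mu21 = float(z[ty:, :tx].mean())
    mu22 = float(z[ty:, tx:].mean())
    return StepFit2D(
        tx=tx,
        ty=ty,
        mu11=mu11,
        mu12=mu12,
        mu21=mu21,
        mu22=mu22,
        snr=float(snr[tyi, txi]),
        signal=float(signal[tyi, txi]),
        noise=float(noise[tyi, txi]),
        grid_size=g,
        surface=surface,
    )


def _midpoint_threshold(values: np.ndarray, r: int) -> float | None:
    """Midpoint of order statistics r and r+1 (1-based); None if r outside [1, n-1]."""
    n = values.size
    if not 1 <= r <= n - 1:
        return None
    s = np.sort(values, kind="stable")
    return float((s[r - 1] + s[r]) / 2.0)


class StepMiner2D:
    """Bivariate step-fit model for one feature pair.

    Parameters
    ----------
    x, y : array-like
        Paired, complete observations (x: e.g. log expression; y: e.g.
        methylation beta).  May also be constructed from an existing
        :class:`PairedSeries` via :meth:`from_pairs`.
    """

    def __init__(self, x, y, ids=(), x_id=None, y_id=None):
        self.pairs = PairedSeries(x=np.asarray(x, float), y=np.asarray(y, float), ids=tuple(ids), x_id=x_id, y_id=y_id)
        self.nobs = self.pairs.n

    @classmethod
    def from_pairs(cls, pairs: PairedSeries) -> "StepMiner2D":
        obj = cls.__new__(cls)
        obj.pairs = pairs
        obj.nobs = pairs.n
        return obj

    def fit(self, grid_size: int = 50) -> StepFit2D:
        surface = build_surface(self.pairs, grid_size=grid_size)
        grid_fit = fit_step_2d(surface)
        rx = int(surface.x_bin_edges[grid_fit.tx])
        ry = int(surface.y_bin_edges[grid_fit.ty])
        return StepFit2D(
            tx=grid_fit.tx,
            ty=grid_fit.ty,
            mu11=grid_fit.mu11,
            mu12=grid_fit.mu12,
            mu21=grid_fit.mu21,
            mu22=grid_fit.mu22,
            snr=grid_fit.snr,
            signal=grid_fit.signal,
            noise=grid_fit.noise,
            grid_size=grid_fit.grid_size,
            threshold_x=_midpoint_threshold(self.pairs.x, rx),
            threshold_y=_midpoint_threshold(self.pairs.y, ry),
            nobs=self.nobs,
            surface=surface,
        )


def stepminer2d(pairs: PairedSeries, grid_size: int = 50) -> StepFit2D:
    """Full bivariate pipeline: rank transform, surface, grid fit, thresholds."""
    return StepMiner2D.from_pairs(pairs).fit(grid_size=grid_size)
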