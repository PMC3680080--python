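"""Univariate step-function fitting (the classic StepMiner procedure).

A continuous measurement with a bimodal marginal — gene expression across a
cohort, or a CpG site's methylation beta value — can be binarized into an
on/off call once a threshold is known.  The StepMiner idea is to sort the
``n`` observations ascending and fit a two-level step function

    f(i) = mu1 * I(i <= t) + mu2 * I(i > t),    1 <= t < n,

choosing the split ``t`` that maximizes a signal-to-noise ratio

    SNR(t) = signal / noise
    signal = sum_i (f(i) - mu)^2        (mu = grand mean)
    noise  = sum_i (f(i) - x_(i))^2     (residual against the sorted data)

The dichotomization threshold is the midpoint of the two order statistics
straddling the optimal split, (x_(t*) + x_(t*+1)) / 2.

The maximal SNR is a measure of bimodality: it diverges for a two-delta
mixture, equals 3 in the large-n limit for uniform data, and is ~1.75 for
Gaussian data regardless of mean and variance.

The model/results split follows statsmodels: build a :class:`StepMiner1D`
from data, call :meth:`~StepMiner1D.fit`, and read estimates off the
returned :class:`StepFit1D`.  Module-level helpers (:func:`fit_step_1d`,
:func:`snr_profile_1d`, :func:`dichotomize`) cover one-shot use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateInputError, InvalidInputError

__all__ = ["StepMiner1D", "StepFit1D", "fit_step_1d", "snr_profile_1d", "dichotomize"]


def _validate_series(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size < 2:
        raise InvalidInputError(f"need at least 2 observations, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("series contains non-finite values; remove missing entries upstream")
    return arr


def _split_profile(xs: np.ndarray):
    """Signal, noise and SNR for every split of an ascending-sorted array.

    Uses the ANOVA identity noise(t) = SS_total - signal(t), where
    SS_total is the total centered sum of squares: the residual of the
    two-level fit against sorted data is exactly the within-segment SS.
    Data are centered before accumulating to keep the identity
    well-conditioned under affine shifts.
    """
    n = xs.size
    xc = xs - xs.mean()
    t = np.arange(1, n)
    cum = np.cumsum(xc)[:-1]          # lower-segment sums, centered
    ss_total = float(np.dot(xc, xc))
    # between-segment SS: t*mu1c^2 + (n-t)*mu2c^2 with mu2c = -cum/(n-t)
    signal = cum**2 / t + cum**2 / (n - t)
    noise = np.maximum(ss_total - signal, 0.0)
    zero = noise <= ss_total * 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(zero, np.inf, signal / np.where(zero, 1.0, noise))
    return t, signal, noise, snr


def _best_split(signal: np.ndarray, snr: np.ndarray) -> int:
    """Index (0-based) of the winning split: max SNR, then max signal, then smallest t.

    Ties are detected to relative 1e-10 so that exactly symmetric series
    (equal-SNR splits whose float values differ only in the last bits)
    resolve deterministically by the smallest-t rule.
    """
    if np.isposinf(snr).any():
        cand = np.flatnonzero(np.isposinf(snr))
    else:
        cand = np.flatnonzero(snr >= snr.max() * (1.0 - 1e-10))
    cand = cand[signal[cand] >= signal[cand].max() * (1.0 - 1e-10)]
    return int(cand.min())


class StepMiner1D:
    """Step-function model for one continuous variable.

    Parameters
    ----------
    values : array-like
        Finite observations, length >= 2.  Missing values must be removed
        before construction.
    id : str, optional
        Free-text label carried through to the results.
    """

    def __init__(self, values, id: str | None = None):
        self.values = _validate_series(values)
        self.id = id
        self.nobs = self.values.size

    def fit(self) -> "StepFit1D":
        """Exhaustive SNR maximization over all splits 1 <= t < n."""
        xs = np.sort(self.values, kind="stable")
        if xs[0] == xs[-1]:
            raise DegenerateInputError(
                "all observations identical: signal is zero for every split, no threshold exists"
            )
        t, signal, noise, snr = _split_profile(xs)
        i = _best_split(signal, snr)
        ts = int(t[i])
        mu1 = float(xs[:ts].mean())
        mu2 = float(xs[ts:].mean())
        return StepFit1D(
            split_index=ts,
            mu1=mu1,
            mu2=mu2,
            snr=float(snr[i]),
            threshold=float((xs[ts - 1] + xs[ts]) / 2.0),
            signal=float(signal[i]),
            noise=float(noise[i]),
            nobs=int(xs.size),
            sorted_values=xs,
            id=self.id,
        )

    def snr_profile(self):
        """``(t, SNR(t))`` for every candidate split — the exhaustive search, exposed."""
        xs = np.sort(self.values, kind="stable")
        if xs[0] == xs[-1]:
            raise DegenerateInputError("all observations identical")
        t, _, _, snr = _split_profile(xs)
        return list(zip(t.tolist(), snr.tolist()))


@dataclass(frozen=True)
class StepFit1D:
    """Fitted univariate step function.

    Attributes
    ----------
    split_index : int
        t* — number of observations in the lower segment, in [1, n-1].
    mu1, mu2 : float
        Means of the lower and upper segments (mu1 <= mu2 by sorting).
    snr : float
        Maximal signal-to-noise ratio; ``inf`` when the fit is exact.
    threshold : float
        Data-scale dichotomization threshold, the midpoint
        (x_(t*) + x_(t*+1)) / 2.
    """

    split_index: int
    mu1: float
    mu2: float
    snr: float
    threshold: float
    signal: float
    noise: float
    nobs: int
    sorted_values: np.ndarray = field(repr=False)
    id: str | None = None

    def dichotomize(self, values=None) -> np.ndarray:
        """Binary calls (1=HIGH, 0=LOW, NaN propagated) for ``values`` or the fit data."""
        if values is None:
            values = self.sorted_values
        return dichotomize(values, self.threshold)

    def recompute_snr(self) -> float:
        """SNR recomputed from the stored split via the literal definitions."""
        xs = self.sorted_values
        t = self.split_index
        f = np.concatenate([np.full(t, xs[:t].mean()), np.full(xs.size - t, xs[t:].mean())])
        signal = float(np.sum((f - xs.mean()) ** 2))
        noise = float(np.sum((f - xs) ** 2))
        return np.inf if noise == 0 else signal / noise

    def summary(self) -> str:
        lines = [
            "Univariate step fit" + (f" [{self.id}]" if self.id else ""),
            "=" * 40,
            f"  n observations   {self.nobs}",
            f"  split index t*   {self.split_index}",
            f"  mu1 (low)        {self.mu1:.6g}",
            f"  mu2 (high)       {self.mu2:.6g}",
            f"  threshold        {self.threshold:.6g}",
            f"  SNR              {self.snr:.6g}",
        ]
        return "\n".join(lines)


def fit_step_1d(values, id: str | None = None) -> StepFit1D:
    """Fit the univariate step function by exhaustive SNR maximization."""
    return StepMiner1D(values, id=id).fit()


def snr_profile_1d(values):
    """Diagnostic view of the exhaustive search: ``[(t, SNR(t)) for t in 1..n-1]``."""
    return StepMiner1D(values).snr_profile()


def dichotomize(values, threshold: float) -> np.ndarray:
    """Binary on/off calls against a threshold.

    HIGH (1.0) iff value > threshold; LOW (0.0) iff value <= threshold —
    a value landing exactly on the threshold is LOW.  NaN entries stay NaN.
    """
    if not np.isfinite(threshold):
        raise InvalidInputError("threshold must be finite")
    arr = np.asarray(values, dtype=float)
    out = (arr > threshold).astype(float)
    out[np.isnan(arr)] = np.nan
    return out
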