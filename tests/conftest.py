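"""Shared fixtures and independent brute-force oracles.

The oracles here recompute every quantity from the literal definitions —
loops over all splits, the full n x n rank surface, term-by-term
hypergeometric sums — and stay deliberately independent of the package's
vectorized implementations.
"""

import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


# ---------------------------------------------------------------- 1D oracle


def _key_round(v):
    """Round to 10 significant digits so float noise cannot break exact ties."""
    return v if not math.isfinite(v) else float(f"{v:.10e}")


def oracle_fit_1d(values):
    """Exhaustive split search straight from the definitions.

    Returns (t*, mu1, mu2, snr, threshold, signal, noise) with the same
    tie-break contract: max SNR, then max signal, then smallest t.
    """
    xs = sorted(values)
    n = len(xs)
    mu = sum(xs) / n
    ss_total = sum((xi - mu) ** 2 for xi in xs)
    best = None
    for t in range(1, n):
        mu1 = sum(xs[:t]) / t
        mu2 = sum(xs[t:]) / (n - t)
        f = [mu1] * t + [mu2] * (n - t)
        signal = sum((fi - mu) ** 2 for fi in f)
        noise = sum((fi - xi) ** 2 for fi, xi in zip(f, xs))
        # zero-noise convention: residuals below float-rounding scale count as exact
        snr = math.inf if noise <= ss_total * 1e-12 else signal / noise
        key = (_key_round(snr), _key_round(signal), -t)
        if best is None or key > best[0]:
            best = (key, t, mu1, mu2, snr, signal, noise)
    _, t, mu1, mu2, snr, signal, noise = best
    threshold = (xs[t - 1] + xs[t]) / 2
    return t, mu1, mu2, snr, threshold, signal, noise


# ---------------------------------------------------------------- 2D oracle


def oracle_surface_full(x, y):
    """Complete n x n rank-resolution surface via the lower-left max recurrence."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    xt = (x - x.mean()) / x.std(ddof=1)
    yt = (y - y.mean()) / y.std(ddof=1)
    h = xt + yt
    rx = np.empty(n, int)
    rx[np.argsort(x, kind="stable")] = np.arange(n)
    ry = np.empty(n, int)
    ry[np.argsort(y, kind="stable")] = np.arange(n)
    gmin = h.min()
    z = np.full((n, n), -np.inf)
    for k in range(n):
        z[ry[k], rx[k]] = h[k]
    out = np.empty((n, n))
    for j in range(n):
        for i in range(n):
            best = z[j, i]
            if j > 0:
                best = max(best, out[j - 1, i])
            if i > 0:
                best = max(best, out[j, i - 1])
            out[j, i] = best if np.isfinite(best) else gmin
    return out, gmin


def oracle_bin_max(zfull, edges):
    """Bin a full-resolution surface to the grid by per-cell max."""
    g = len(edges) - 1
    out = np.empty((g, g))
    for b in range(g):
        for a in range(g):
            block = zfull[edges[b]: edges[b + 1], edges[a]: edges[a + 1]]
            out[b, a] = block.max() if block.size else np.nan
    # empty rows/cols (n < G) inherit from the monotone fill of the full surface
    for b in range(g):
        for a in range(g):
            if np.isnan(out[b, a]):
                lo = zfull.min()
                if a > 0 and not np.isnan(out[b, a - 1]):
                    lo = max(lo, out[b, a - 1])
                if b > 0 and not np.isnan(out[b - 1, a]):
                    lo = max(lo, out[b - 1, a])
                out[b, a] = lo
    return out


def oracle_fit_2d(z):
    """Enumerate every grid split from the definitions; same tie-break contract."""
    g = z.shape[0]
    mu_bar = z.mean()
    best = None
    for tx in range(1, g):
        for ty in range(1, g):
            q = {
                (1, 1): z[:ty, :tx],
                (1, 2): z[:ty, tx:],
                (2, 1): z[ty:, :tx],
                (2, 2): z[ty:, tx:],
            }
            mus = {k: v.mean() for k, v in q.items()}
            f = np.empty_like(z)
            f[:ty, :tx] = mus[(1, 1)]
            f[:ty, tx:] = mus[(1, 2)]
            f[ty:, :tx] = mus[(2, 1)]
            f[ty:, tx:] = mus[(2, 2)]
            signal = float(np.sum((f - mu_bar) ** 2))
            noise = float(np.sum((f - z) ** 2))
            snr = math.inf if noise <= np.sum((z - mu_bar) ** 2) * 1e-12 else signal / noise
            key = (_key_round(snr), _key_round(signal), -tx, -ty)
            if best is None or key > best[0]:
                best = (key, tx, ty, mus, snr, signal, noise)
    _, tx, ty, mus, snr, signal, noise = best
    return tx, ty, mus, snr, signal, noise


# ------------------------------------------------------- hypergeometric


def oracle_hypergeom_pvalue(n, r, u, k):
    """Term-by-term exact-rational enumeration of P(count <= k)."""
    if k >= min(r, u):
        return 1.0
    denom = math.comb(n, r)
    lo = max(0, r + u - n)
    total = 0
    for kk in range(lo, k + 1):
        total += math.comb(u, kk) * math.comb(n - u, r - kk)
    return total / denom
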