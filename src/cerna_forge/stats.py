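"""Shared statistical kernels: Pearson correlation, hypergeometric upper tail, BH-FDR.

These are the primitives every screening stage leans on, so they live in one
place and every module imports from here — the enrichment and sponge-screen
p-values are bit-identical by construction.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as _st
from statsmodels.stats.multitest import multipletests

__all__ = ["pearson", "hypergeom_upper_tail", "bh_adjust", "ZeroVarianceError"]


class ZeroVarianceError(ValueError):
    """Raised when a correlation is requested for a constant vector."""


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with a two-tailed t-based p-value.

    r is the usual centered-moment ratio; the p-value comes from
    t = r * sqrt((n-2) / (1-r^2)) referred to a t distribution on n-2
    degrees of freedom. Requires n >= 3 and nonzero variance in both vectors.

    Returns
    -------
    (r, p) : tuple of floats, r in [-1, 1], p in (0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pearson expects two 1-d vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need n >= 3 samples, got {n}")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx == 0.0 or syy == 0.0:
        raise ZeroVarianceError("constant vector: correlation undefined")
    r = float(xc @ yc) / np.sqrt(sxx * syy)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(_st.t.sf(abs(t), df=n - 2))
    return r, min(p, 1.0)


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    N: population size (e.g. the miRNA universe), K: marked items
    (miRNAs targeting one partner), n: draws (miRNAs targeting the other),
    k: observed overlap. k = 0 gives 1.0 exactly.
    """
    k, K, n, N = int(k), int(K), int(n), int(N)
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"require 0 <= K, n <= N; got K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"require 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if k == 0:
        return 1.0
    return float(_st.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR), order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
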