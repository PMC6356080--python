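"""Shared statistical primitives: BH FDR and hypergeometric upper tails."""

from __future__ import annotations

import numpy as np
from scipy import stats


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, monotone)."""
    p = np.asarray(pvals, dtype=float)
    _check_p(p)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


def bh_threshold(pvals, alpha: float = 0.05) -> tuple[float, np.ndarray]:
    """BH rejection threshold: largest p_(k) with p_(k) <= k*alpha/m.

    Returns ``(threshold, reject_flags)``; threshold 0 when nothing is
    rejected (then no p can satisfy p <= 0 unless p == 0).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    _check_p(p)
    m = p.size
    srt = np.sort(p)
    ok = srt <= np.arange(1, m + 1) * alpha / m
    if not ok.any():
        return 0.0, np.zeros(m, dtype=bool)
    thr = float(srt[np.nonzero(ok)[0].max()])
    return thr, p <= thr


def _check_p(p: np.ndarray) -> None:
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")


def hypergeom_sf(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeom(N, K, n), log-space safe."""
    return float(np.exp(hypergeom_logsf(k, N, K, n)))


def hypergeom_logsf(k: int, N: int, K: int, n: int) -> float:
    """log P(X >= k); validates the table before delegating to scipy."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric table N={N}, K={K}, n={n}")
    if k > min(K, n):
        raise ValueError(f"k={k} exceeds min(K={K}, n={n})")
    if k <= max(0, n + K - N):
        return 0.0
    return float(stats.hypergeom.logsf(k - 1, N, K, n))
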