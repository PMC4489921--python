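"""Independent brute-force reference implementations.

Everything here recomputes the package's statistics with plain nested
loops on dense matrices, sharing no code with the implementation, so the
vectorized banded algorithms can be checked for exact agreement on small
inputs.
"""

from __future__ import annotations

import numpy as np

SHELL_RATIO = 2.0**0.25


def dense_from_banded(banded: np.ndarray, symmetric: bool = True) -> np.ndarray:
    n, K1 = banded.shape
    out = np.zeros((n, n), dtype=float)
    for i in range(n):
        for k in range(K1):
            j = i + k
            if j < n:
                out[i, j] = banded[i, k]
                if symmetric and k > 0:
                    out[j, i] = banded[i, k]
    return out


def shell_edges(bin_size: int, max_offset: int) -> list[float]:
    edges = [float(bin_size)]
    while edges[-1] < max_offset * bin_size:
        edges.append(edges[-1] * SHELL_RATIO)
    return edges


def oracle_decay(counts_banded: np.ndarray, bin_size: int):
    """f per shell and the per-offset expected count, by exhaustive loops."""
    n, K1 = counts_banded.shape
    edges = shell_edges(bin_size, K1 - 1)
    n_shells = len(edges) - 1
    sums = np.zeros(n_shells)
    pairs = np.zeros(n_shells)
    for k in range(1, K1):
        d = k * bin_size
        m = 0
        while m + 1 < len(edges) - 1 and d >= edges[m + 1]:
            m += 1
        for i in range(n - k):
            sums[m] += counts_banded[i, k]
        pairs[m] += n - k
    f = np.where(pairs > 0, sums / np.maximum(pairs, 1), 0.0)
    f_of_k = np.full(K1, np.nan)
    for k in range(1, K1):
        d = k * bin_size
        m = 0
        while m + 1 < len(edges) - 1 and d >= edges[m + 1]:
            m += 1
        f_of_k[k] = f[m]
    return np.asarray(edges), f, f_of_k


def _rolling_median(x: np.ndarray, win: int, min_periods: int) -> np.ndarray:
    n = x.size
    half = win // 2
    out = np.zeros(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        vals = [v for v in x[lo:hi] if np.isfinite(v)]
        out[i] = np.median(vals) if len(vals) >= min_periods else 0.0
    return out


def oracle_biases(
    counts_banded: np.ndarray,
    f_of_k: np.ndarray,
    bin_size: int,
    mask_fraction: float = 0.2,
    tol: float = 1e-4,
    max_iter: int = 200,
    damping: float = 0.5,
    detrend_window: int | None = 300_000,
):
    """Dense damped IPF with rolling-median high-pass, by loops."""
    dense = dense_from_banded(counts_banded)
    n = dense.shape[0]
    K1 = counts_banded.shape[1]
    m = np.array(
        [sum(dense[i, j] for j in range(n) if 0 < abs(i - j) < K1) for i in range(n)]
    )
    mask = m < mask_fraction * np.median(m)
    fd = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            k = abs(i - j)
            if 0 < k < K1 and np.isfinite(f_of_k[k]):
                fd[i, j] = f_of_k[k]
    b = np.where(mask, 0.0, 1.0)
    for _ in range(max_iter):
        b_new = b.copy()
        for i in range(n):
            if mask[i]:
                continue
            E = b[i] * sum(b[j] * fd[i, j] for j in range(n))
            if E > 0:
                b_new[i] = b[i] * (m[i] / E) ** damping
        gm = np.exp(np.mean([np.log(v) for v in b_new[~mask]]))
        b_new = np.where(mask, 0.0, b_new / gm)
        change = max(
            abs(b_new[i] - b[i]) / b[i] for i in range(n) if not mask[i]
        )
        b = b_new
        if change < tol:
            break
    out = np.where(mask, np.nan, b)
    if detrend_window is not None:
        win = max(3, int(detrend_window // bin_size) | 1)
        logb = np.where(mask, np.nan, np.log(out))
        trend = _rolling_median(logb, win, max(1, win // 4))
        out = np.exp(np.log(out) - trend)
        gm = np.exp(np.nanmean(np.log(out)))
        out = out / gm
    return out, mask


def oracle_enrichment(
    counts_banded: np.ndarray,
    b: np.ndarray,
    f_of_k: np.ndarray,
    pseudocount: float = 1.0,
):
    """Banded e and expected arrays by explicit loops."""
    n, K1 = counts_banded.shape
    e = np.full((n, K1), np.nan)
    exp = np.full((n, K1), np.nan)
    for i in range(n):
        for k in range(1, K1):
            j = i + k
            if j >= n or not np.isfinite(b[i]) or not np.isfinite(b[j]):
                continue
            exp[i, k] = b[i] * b[j] * f_of_k[k]
            e[i, k] = np.log2(
                (counts_banded[i, k] + pseudocount) / (exp[i, k] + pseudocount)
            )
    return e, exp


def oracle_insulation(
    e_banded: np.ndarray,
    wb: int,
    min_pairs: int = 10,
    mode: str = "mean",
    obs_banded: np.ndarray | None = None,
    exp_banded: np.ndarray | None = None,
    pseudocount: float = 1.0,
) -> np.ndarray:
    """I(x, w) by double loop over the crossing square."""
    n, K1 = e_banded.shape
    out = np.full(n, np.nan)
    for x in range(n):
        vals, osum, esum, cnt = [], 0.0, 0.0, 0
        for i in range(max(0, x - wb), x):
            for j in range(x, min(n, x + wb)):
                k = j - i
                if k < 1 or k >= K1:
                    continue
                if mode == "mean":
                    v = e_banded[i, k]
                    if np.isfinite(v):
                        vals.append(v)
                        cnt += 1
                else:
                    ev = exp_banded[i, k]
                    if np.isfinite(ev):
                        osum += obs_banded[i, k]
                        esum += ev
                        cnt += 1
        if cnt >= min_pairs:
            if mode == "mean":
                out[x] = float(np.mean(vals))
            else:
                out[x] = np.log2((osum + pseudocount) / (esum + pseudocount))
    return out


def oracle_pool(
    e_banded: np.ndarray,
    pairs_bins: np.ndarray,
    h: int,
    mode: str = "log",
    obs_banded: np.ndarray | None = None,
    exp_banded: np.ndarray | None = None,
) -> np.ndarray:
    """Pooled submatrix by explicit loops over pairs and offsets."""
    n, K1 = e_banded.shape
    size = 2 * h + 1
    out = np.full((size, size), np.nan)
    for ui, u in enumerate(range(-h, h + 1)):
        for vi, v in enumerate(range(-h, h + 1)):
            vals = []
            for a, b in pairs_bins:
                i, j = a + u, b + v
                k = j - i
                if i < 0 or j >= n or k < 1 or k >= K1:
                    continue
                if mode == "log":
                    val = e_banded[i, k]
                    if np.isfinite(val):
                        vals.append(val)
                else:
                    ev = exp_banded[i, k]
                    if np.isfinite(ev) and ev > 0:
                        vals.append(obs_banded[i, k] / ev)
            if vals:
                m = float(np.mean(vals))
                out[ui, vi] = m if mode == "log" else np.log2(m)
    return out


def oracle_sliding_median(coverage: np.ndarray, window: int, bin_size: int):
    half = int(window / 2 // bin_size)
    n = coverage.size
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = float(np.median(coverage[lo:hi]))
    return out
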