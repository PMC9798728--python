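"""Comparison machinery: rank tests, correlation-coefficient comparisons,
and rate-matched downsampling controls."""

from __future__ import annotations

import numpy as np
from scipy import stats as sstats

__all__ = ["compare_groups", "compare_correlations", "downsample_matched"]

_TESTS = {
    "ranksum": lambda a, b: sstats.ranksums(a, b),
    "mannwhitney": lambda a, b: sstats.mannwhitneyu(a, b, alternative="two-sided"),
    "kruskal": lambda a, b: sstats.kruskal(a, b),
    "ttest": lambda a, b: sstats.ttest_ind(a, b),
    "signrank": lambda a, b: sstats.wilcoxon(a, b),
}


def compare_groups(values_a, values_b, test: str = "ranksum") -> tuple[float, float]:
    """Two-sided comparison of two groups; (statistic, p).

    ``test`` is one of ranksum, mannwhitney, kruskal, ttest (plus signrank
    for paired data).  Thin delegation to scipy for pipeline completeness.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        return np.nan, np.nan
    if test not in _TESTS:
        raise ValueError(f"unknown test {test!r}")
    res = _TESTS[test](a, b)
    return float(res[0]), float(res[1])


def compare_correlations(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Two-sample comparison of Pearson correlations via the Fisher r-to-z
    transform: ``z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3))``,
    two-sided p from the normal reference.  Antisymmetric in its arguments.
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError("need n > 3 in both samples")
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise ValueError("|r| must be < 1")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * sstats.norm.sf(abs(z))
    return float(z), float(p)


def downsample_matched(
    values_a: np.ndarray,
    rates_a: np.ndarray,
    values_b: np.ndarray,
    rates_b: np.ndarray,
    statistic=np.mean,
    n_resamples: int = 100,
    n_bins: int = 10,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Subsample the larger set to the smaller's size with matched firing
    rates, returning the statistic's distribution across resamples.

    Rates of both sets are pooled into decile bins; within each bin the
    larger set is sampled without replacement to the smaller set's bin
    count.  Raises when the rate supports are disjoint (matching
    infeasible).
    """
    rng = rng or np.random.default_rng(0)
    a_v, a_r = np.asarray(values_a, float), np.asarray(rates_a, float)
    b_v, b_r = np.asarray(values_b, float), np.asarray(rates_b, float)
    if a_r.min() > b_r.max() or b_r.min() > a_r.max():
        raise ValueError("disjoint rate supports: matching infeasible")
    swap = a_v.size < b_v.size
    if swap:
        a_v, a_r, b_v, b_r = b_v, b_r, a_v, a_r
    # a is now the larger set, downsampled to match b's rate histogram
    pooled = np.concatenate([a_r, b_r])
    edges = np.quantile(pooled, np.linspace(0, 1, n_bins + 1))
    edges[0] -= 1e-9
    edges[-1] += 1e-9
    a_bin = np.clip(np.searchsorted(edges, a_r, side="right") - 1, 0, n_bins - 1)
    b_bin = np.clip(np.searchsorted(edges, b_r, side="right") - 1, 0, n_bins - 1)
    out = np.empty(n_resamples)
    for k in range(n_resamples):
        chosen = []
        for bb in range(n_bins):
            need = int(np.sum(b_bin == bb))
            pool = np.flatnonzero(a_bin == bb)
            if need == 0:
                continue
            if pool.size == 0:
                # fall back to nearest-rate neighbors outside the bin
                target = 0.5 * (edges[bb] + edges[bb + 1])
                pool = np.argsort(np.abs(a_r - target))[: max(need * 2, need)]
            take = pool if pool.size <= need else rng.choice(pool, need, replace=False)
            chosen.append(take)
        idx = np.concatenate(chosen) if chosen else np.empty(0, dtype=int)
        out[k] = statistic(a_v[idx]) if idx.size else np.nan
    return out
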