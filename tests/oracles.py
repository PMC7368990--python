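"""Independent brute-force oracles used by the test suite.

Each oracle is deliberately coded differently from the package
implementation (explicit loops, convolution instead of closed forms, exact
rational arithmetic) so that agreement is evidence of correctness rather
than shared code.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
from scipy.stats import nbinom, poisson


def _avg_rank(values: np.ndarray) -> np.ndarray:
    """Average ranks (1-based) computed by counting, not by library call."""
    out = np.empty(len(values))
    for i, v in enumerate(values):
        less = int(np.sum(values < v))
        equal = int(np.sum(values == v))
        out[i] = less + (equal + 1) / 2.0
    return out


def tmm_factors_oracle(
    counts: np.ndarray, trim_m: float = 0.30, trim_a: float = 0.05
) -> np.ndarray:
    """Brute-force TMM factors (geometric mean 1) for a genes x samples matrix."""
    lib = counts.sum(axis=0)
    q75 = np.array([np.quantile(counts[:, j], 0.75) for j in range(counts.shape[1])]) / lib
    ref_j = int(np.argmin(np.abs(q75 - q75.mean())))
    factors = []
    for j in range(counts.shape[1]):
        obs, ref = counts[:, j].astype(float), counts[:, ref_j].astype(float)
        n_o, n_r = obs.sum(), ref.sum()
        m_list, a_list, w_list = [], [], []
        for g in range(len(obs)):
            if obs[g] > 0 and ref[g] > 0:
                m = np.log2((obs[g] / n_o) / (ref[g] / n_r))
                a = 0.5 * (np.log2(obs[g] / n_o) + np.log2(ref[g] / n_r))
                v = (n_o - obs[g]) / (n_o * obs[g]) + (n_r - ref[g]) / (n_r * ref[g])
                m_list.append(m)
                a_list.append(a)
                w_list.append(1.0 / v)
        m_arr = np.array(m_list)
        a_arr = np.array(a_list)
        w_arr = np.array(w_list)
        if m_arr.size == 0 or np.max(np.abs(m_arr)) < 1e-6:
            factors.append(1.0)
            continue
        n = m_arr.size
        lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
        rm, ra = _avg_rank(m_arr), _avg_rank(a_arr)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if not keep.any():
            factors.append(1.0)
            continue
        f = np.sum(m_arr[keep] * w_arr[keep]) / np.sum(w_arr[keep])
        factors.append(2.0**f)
    factors = np.array(factors)
    return factors / np.exp(np.mean(np.log(factors)))


def exact_test_oracle(counts_a, counts_b, phi: float) -> float:
    """Exact conditional NB test p-value via per-replicate pmf convolution."""
    counts_a = np.asarray(counts_a)
    counts_b = np.asarray(counts_b)
    t = int(counts_a.sum() + counts_b.sum())
    if t == 0:
        return 1.0
    n_a, n_b = len(counts_a), len(counts_b)
    mu = t / (n_a + n_b)
    support = np.arange(t + 1)
    if phi == 0.0:
        single = poisson.pmf(support, mu)
    else:
        r = 1.0 / phi
        single = nbinom.pmf(support, r, r / (r + mu))

    def group_pmf(n_reps: int) -> np.ndarray:
        pmf = np.array([1.0])
        for _ in range(n_reps):
            pmf = np.convolve(pmf, single)[: t + 1]
        return pmf

    pa = group_pmf(n_a)
    pb = group_pmf(n_b)
    joint = np.array([pa[a] * pb[t - a] for a in range(t + 1)])
    joint = joint / joint.sum()
    obs = joint[int(counts_a.sum())]
    return float(min(1.0, joint[joint <= obs * (1 + 1e-9)].sum()))


def bh_oracle(pvals: np.ndarray) -> np.ndarray:
    """Step-up BH adjustment written out longhand."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = p[i] * m / rank_from_top
        running_min = min(running_min, value)
        adjusted[i] = running_min
    return adjusted


def gsea_es_oracle(metric: np.ndarray, member: np.ndarray, p: float = 1.0) -> float:
    """Enrichment score by an explicit walk down the sorted gene list."""
    order = np.argsort(-metric, kind="stable")
    m_sorted = metric[order]
    hit = member[order]
    n = len(metric)
    k = int(hit.sum())
    denom_hit = float(np.sum(np.abs(m_sorted[hit]) ** p))
    running, best, best_abs = 0.0, 0.0, -1.0
    for i in range(n):
        if hit[i]:
            running += abs(m_sorted[i]) ** p / denom_hit
        else:
            running -= 1.0 / (n - k)
        if abs(running) > best_abs:
            best_abs, best = abs(running), running
    return best


def hypergeom_upper_tail_oracle(overlap: int, universe: int, set_size: int, query: int) -> Fraction:
    """P(X >= overlap) for the hypergeometric, in exact rational arithmetic."""
    total = comb(universe, query)
    acc = Fraction(0)
    for x in range(overlap, min(set_size, query) + 1):
        acc += Fraction(comb(set_size, x) * comb(universe - set_size, query - x), total)
    return acc
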