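"""Negative-binomial exact differential-expression testing.

The count model is NB with mean/dispersion parameterization,
Var = mu + phi * mu^2; phi = 0 degenerates to Poisson. Libraries are first
equalized to a common effective size so that replicate counts within a group
are exchangeable; a single common dispersion is then estimated by maximizing
the NB conditional likelihood (conditioning on each gene's within-condition
total, which removes the mean as a nuisance parameter); and each gene is
tested with an exact conditional test on the split of its total between the
two groups. Two-sidedness follows the "sum of outcomes at most as probable
as the observed one" rule, which is well defined for the asymmetric NB-sum
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .expression import CountMatrix, NormalizationResult, cpm

__all__ = [
    "DETable",
    "DispersionEstimate",
    "equalize_libraries",
    "estimate_common_dispersion",
    "exact_nb_test",
    "log2_fold_change",
    "bh_adjust",
    "call_de",
    "run_de",
]


@dataclass
class DispersionEstimate:
    """Common NB dispersion phi (Var = mu + phi mu^2) and how it was obtained."""

    phi: float
    method: str = "conditional-ml"

    def __post_init__(self) -> None:
        if self.phi < 0:
            raise ValueError("dispersion must be non-negative")


@dataclass
class DETable:
    """Per-gene differential-expression results for one contrast in one assay."""

    table: pd.DataFrame  # columns: logFC, meanCPM, pvalue, FDR, significant
    contrast: tuple[str, str]  # (B, A): logFC is B vs A
    assay: str = ""

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    def write(self, path) -> None:
        out = self.table.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")


def equalize_libraries(
    matrix: CountMatrix, norm: NormalizationResult
) -> tuple[pd.DataFrame, pd.Series]:
    """Rescale counts to a common effective library size.

    Each sample's counts are multiplied by (geometric mean effective size /
    its effective size) and rounded half-to-even back to integers. Returns
    the adjusted counts and the per-sample scaling factors applied.
    """
    eff = norm.effective_sizes.loc[matrix.counts.columns]
    if (eff <= 0).any():
        raise ValueError("non-positive effective library size")
    common = np.exp(np.mean(np.log(eff)))
    scale = common / eff
    adjusted = matrix.counts * scale
    # numpy rint rounds half to even
    adjusted = pd.DataFrame(
        np.rint(adjusted.to_numpy()).astype(np.int64),
        index=matrix.counts.index,
        columns=matrix.counts.columns,
    )
    return adjusted, scale


def _conditional_loglik(counts: np.ndarray, r: float) -> float:
    """NB conditional log-likelihood of replicate counts given their total.

    For n iid NB(r, p) counts y_i with total z the distribution of the vector
    given z is free of p:
    P(y|z) = prod_i C(y_i+r-1, y_i) / C(z + n r - 1, z).
    ``counts`` is genes x replicates for one condition.
    """
    n = counts.shape[1]
    z = counts.sum(axis=1)
    ll = (
        gammaln(counts + r).sum(axis=1)
        - counts.shape[1] * gammaln(r)
        - gammaln(counts + 1).sum(axis=1)
    )
    ll -= gammaln(z + n * r) - gammaln(n * r) - gammaln(z + 1)
    return float(ll.sum())


def estimate_common_dispersion(
    adjusted: pd.DataFrame,
    conditions: pd.Series,
    bounds: tuple[float, float] = (1e-6, 10.0),
    grid_points: int = 25,
) -> DispersionEstimate:
    """Common dispersion by maximizing the summed conditional log-likelihood.

    The likelihood is summed over genes and over every condition with >= 2
    replicates; a log-spaced grid brackets the maximum, refined by
    golden-section search.
    """
    conditions = conditions.loc[adjusted.columns]
    groups = []
    for cond in conditions.unique():
        cols = conditions.index[conditions == cond]
        if len(cols) >= 2:
            arr = adjusted[list(cols)].to_numpy(dtype=float)
            groups.append(arr[arr.sum(axis=1) > 0])
    if not groups:
        raise ValueError("dispersion not estimable: no condition has replicates")

    def negll(log_phi: float) -> float:
        r = 1.0 / np.exp(log_phi)
        return -sum(_conditional_loglik(g, r) for g in groups)

    lo, hi = np.log(bounds[0]), np.log(bounds[1])
    grid = np.linspace(lo, hi, grid_points)
    vals = np.array([negll(x) for x in grid])
    i = int(np.argmin(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, grid_points - 1)]
    if i in (0, grid_points - 1):
        phi = float(np.exp(grid[i]))
    else:
        res = minimize_scalar(negll, bracket=(a, grid[i], b), method="golden")
        phi = float(np.exp(np.clip(res.x, lo, hi)))
    return DispersionEstimate(phi=phi)


def _nb_sum_logpmf(x: np.ndarray, n: int, mu: float, phi: float) -> np.ndarray:
    """log pmf of the sum of n iid NB(mean mu, dispersion phi) at values x.

    The sum of n iid NB(size r, prob p) is NB(size n*r, prob p); phi=0 is the
    Poisson limit (sum ~ Poisson(n*mu)).
    """
    x = np.asarray(x, dtype=float)
    if phi == 0.0:
        lam = n * mu
        return x * np.log(lam) - lam - gammaln(x + 1)
    r = n / phi  # size of the sum
    log_p = np.log(r) - np.log(r + n * mu)  # log prob of "success" (size param)
    log_q = np.log(n * mu) - np.log(r + n * mu)
    return gammaln(x + r) - gammaln(r) - gammaln(x + 1) + r * log_p + x * log_q


def exact_nb_test(
    counts_a: np.ndarray, counts_b: np.ndarray, phi: float
) -> float:
    """Exact conditional NB test for a difference in means between two groups.

    Conditional on the total t = sum(A) + sum(B), the p-value is the sum of
    probabilities of all splits (a, t - a) whose point probability does not
    exceed that of the observed split, group-sum probabilities taken from the
    NB-sum distribution with common mean t / (nA + nB) per sample.
    """
    counts_a = np.asarray(counts_a)
    counts_b = np.asarray(counts_b)
    n_a, n_b = len(counts_a), len(counts_b)
    sa, sb = int(counts_a.sum()), int(counts_b.sum())
    t = sa + sb
    if t == 0:
        return 1.0
    mu = t / (n_a + n_b)
    a_vals = np.arange(t + 1)
    log_pa = _nb_sum_logpmf(a_vals, n_a, mu, phi)
    log_pb = _nb_sum_logpmf(t - a_vals, n_b, mu, phi)
    log_joint = log_pa + log_pb
    log_joint -= logsumexp(log_joint)
    obs = log_joint[sa]
    keep = log_joint <= obs + 1e-10  # tolerate float ties
    return float(min(1.0, np.exp(logsumexp(log_joint[keep]))))


def log2_fold_change(
    counts_a: np.ndarray | pd.DataFrame,
    counts_b: np.ndarray | pd.DataFrame,
    prior_count: float = 0.5,
    axis: int | None = None,
):
    """log2((mean(B) + prior) / (mean(A) + prior)) on equalized counts."""
    if prior_count < 0:
        raise ValueError("prior count must be non-negative")
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    mean_a = a.mean(axis=-1 if axis is None else axis)
    mean_b = b.mean(axis=-1 if axis is None else axis)
    return np.log2((mean_b + prior_count) / (mean_a + prior_count))


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment."""
    p = np.asarray(pvals, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-values")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def call_de(table: pd.DataFrame, fdr_cut: float = 0.01, lfc_cut: float = 1.0) -> pd.Series:
    """Significance rule: FDR < fdr_cut and |log2FC| > lfc_cut."""
    return (table["FDR"] < fdr_cut) & (table["logFC"].abs() > lfc_cut)


def run_de(
    matrix: CountMatrix,
    norm: NormalizationResult,
    condition_b: str,
    condition_a: str,
    phi: float | None = None,
    fdr_cut: float = 0.01,
    lfc_cut: float = 1.0,
    prior_count: float = 0.5,
) -> tuple[DETable, DispersionEstimate]:
    """Full DE analysis of one contrast (B vs A) within one assay's matrix."""
    adjusted, _ = equalize_libraries(matrix, norm)
    conditions = matrix.samples["condition"]
    if phi is None:
        disp = estimate_common_dispersion(adjusted, conditions)
    else:
        disp = DispersionEstimate(phi=phi, method="given")
    cols_a = matrix.condition_samples(condition_a)
    cols_b = matrix.condition_samples(condition_b)
    if not cols_a or not cols_b:
        raise ValueError(f"contrast conditions not found: {condition_b} vs {condition_a}")
    arr_a = adjusted[cols_a].to_numpy()
    arr_b = adjusted[cols_b].to_numpy()
    lfc = log2_fold_change(arr_a, arr_b, prior_count=prior_count, axis=1)
    pvals = np.array(
        [exact_nb_test(arr_a[g], arr_b[g], disp.phi) for g in range(arr_a.shape[0])]
    )
    mean_cpm = cpm(matrix, norm.effective_sizes)[cols_a + cols_b].mean(axis=1)
    table = pd.DataFrame(
        {
            "logFC": lfc,
            "meanCPM": mean_cpm.to_numpy(),
            "pvalue": pvals,
            "FDR": bh_adjust(pvals),
        },
        index=matrix.gene_ids,
    )
    table["significant"] = call_de(table, fdr_cut, lfc_cut)
    return DETable(table=table, contrast=(condition_b, condition_a), assay=str(
        matrix.samples["assay"].iloc[0]
    )), disp
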