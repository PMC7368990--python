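"""Translation-efficiency analysis.

Two complementary views of translational control:

* a *global* summary — the slope of log2(RPF RPKM) on log2(RNA RPKM) across
  genes within one condition, with its 95% confidence interval; a slope above
  1 indicates that highly transcribed genes are translated disproportionately
  well;
* a *per-gene* differential test — the difference between the RPF and RNA
  log2 fold changes of a contrast (delta TE), with a delta-method Wald test.

For the Wald test, the variance of a log2 fold change of NB group means is
approximated as Var(log2 mean) ~= (1/ln2^2) * (1/mu + phi) / n summed over
the two groups of the contrast, which requires only quantities the DE stage
already produces (group means and the common dispersion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .de import DETable, bh_adjust

LN2_SQ = np.log(2.0) ** 2

__all__ = ["SlopeResult", "DTETable", "global_te_slope", "te_per_gene", "differential_te"]


@dataclass
class SlopeResult:
    """OLS slope of log2 RPF abundance on log2 RNA abundance with 95% CI."""

    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    n_genes: int
    r_squared: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.slope <= self.ci_high):
            raise ValueError("CI must bracket the slope")


@dataclass
class DTETable:
    """Per-gene differential translation efficiency for one contrast."""

    table: pd.DataFrame  # lfc_rna, lfc_rpf, delta_te, se, z, pvalue, FDR
    contrast: tuple[str, str]

    def write(self, path) -> None:
        out = self.table.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")


def global_te_slope(
    rpkm_rna: pd.DataFrame | np.ndarray,
    rpkm_rpf: pd.DataFrame | np.ndarray,
    genes=None,
    pseudocount: float = 0.01,
) -> SlopeResult:
    """Regress log2(RPF RPKM + c) on log2(RNA RPKM + c) over genes.

    Inputs are replicate-averaged RPKM vectors (or matrices whose rows are
    averaged) for one condition. The 95% CI is slope +/- t(0.975, n-2) * SE.
    """
    x = np.asarray(rpkm_rna, dtype=float)
    y = np.asarray(rpkm_rpf, dtype=float)
    if x.ndim == 2:
        x = x.mean(axis=1)
    if y.ndim == 2:
        y = y.mean(axis=1)
    if genes is not None:
        genes = np.asarray(genes)
        x, y = x[genes], y[genes]
    if x.shape != y.shape:
        raise ValueError("RNA and RPF vectors must align")
    n = x.size
    if n < 3:
        raise ValueError("slope requires at least 3 genes")
    lx = np.log2(x + pseudocount)
    ly = np.log2(y + pseudocount)
    fit = stats.linregress(lx, ly)
    half = stats.t.ppf(0.975, n - 2) * fit.stderr
    return SlopeResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        ci_low=float(fit.slope - half),
        ci_high=float(fit.slope + half),
        n_genes=int(n),
        r_squared=float(fit.rvalue**2),
    )


def te_per_gene(
    cpm_rna: pd.DataFrame,
    cpm_rpf: pd.DataFrame,
    samples_rna: pd.Series | None = None,
    samples_rpf: pd.Series | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """log2 translation efficiency per gene per condition.

    TE = log2((mean RPF CPM + c) / (mean RNA CPM + c)), the mean taken over
    a condition's replicates. Without grouping metadata all columns of each
    matrix are averaged into a single condition.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if not cpm_rna.index.equals(cpm_rpf.index):
        raise ValueError("gene sets differ between RNA and RPF")
    if samples_rna is None or samples_rpf is None:
        rna_means = {"all": cpm_rna.mean(axis=1)}
        rpf_means = {"all": cpm_rpf.mean(axis=1)}
    else:
        rna_means = {
            cond: cpm_rna[list(samples_rna.index[samples_rna == cond])].mean(axis=1)
            for cond in samples_rna.unique()
        }
        rpf_means = {
            cond: cpm_rpf[list(samples_rpf.index[samples_rpf == cond])].mean(axis=1)
            for cond in samples_rpf.unique()
        }
    out = {}
    for cond in rna_means:
        if cond not in rpf_means:
            raise ValueError(f"condition {cond!r} missing from RPF samples")
        out[cond] = np.log2(
            (rpf_means[cond] + pseudocount) / (rna_means[cond] + pseudocount)
        )
    return pd.DataFrame(out)


def _lfc_variance(
    mean_a: np.ndarray, mean_b: np.ndarray, n_a: int, n_b: int, phi: float,
    prior: float = 0.5,
) -> np.ndarray:
    """Delta-method variance of the log2 fold change of two NB group means."""
    mu_a = np.maximum(mean_a, 0.0) + prior
    mu_b = np.maximum(mean_b, 0.0) + prior
    return (1.0 / LN2_SQ) * ((1.0 / mu_a + phi) / n_a + (1.0 / mu_b + phi) / n_b)


def differential_te(
    de_rna: DETable,
    de_rpf: DETable,
    dispersion_rna: float,
    dispersion_rpf: float,
    means_rna: tuple[np.ndarray, np.ndarray],
    means_rpf: tuple[np.ndarray, np.ndarray],
    n_rna: tuple[int, int],
    n_rpf: tuple[int, int],
) -> DTETable:
    """Wald test of delta TE = lfc_RPF - lfc_RNA for one contrast.

    ``means_*`` are the (group A, group B) per-gene mean equalized counts for
    each assay; ``n_*`` the replicate numbers. The two assays' fold-change
    variances add because the libraries are independent.
    """
    if not de_rna.table.index.equals(de_rpf.table.index):
        raise ValueError("gene sets differ between RNA and RPF tables")
    if de_rna.contrast != de_rpf.contrast:
        raise ValueError("contrasts differ between RNA and RPF tables")
    lfc_rna = de_rna.table["logFC"].to_numpy()
    lfc_rpf = de_rpf.table["logFC"].to_numpy()
    delta = lfc_rpf - lfc_rna
    var = _lfc_variance(
        means_rna[0], means_rna[1], n_rna[0], n_rna[1], dispersion_rna
    ) + _lfc_variance(means_rpf[0], means_rpf[1], n_rpf[0], n_rpf[1], dispersion_rpf)
    se = np.sqrt(var)
    z = np.where(se > 0, delta / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    table = pd.DataFrame(
        {
            "lfc_rna": lfc_rna,
            "lfc_rpf": lfc_rpf,
            "delta_te": delta,
            "se": se,
            "z": z,
            "pvalue": p,
            "FDR": bh_adjust(p),
        },
        index=de_rna.table.index,
    )
    return DTETable(table=table, contrast=de_rna.contrast)
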