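"""Transcription/translation decoupling classification.

A gene whose ribosome-footprint (RPF) fold change departs from its mRNA fold
change by more than a tolerance band (default +/-1 log2 unit) is regulated at
the level of translation. Genes significant in both assays whose fold changes
agree within the band are transcriptionally driven; the rest are unchanged.

Two rule variants are available: the *literal* one classifies purely by the
fold-change band, while the *guarded* default additionally requires
differential-expression significance in the relevant assay so that
noise-driven fold-change differences among unexpressed genes are not called.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .de import DETable

TRANSCRIPTIONAL = "TRANSCRIPTIONAL"
TE_UP = "TE_UP"
TE_DOWN = "TE_DOWN"
UNCHANGED = "UNCHANGED"

CLASSES = (TRANSCRIPTIONAL, TE_UP, TE_DOWN, UNCHANGED)

__all__ = [
    "RegulationCalls",
    "ScatterGroups",
    "classify_regulation",
    "decoupled_fraction",
    "scatter_expression_groups",
    "compare_foldchanges",
    "TRANSCRIPTIONAL",
    "TE_UP",
    "TE_DOWN",
    "UNCHANGED",
]


@dataclass
class RegulationCalls:
    """Per-gene regulation class with supporting statistics and class counts."""

    table: pd.DataFrame  # class, lfc_rna, lfc_rpf, delta, sig_rna, sig_rpf[, dte_fdr]
    band: float
    mode: str

    @property
    def class_counts(self) -> pd.Series:
        return self.table["class"].value_counts().reindex(CLASSES, fill_value=0)

    def write(self, path) -> None:
        out = self.table.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")


@dataclass
class ScatterGroups:
    """Fig-style expression scatter groups among high-transcription genes."""

    groups: pd.Series  # RED / BLUE / GREEN / NONE per gene
    high_q: float
    residual_q: float


def classify_regulation(
    de_rna: DETable,
    de_rpf: DETable,
    band: float = 1.0,
    mode: str = "guarded",
    dte_fdr: pd.Series | None = None,
) -> RegulationCalls:
    """Classify each gene as TRANSCRIPTIONAL, TE_UP, TE_DOWN or UNCHANGED.

    Rules, applied in order (guarded mode):

    a. neither assay significant -> UNCHANGED;
    b. delta = lfc_rpf - lfc_rna > band and RPF significant -> TE_UP;
    c. delta < -band and (RNA or RPF significant) -> TE_DOWN;
    d. both significant and |delta| <= band -> TRANSCRIPTIONAL;
    e. otherwise UNCHANGED.

    ``mode="literal"`` drops the significance guards on rules b/c, so the
    band alone decides TE_UP/TE_DOWN among genes significant in either assay.
    """
    if mode not in ("guarded", "literal"):
        raise ValueError(f"unknown mode {mode!r}")
    if not de_rna.table.index.equals(de_rpf.table.index):
        raise ValueError("gene universes differ between RNA and RPF tables")
    lfc_rna = de_rna.table["logFC"].to_numpy()
    lfc_rpf = de_rpf.table["logFC"].to_numpy()
    sig_rna = de_rna.table["significant"].to_numpy(dtype=bool)
    sig_rpf = de_rpf.table["significant"].to_numpy(dtype=bool)
    delta = lfc_rpf - lfc_rna
    any_sig = sig_rna | sig_rpf

    cls = np.full(lfc_rna.shape, UNCHANGED, dtype=object)
    if mode == "guarded":
        up = any_sig & (delta > band) & sig_rpf
        down = any_sig & (delta < -band) & (sig_rna | sig_rpf)
    else:
        up = any_sig & (delta > band)
        down = any_sig & (delta < -band)
    trans = any_sig & ~up & ~down & sig_rna & sig_rpf & (np.abs(delta) <= band)
    cls[up] = TE_UP
    cls[down] = TE_DOWN
    cls[trans] = TRANSCRIPTIONAL

    table = pd.DataFrame(
        {
            "class": cls,
            "lfc_rna": lfc_rna,
            "lfc_rpf": lfc_rpf,
            "delta": delta,
            "sig_rna": sig_rna,
            "sig_rpf": sig_rpf,
        },
        index=de_rna.table.index,
    )
    if dte_fdr is not None:
        table["dte_fdr"] = dte_fdr.loc[table.index].to_numpy()
    return RegulationCalls(table=table, band=band, mode=mode)


def decoupled_fraction(calls: RegulationCalls) -> float:
    """Fraction of classified-significant genes regulated at translation.

    |TE_UP u TE_DOWN| / |TE_UP u TE_DOWN u TRANSCRIPTIONAL|; NaN when no
    gene falls in any of the three classes.
    """
    counts = calls.class_counts
    decoupled = counts[TE_UP] + counts[TE_DOWN]
    denom = decoupled + counts[TRANSCRIPTIONAL]
    if denom == 0:
        return float("nan")
    return float(decoupled / denom)


def scatter_expression_groups(
    rpkm_rna: np.ndarray | pd.Series,
    rpkm_rpf: np.ndarray | pd.Series,
    high_q: float = 0.90,
    residual_q: float = 0.05,
    pseudocount: float = 0.01,
) -> ScatterGroups:
    """Expression-scatter groups among highly transcribed genes.

    Genes above the ``high_q`` quantile of RNA RPKM are "high transcription".
    Within that set, genes whose residual from the global log-log regression
    is below the ``residual_q`` residual quantile are RED (low translation),
    above the 1 - residual_q quantile BLUE (very high translation), and the
    remainder GREEN. Quantile thresholds are computed within the
    high-transcription set; comparisons are strict, so residual_q -> 0
    empties RED and BLUE.
    """
    if not (0 < high_q < 1) or not (0 <= residual_q < 0.5):
        raise ValueError("quantiles out of range")
    index = rpkm_rna.index if isinstance(rpkm_rna, pd.Series) else None
    x = np.log2(np.asarray(rpkm_rna, dtype=float) + pseudocount)
    y = np.log2(np.asarray(rpkm_rpf, dtype=float) + pseudocount)
    fit = stats.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    high = np.asarray(rpkm_rna, dtype=float) > np.quantile(
        np.asarray(rpkm_rna, dtype=float), high_q
    )
    groups = np.full(x.shape, "NONE", dtype=object)
    if high.any():
        r_high = resid[high]
        lo = np.quantile(r_high, residual_q)
        hi = np.quantile(r_high, 1 - residual_q)
        sub = np.full(r_high.shape, "GREEN", dtype=object)
        sub[r_high < lo] = "RED"
        sub[r_high > hi] = "BLUE"
        groups[high] = sub
    return ScatterGroups(
        groups=pd.Series(groups, index=index), high_q=high_q, residual_q=residual_q
    )


def compare_foldchanges(
    lfc_a: pd.Series, lfc_b: pd.Series
) -> tuple[float, float, int]:
    """Pearson correlation of two per-gene log2 fold-change vectors.

    Used to check concordance of fold changes against an external platform
    (e.g. microarray). Returns (r, two-sided p, n shared genes).
    """
    shared = lfc_a.index.intersection(lfc_b.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared genes")
    a = lfc_a.loc[shared].to_numpy(dtype=float)
    b = lfc_b.loc[shared].to_numpy(dtype=float)
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in fold changes")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p), int(len(shared))
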