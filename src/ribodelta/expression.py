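"""Count-matrix container, CPM/RPKM, expression filters, and TMM normalization.

The container couples a genes x samples integer count table with per-sample
metadata (condition, replicate, assay) as produced by a ribosome-profiling +
RNA-seq experiment, where each biological sample is sequenced twice: once as
total RNA and once as ribosome-protected fragments (RPFs).

TMM (trimmed mean of M-values) is implemented from scratch: between-sample
scale factors are estimated from gene-wise log-ratios (M) against a reference
sample after double trimming on M and on average log-abundance (A), with
inverse-variance (delta-method) weights, and rescaled to geometric mean 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

RNA = "RNA"
RPF = "RPF"

__all__ = [
    "CountMatrix",
    "NormalizationResult",
    "read_count_matrix",
    "cpm",
    "rpkm",
    "filter_expressed",
    "presence_flags",
    "tmm_normalize",
]


@dataclass
class CountMatrix:
    """Gene x sample integer counts plus sample metadata.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, index = gene ids (unique),
        columns = sample names.
    samples
        DataFrame indexed by sample name with columns ``condition``,
        ``replicate`` and ``assay`` (one of ``"RNA"``/``"RPF"``), aligned
        with the count columns.
    gene_lengths
        Optional Series of positive transcript lengths in nucleotides,
        indexed like ``counts``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    gene_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        vals = self.counts.to_numpy()
        if not np.isfinite(vals).all():
            raise ValueError("counts must be finite")
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.array_equal(vals, np.rint(vals)):
            raise ValueError("counts must be integers")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples missing metadata: {sorted(missing)}")
        for col in ("condition", "replicate", "assay"):
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata lacks column {col!r}")
        # keep metadata aligned to count columns
        self.samples = self.samples.loc[list(self.counts.columns)]
        if self.gene_lengths is not None:
            self.gene_lengths = self.gene_lengths.loc[self.counts.index]
            if (self.gene_lengths <= 0).any():
                raise ValueError("gene lengths must be positive")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def condition_samples(self, condition: str) -> list[str]:
        return list(self.samples.index[self.samples["condition"] == condition])

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for c in self.samples["condition"]:
            if c not in seen:
                seen.append(c)
        return seen

    def subset_genes(self, genes) -> "CountMatrix":
        lengths = None if self.gene_lengths is None else self.gene_lengths.loc[genes]
        return CountMatrix(self.counts.loc[genes], self.samples.copy(), lengths)

    def write(self, counts_path: str | Path, metadata_path: str | Path) -> None:
        out = self.counts.copy()
        out.index.name = "gene_id"
        out.to_csv(counts_path, sep="\t")
        meta = self.samples.copy()
        meta.index.name = "sample"
        meta.to_csv(metadata_path, sep="\t")


@dataclass
class NormalizationResult:
    """Per-sample TMM scale factors and effective library sizes."""

    factors: pd.Series
    library_sizes: pd.Series
    reference: str

    @property
    def effective_sizes(self) -> pd.Series:
        return self.library_sizes * self.factors

    def write(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "factor": self.factors,
                "library_size": self.library_sizes,
                "effective_size": self.effective_sizes,
            }
        )
        df.index.name = "sample"
        df.to_csv(path, sep="\t")


def read_count_matrix(
    path: str | Path,
    metadata_path: str | Path,
    lengths_path: str | Path | None = None,
) -> CountMatrix:
    """Read a TSV count matrix (gene_id + one column per sample) and metadata.

    Raises ``ValueError`` naming the offending gene on duplicate ids and the
    offending cell on non-integer counts.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate gene id: {dup!r}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number) or not np.array_equal(arr, np.rint(arr)):
        bad = np.argwhere(arr != np.rint(arr))
        if bad.size:
            g, s = bad[0]
            raise ValueError(
                f"non-integer count at gene {df.index[g]!r}, sample {df.columns[s]!r}"
            )
        raise ValueError("non-numeric counts in matrix")
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
    lengths = None
    if lengths_path is not None:
        lengths = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
    return CountMatrix(df.astype(np.int64), meta, lengths)


def cpm(matrix: CountMatrix, effective_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million: count / library size * 1e6.

    With ``effective_sizes`` (e.g. TMM-adjusted) those replace the raw library
    sizes.
    """
    sizes = matrix.library_sizes if effective_sizes is None else effective_sizes
    sizes = sizes.loc[matrix.counts.columns]
    if (sizes <= 0).any():
        bad = sizes.index[sizes <= 0][0]
        raise ValueError(f"non-positive library size for sample {bad!r}")
    return matrix.counts / sizes * 1e6


def rpkm(matrix: CountMatrix, effective_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads; requires gene lengths."""
    if matrix.gene_lengths is None:
        raise ValueError("gene lengths required for RPKM")
    kb = matrix.gene_lengths / 1e3
    return cpm(matrix, effective_sizes).div(kb, axis=0)


def filter_expressed(
    matrix: CountMatrix,
    threshold_cpm: float = 1.0,
    scope: str = "any_condition",
    effective_sizes: pd.Series | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Expression filter: CPM >= threshold in every replicate of a condition.

    A gene is detected in a condition when its CPM reaches ``threshold_cpm``
    in all of that condition's replicates. ``scope="any_condition"`` keeps
    genes detected in at least one condition; ``scope="all_conditions"``
    requires detection everywhere.

    Returns
    -------
    (mask, detected)
        ``mask``: boolean Series over genes (True = retained);
        ``detected``: boolean genes x conditions DataFrame of detection flags.
    """
    if threshold_cpm < 0:
        raise ValueError("threshold must be non-negative")
    if scope not in ("any_condition", "all_conditions"):
        raise ValueError(f"unknown scope {scope!r}")
    c = cpm(matrix, effective_sizes)
    detected = {}
    for cond in matrix.conditions:
        cols = matrix.condition_samples(cond)
        detected[cond] = (c[cols] >= threshold_cpm).all(axis=1)
    det = pd.DataFrame(detected)
    mask = det.any(axis=1) if scope == "any_condition" else det.all(axis=1)
    return mask, det


def presence_flags(
    rpkm_matrix: pd.DataFrame, samples: pd.DataFrame, threshold: float = 1.0
) -> pd.DataFrame:
    """Gene-presence calls per condition: RPKM > threshold in all replicates."""
    flags = {}
    for cond in samples["condition"].unique():
        cols = samples.index[samples["condition"] == cond]
        missing = [c for c in cols if c not in rpkm_matrix.columns]
        if missing:
            raise ValueError(f"RPKM matrix lacks samples {missing}")
        flags[cond] = (rpkm_matrix[list(cols)] > threshold).all(axis=1)
    return pd.DataFrame(flags)


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    trim_m: float,
    trim_a: float,
) -> float:
    """TMM factor of one sample against the reference (log2 scale -> 2^f).

    Genes with a zero in either sample are dropped (no pseudocount); the
    remaining M values are trimmed by rank (30% each side by default), A
    values by 5% each side, and averaged with inverse approximate variance
    weights w = (N-y)/(N*y) summed over the pair.
    """
    n_obs = obs.sum()
    n_ref = ref.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / n_obs) / (ref / n_ref))
        abs_e = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2
        v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    finite = np.isfinite(log_r) & np.isfinite(abs_e)
    log_r, abs_e, v = log_r[finite], abs_e[finite], v[finite]
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(log_r)
    rank_a = rankdata(abs_e)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(2.0**f)


def tmm_normalize(
    matrix: CountMatrix,
    reference: str | None = None,
    trim_M: float = 0.30,
    trim_A: float = 0.05,
) -> NormalizationResult:
    """Trimmed-mean-of-M-values normalization factors for all samples.

    The reference defaults to the sample whose 75th percentile of
    count/library-size is closest to the mean 75th percentile. Factors are
    rescaled so their geometric mean is exactly 1.
    """
    counts = matrix.counts.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        bad = matrix.counts.columns[lib == 0][0]
        raise ValueError(f"sample {bad!r} has all-zero counts")
    if counts.shape[1] < 2:
        raise ValueError("TMM requires at least two samples")
    names = list(matrix.counts.columns)
    if reference is None:
        q75 = np.quantile(counts, 0.75, axis=0) / lib
        reference = names[int(np.argmin(np.abs(q75 - q75.mean())))]
    ref_idx = names.index(reference)
    ref = counts[:, ref_idx]
    factors = np.array(
        [_tmm_pair_factor(counts[:, j], ref, trim_M, trim_A) for j in range(len(names))]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return NormalizationResult(
        factors=pd.Series(factors, index=names),
        library_sizes=pd.Series(lib, index=names),
        reference=reference,
    )
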