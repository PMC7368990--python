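"""Gene-set enrichment: preranked GSEA and hypergeometric over-representation.

The preranked GSEA statistic is the classic weighted Kolmogorov-Smirnov
running sum over a gene list sorted by a real-valued metric (e.g. a DE or
differential-TE statistic): hits increment by |metric|^p normalized to sum 1
over the set, misses decrement by 1/(N - k). The enrichment score (ES) is the
signed maximum deviation from zero; significance comes from permuting set
membership (random gene sets of equal size), appropriate when the input is a
preranked statistic rather than per-sample expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .de import bh_adjust

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "read_gmt",
    "write_gmt",
    "gsea_preranked",
    "ora_hypergeometric",
]


@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions (GMT semantics)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __iter__(self):
        return iter(self.sets.items())

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class EnrichmentResult:
    """GSEA result for one set against one ranking."""

    set_name: str
    es: float
    nes: float
    pvalue: float
    direction: str  # "left" (enriched at the top) or "right"
    overlap: int


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a tab-separated GMT file (name, description, members...)."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: fewer than 3 fields")
            name, desc, *members = fields
            if name in sets:
                raise ValueError(f"duplicate gene set name {name!r}")
            sets[name] = [m for m in members if m]
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def _running_sum(metric_sorted: np.ndarray, member_mask: np.ndarray, p: float) -> np.ndarray:
    """Weighted KS running sum along an already-sorted ranking."""
    n = metric_sorted.size
    k = int(member_mask.sum())
    weights = np.abs(metric_sorted) ** p
    hit_norm = weights[member_mask].sum()
    steps = np.where(
        member_mask,
        weights / hit_norm if hit_norm > 0 else 0.0,
        -1.0 / (n - k),
    )
    return np.cumsum(steps)


def _es_from_running(running: np.ndarray) -> tuple[float, int]:
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), i


def gsea_preranked(
    ranking: pd.Series,
    gene_set: list[str] | set[str],
    n_perm: int = 1000,
    p: float = 1.0,
    seed: int | None = None,
) -> EnrichmentResult:
    """Preranked GSEA of one gene set against a per-gene metric.

    ``ranking`` maps gene id to a finite real statistic; genes are sorted
    descending. The null distribution is the ES of ``n_perm`` uniformly drawn
    member sets of equal size; p = (1 + #{|ES_perm| >= |ES|}) / (n_perm + 1);
    NES divides ES by the mean |ES_perm| of the same sign. Direction reports
    whether the extreme of the running sum falls in the left (top) or right
    half of the list.
    """
    metric = ranking.to_numpy(dtype=float)
    if not np.isfinite(metric).all():
        raise ValueError("ranking metric must be finite")
    order = np.argsort(-metric, kind="stable")
    genes_sorted = ranking.index.to_numpy()[order]
    metric_sorted = metric[order]
    member_mask = np.isin(genes_sorted, list(gene_set))
    k = int(member_mask.sum())
    n = metric_sorted.size
    if k == 0:
        raise ValueError("set not represented in ranking")
    if k == n:
        raise ValueError("set covers the entire ranking; ES undefined")
    running = _running_sum(metric_sorted, member_mask, p)
    es, argmax = _es_from_running(running)

    rng = np.random.default_rng(seed)
    # vectorized permutation null: each row is a uniform size-k member set
    picks = np.argsort(rng.random((n_perm, n)), axis=1)[:, :k]
    masks = np.zeros((n_perm, n), dtype=bool)
    np.put_along_axis(masks, picks, True, axis=1)
    weights = np.abs(metric_sorted) ** p
    hit_norm = (masks * weights).sum(axis=1, keepdims=True)
    steps = np.where(masks, weights / np.where(hit_norm > 0, hit_norm, 1.0), -1.0 / (n - k))
    running_perm = np.cumsum(steps, axis=1)
    idx = np.argmax(np.abs(running_perm), axis=1)
    es_perm = running_perm[np.arange(n_perm), idx]
    pval = (1.0 + np.sum(np.abs(es_perm) >= abs(es))) / (n_perm + 1.0)
    same_sign = es_perm[np.sign(es_perm) == np.sign(es)] if es != 0 else es_perm
    denom = np.mean(np.abs(same_sign)) if same_sign.size else np.mean(np.abs(es_perm))
    nes = es / denom if denom > 0 else 0.0
    return EnrichmentResult(
        set_name="",
        es=es,
        nes=float(nes),
        pvalue=float(pval),
        direction="left" if argmax < n / 2 else "right",
        overlap=k,
    )


def ora_hypergeometric(
    query: set[str] | list[str],
    universe: set[str] | list[str],
    collection: GeneSetCollection,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each set in a query gene list.

    p is the upper tail P(X >= overlap) for X ~ Hypergeom(|universe|,
    |set n universe|, |query|); fold enrichment compares the overlap rate in
    the query with the set's rate in the universe. BH FDR across sets.
    """
    query = set(query)
    universe = set(universe)
    if not query <= universe:
        raise ValueError("query genes must be contained in the universe")
    m = len(universe)
    q = len(query)
    rows = []
    for name, members in collection:
        in_universe = set(members) & universe
        k = len(in_universe)
        overlap = len(in_universe & query)
        if k == 0:
            pval, fold = 1.0, float("nan")
        else:
            pval = float(hypergeom.sf(overlap - 1, m, k, q))
            expected = k / m
            fold = (overlap / q) / expected if q > 0 else float("nan")
        rows.append(
            {"set": name, "size": k, "overlap": overlap, "pvalue": pval, "fold": fold}
        )
    df = pd.DataFrame(rows).set_index("set")
    df["FDR"] = bh_adjust(df["pvalue"].to_numpy())
    return df
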