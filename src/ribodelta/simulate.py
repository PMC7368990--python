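"""Synthetic joint RNA/RPF data with planted regulatory classes.

The generator emulates the study design this package analyzes: a small panel
of cell lines (3 conditions by default), each with 3 biological replicates,
sequenced as both total RNA and ribosome-protected fragments (RPFs). Genes
are planted in four classes:

* ``null`` — no change anywhere;
* ``transcriptional`` — the same log2 fold change in RNA and RPF (coupled);
* ``te_up`` / ``te_down`` — the RPF fold change exceeds / falls short of the
  RNA fold change by ``delta_te`` log2 units (decoupled, translation-level
  regulation).

Counts are negative binomial with Var = mu + phi mu^2 (phi = 0 -> Poisson);
condition effects are applied symmetrically (+/- lfc/2 around baseline) so the
planted contrast equals the stated lfc exactly. A second generator produces
polysome-fraction qPCR Cq tables with a known polysome/monosome mass split
and fraction-specific spike offsets, and a third writes GMT gene-set files
with one set planted in the te_up genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import CountMatrix, RNA, RPF
from .enrichment import GeneSetCollection
from .qpcr import CQ_COLUMNS, DEFAULT_FRACTIONS, DEFAULT_MONOSOME, DEFAULT_POLYSOME

NULL = "null"
TRANSCRIPTIONAL = "transcriptional"
TE_UP = "te_up"
TE_DOWN = "te_down"
CLASS_ORDER = (NULL, TRANSCRIPTIONAL, TE_UP, TE_DOWN)

__all__ = [
    "SimulationConfig",
    "generate_joint_counts",
    "generate_cq_table",
    "generate_gene_sets",
    "NULL",
    "TRANSCRIPTIONAL",
    "TE_UP",
    "TE_DOWN",
]


@dataclass
class SimulationConfig:
    """Parameters of the joint RNA/RPF count simulation.

    Defaults mirror the emulated study design: 3 cell lines x 3 biological
    replicates x 2 assays, NB counts, a log-normal baseline abundance
    distribution, and 2-fold (1 log2 unit) planted effects scaled up to the
    4-fold regime for the recovery studies that need them.
    """

    n_genes: int = 2000
    conditions: tuple[str, ...] = ("control", "deltaN200", "deltaC301")
    n_replicates: int = 3
    class_proportions: dict[str, float] = field(
        default_factory=lambda: {NULL: 0.60, TRANSCRIPTIONAL: 0.20, TE_UP: 0.10, TE_DOWN: 0.10}
    )
    lfc_transcriptional: float = 2.0
    delta_te: float = 2.0
    dispersion: float = 0.05
    baseline_log_mean: float = 5.7
    baseline_log_sd: float = 0.4
    baseline_te_log2_sd: float = 0.5
    library_size_range: tuple[int, int] = (800_000, 1_200_000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates per condition")
        if len(self.conditions) < 2:
            raise ValueError("need at least 2 conditions")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, not 1")
        if any(v < 0 for v in self.class_proportions.values()):
            raise ValueError("class proportions must be non-negative")
        if self.dispersion < 0 or not np.isfinite(self.dispersion):
            raise ValueError("dispersion must be finite and >= 0")
        for name in ("lfc_transcriptional", "delta_te", "baseline_log_mean",
                     "baseline_log_sd", "baseline_te_log2_sd"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise ValueError("invalid library size range")


def _class_counts(proportions: dict[str, float], n: int) -> dict[str, int]:
    """Integer class sizes matching proportions * n (largest remainder)."""
    raw = {k: proportions.get(k, 0.0) * n for k in CLASS_ORDER}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    remainders = sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)
    for k in remainders[:short]:
        counts[k] += 1
    return counts


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    if phi == 0.0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / phi, scale=mean * phi)
    return rng.poisson(lam)


def generate_joint_counts(
    config: SimulationConfig,
) -> tuple[CountMatrix, CountMatrix, pd.DataFrame]:
    """Simulate matched RNA and RPF count matrices with known ground truth.

    The second condition carries the planted per-class effects; the first and
    any further conditions are unperturbed controls. Returns the two matrices
    plus a ground-truth table with columns ``class``, ``lfc_rna``, ``lfc_rpf``
    (the true log2 fold change of the perturbed condition vs any control) and
    ``baseline_te`` (the gene's latent log2 RPF/RNA ratio).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = pd.Index([f"G{i:05d}" for i in range(n)], name="gene_id")

    counts_by_class = _class_counts(config.class_proportions, n)
    labels = np.concatenate(
        [np.full(counts_by_class[k], k, dtype=object) for k in CLASS_ORDER]
    )
    rng.shuffle(labels)

    baseline = np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd, n))
    baseline_te = rng.normal(0.0, config.baseline_te_log2_sd, n)

    # transcriptional effects carry random balanced signs so the planted
    # changes do not shift library composition in one direction
    signs = rng.choice([-1.0, 1.0], size=n)
    lfc_rna = np.where(labels == TRANSCRIPTIONAL, signs * config.lfc_transcriptional, 0.0)
    lfc_rpf = lfc_rna + np.where(
        labels == TE_UP, config.delta_te, 0.0
    ) - np.where(labels == TE_DOWN, config.delta_te, 0.0)

    truth = pd.DataFrame(
        {"class": labels, "lfc_rna": lfc_rna, "lfc_rpf": lfc_rpf, "baseline_te": baseline_te},
        index=genes,
    )

    gene_lengths = pd.Series(rng.integers(300, 5001, n), index=genes, name="length")

    lo, hi = config.library_size_range
    data: dict[str, dict[str, np.ndarray]] = {RNA: {}, RPF: {}}
    meta_rows = []
    for assay in (RNA, RPF):
        lfc = lfc_rna if assay == RNA else lfc_rpf
        te = np.zeros(n) if assay == RNA else baseline_te
        for ci, cond in enumerate(config.conditions):
            # the second condition is the perturbed line; all others are
            # controls, so the perturbed-vs-control contrast is exactly lfc
            # (symmetric +/- lfc/2 split) and control-vs-control is null
            half = 0.5 * lfc if ci == 1 else -0.5 * lfc
            rel = baseline * 2.0 ** (te + half)
            rel_frac = rel / rel.sum()
            for rep in range(1, config.n_replicates + 1):
                name = f"{cond}_{assay}_r{rep}"
                libsize = int(rng.integers(lo, hi + 1))
                data[assay][name] = _nb_draw(rng, rel_frac * libsize, config.dispersion)
                meta_rows.append(
                    {"sample": name, "condition": cond, "replicate": rep, "assay": assay}
                )

    meta = pd.DataFrame(meta_rows).set_index("sample")
    matrices = {}
    for assay in (RNA, RPF):
        counts = pd.DataFrame(data[assay], index=genes)
        matrices[assay] = CountMatrix(
            counts=counts,
            samples=meta.loc[counts.columns].copy(),
            gene_lengths=gene_lengths.copy(),
        )
    return matrices[RNA], matrices[RPF], truth


def _block_profile(
    te_ratio: float,
    fractions: tuple[int, ...],
    monosome: tuple[int, ...],
    polysome: tuple[int, ...],
) -> np.ndarray:
    """Two-block mass profile with polysome/monosome mass ratio = te_ratio."""
    q = np.zeros(len(fractions))
    mono_share = 1.0 / (1.0 + te_ratio)
    poly_share = te_ratio / (1.0 + te_ratio)
    for i, f in enumerate(fractions):
        if f in monosome:
            q[i] = mono_share / len(monosome)
        elif f in polysome:
            q[i] = poly_share / len(polysome)
    return q


def generate_cq_table(
    n_genes: int,
    te_ratio_truth: np.ndarray | float,
    noise_sd: float = 0.2,
    seed: int = 0,
    fractions: tuple[int, ...] = DEFAULT_FRACTIONS,
    monosome_fractions: tuple[int, ...] = DEFAULT_MONOSOME,
    polysome_fractions: tuple[int, ...] = DEFAULT_POLYSOME,
    n_replicates: int = 3,
    sample: str = "S1",
    profiles: np.ndarray | None = None,
    base_cq: float = 20.0,
    spike_base_cq: float = 18.0,
    offset_sd: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a polysome-fraction qPCR Cq table with known truth.

    Each gene's mass profile over the gradient is a two-block split implied
    by its true polysome/monosome ratio (or an explicit ``profiles`` row).
    Gene Cq values follow Cq = base - log2(q) plus a fraction-specific
    technical offset shared with the spike-in Cq of the same fraction and
    Gaussian noise of ``noise_sd`` cycles. Offsets are drawn mean-zero across
    fractions, so spike correction restores the noise-free truth exactly.

    Returns the long-format Cq table and a truth table (te_ratio and the
    true normalized quantity per fraction).
    """
    if len(fractions) < 2:
        raise ValueError("need at least 2 fractions")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    ratios = np.broadcast_to(np.asarray(te_ratio_truth, dtype=float), (n_genes,)).copy()
    if (ratios <= 0).any():
        raise ValueError("te_ratio_truth must be positive")
    rng = np.random.default_rng(seed)
    genes = [f"Q{i:03d}" for i in range(n_genes)]
    if profiles is None:
        profiles = np.vstack(
            [_block_profile(r, fractions, monosome_fractions, polysome_fractions)
             for r in ratios]
        )
    else:
        profiles = np.asarray(profiles, dtype=float)
        if profiles.shape != (n_genes, len(fractions)):
            raise ValueError("profiles shape must be (n_genes, n_fractions)")
        profiles = profiles / profiles.sum(axis=1, keepdims=True)

    rows = []
    for rep in range(1, n_replicates + 1):
        offsets = rng.normal(0.0, offset_sd, len(fractions))
        offsets -= offsets.mean()
        for gi, gene in enumerate(genes):
            with np.errstate(divide="ignore"):
                cq_true = base_cq - np.log2(profiles[gi])
            cq = cq_true + offsets + rng.normal(0.0, noise_sd, len(fractions))
            spike = spike_base_cq + offsets
            for fi, f in enumerate(fractions):
                rows.append(
                    {
                        "sample": sample,
                        "gene": gene,
                        "fraction": f,
                        "replicate": rep,
                        "Cq": cq[fi],
                        "spike_Cq": spike[fi],
                    }
                )
    table = pd.DataFrame(rows, columns=CQ_COLUMNS)
    truth = pd.DataFrame(
        profiles, index=pd.Index(genes, name="gene"), columns=list(fractions)
    )
    truth.insert(0, "te_ratio", ratios)
    return table, truth


def generate_gene_sets(
    truth: pd.DataFrame,
    n_decoy_sets: int = 10,
    set_size: int = 50,
    seed: int = 0,
) -> GeneSetCollection:
    """Gene sets for enrichment tests: one planted in te_up genes plus decoys.

    The planted set draws its members from the te_up class (topped up with
    random genes if the class is smaller than ``set_size``); decoy sets are
    uniform draws from all genes.
    """
    if truth.empty:
        raise ValueError("empty ground truth")
    if set_size <= 0:
        raise ValueError("set_size must be positive")
    if set_size > len(truth):
        raise ValueError("set_size exceeds number of genes")
    rng = np.random.default_rng(seed)
    genes = truth.index.to_numpy()
    te_up_genes = truth.index[truth["class"] == TE_UP].to_numpy()
    k = min(set_size, len(te_up_genes))
    planted = list(rng.choice(te_up_genes, size=k, replace=False)) if k else []
    if k < set_size:
        pool = np.setdiff1d(genes, np.array(planted, dtype=object))
        planted += list(rng.choice(pool, size=set_size - k, replace=False))
    sets = {"planted_te_up": sorted(planted)}
    descriptions = {"planted_te_up": "genes planted with increased translation efficiency"}
    for i in range(n_decoy_sets):
        name = f"decoy_{i:03d}"
        sets[name] = sorted(rng.choice(genes, size=set_size, replace=False))
        descriptions[name] = "uniform random gene set"
    return GeneSetCollection(sets=sets, descriptions=descriptions)
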