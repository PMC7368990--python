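"""Polysome-gradient qPCR quantification.

mRNAs sampled from sucrose-gradient fractions (monosome-bound at the light
end, heavily polysome-bound at the heavy end) are quantified by qPCR. Each
fraction receives a fixed mass of an in-vitro-transcribed spike-in RNA before
extraction, so per-fraction technical variation (recovery, RT efficiency) can
be removed by referencing each fraction's spike Cq to the within-sample mean
spike Cq. Relative quantities follow 2^(Cq_min - Cq); the polysome/monosome
ratio of summed quantities estimates how efficiently a transcript is
translated, and the quantity-weighted mean fraction index locates the profile
along the gradient (a right shift = more ribosomes per mRNA).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_FRACTIONS = tuple(range(7, 15))
DEFAULT_MONOSOME = (7, 8)
DEFAULT_POLYSOME = (9, 10, 11, 12, 13, 14)

__all__ = [
    "FractionProfile",
    "TEEstimate",
    "spike_correct",
    "relative_quantity",
    "fraction_profiles",
    "translation_efficiency_ratio",
    "profile_shift",
    "DEFAULT_MONOSOME",
    "DEFAULT_POLYSOME",
]

CQ_COLUMNS = ["sample", "gene", "fraction", "replicate", "Cq", "spike_Cq"]


@dataclass
class FractionProfile:
    """Relative quantities per fraction for each (sample, gene, replicate)."""

    quantities: pd.DataFrame  # index (sample, gene, replicate), columns fractions

    @property
    def normalized(self) -> pd.DataFrame:
        totals = self.quantities.sum(axis=1)
        return self.quantities.div(totals, axis=0)

    def mean_profile(self, sample: str, gene: str) -> pd.Series:
        sub = self.normalized.xs((sample, gene), level=("sample", "gene"))
        return sub.mean(axis=0)


@dataclass
class TEEstimate:
    """Polysome/monosome ratio for one (sample, gene)."""

    te_ratio: float
    te_sd: float
    monosome_fractions: tuple[int, ...]
    polysome_fractions: tuple[int, ...]


def spike_correct(table: pd.DataFrame) -> pd.DataFrame:
    """Remove per-fraction technical offsets using the spike-in Cq.

    Cq_corr = Cq - (spike_Cq_fraction - mean spike_Cq within the sample run).
    The correction is invariant to adding any per-fraction constant to both
    the gene and the spike Cq of that fraction.
    """
    missing = [c for c in CQ_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Cq table lacks columns {missing}")
    if table["spike_Cq"].isna().any():
        bad = table.loc[table["spike_Cq"].isna()].iloc[0]
        raise ValueError(
            f"missing spike Cq for sample {bad['sample']!r} fraction {bad['fraction']}"
        )
    out = table.copy()
    ref = out.groupby(["sample", "replicate"])["spike_Cq"].transform("mean")
    out["Cq_corrected"] = out["Cq"] - (out["spike_Cq"] - ref)
    return out


def relative_quantity(cq: pd.Series | np.ndarray) -> np.ndarray:
    """Relative quantity per fraction: 2^(Cq_min - Cq); the best fraction is 1."""
    arr = np.asarray(cq, dtype=float)
    if np.isnan(arr).all():
        raise ValueError("all Cq values missing")
    return 2.0 ** (np.nanmin(arr) - arr)


def fraction_profiles(corrected: pd.DataFrame) -> FractionProfile:
    """Relative-quantity profiles for every (sample, gene, replicate)."""
    col = "Cq_corrected" if "Cq_corrected" in corrected.columns else "Cq"
    wide = corrected.pivot_table(
        index=["sample", "gene", "replicate"], columns="fraction", values=col
    )
    q = pd.DataFrame(
        np.vstack([relative_quantity(row) for _, row in wide.iterrows()]),
        index=wide.index,
        columns=wide.columns,
    )
    return FractionProfile(quantities=q)


def translation_efficiency_ratio(
    profile: FractionProfile,
    sample: str,
    gene: str,
    monosome_fractions: tuple[int, ...] = DEFAULT_MONOSOME,
    polysome_fractions: tuple[int, ...] = DEFAULT_POLYSOME,
) -> TEEstimate:
    """Polysome/monosome fold change of summed relative quantities.

    Computed per replicate and aggregated by mean with SD. A replicate with
    zero monosome signal contributes NaN; if all replicates do, the ratio is
    reported as NaN (undefined).
    """
    mono = set(monosome_fractions)
    poly = set(polysome_fractions)
    if not mono or not poly:
        raise ValueError("both fraction sets must be non-empty")
    if mono & poly:
        raise ValueError("monosome and polysome fraction sets overlap")
    sub = profile.quantities.xs((sample, gene), level=("sample", "gene"))
    mono_cols = [f for f in sub.columns if f in mono]
    poly_cols = [f for f in sub.columns if f in poly]
    if not mono_cols or not poly_cols:
        raise ValueError("fraction sets not present in the profile")
    mono_sum = sub[mono_cols].sum(axis=1)
    poly_sum = sub[poly_cols].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(mono_sum > 0, poly_sum / mono_sum, np.nan)
    ratios = ratios[~np.isnan(ratios)]
    if ratios.size == 0:
        return TEEstimate(float("nan"), float("nan"), tuple(sorted(mono)), tuple(sorted(poly)))
    return TEEstimate(
        te_ratio=float(np.mean(ratios)),
        te_sd=float(np.std(ratios, ddof=1)) if ratios.size > 1 else 0.0,
        monosome_fractions=tuple(sorted(mono)),
        polysome_fractions=tuple(sorted(poly)),
    )


def _centroid(norm_profiles: pd.DataFrame) -> np.ndarray:
    """Quantity-weighted mean fraction index per replicate row."""
    fractions = norm_profiles.columns.to_numpy(dtype=float)
    return norm_profiles.to_numpy() @ fractions


def profile_shift(
    profile_a: pd.DataFrame,
    profile_b: pd.DataFrame,
    n_boot: int = 1000,
    seed: int | None = None,
) -> tuple[float, float | None]:
    """Shift of the profile centroid between two conditions (B - A).

    Inputs are replicate x fraction tables of quantities on the same fraction
    grid; each replicate row is normalized to sum 1 and summarized by its
    weighted mean fraction index. The statistic is the difference of the mean
    centroids. The one-sided bootstrap p (for a right-shift claim, shift > 0)
    resamples replicates with replacement and reports the fraction of
    bootstrap shifts <= 0. With a single replicate on either side the shift
    is still returned but p is None.
    """
    if list(profile_a.columns) != list(profile_b.columns):
        raise ValueError("fraction grids differ between profiles")
    norm_a = profile_a.div(profile_a.sum(axis=1), axis=0)
    norm_b = profile_b.div(profile_b.sum(axis=1), axis=0)
    cent_a = _centroid(norm_a)
    cent_b = _centroid(norm_b)
    shift = float(np.mean(cent_b) - np.mean(cent_a))
    if len(cent_a) < 2 or len(cent_b) < 2:
        return shift, None
    rng = np.random.default_rng(seed)
    idx_a = rng.integers(0, len(cent_a), size=(n_boot, len(cent_a)))
    idx_b = rng.integers(0, len(cent_b), size=(n_boot, len(cent_b)))
    boot = cent_b[idx_b].mean(axis=1) - cent_a[idx_a].mean(axis=1)
    p = float(np.mean(boot <= 0.0))
    return shift, max(p, 1.0 / n_boot)
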