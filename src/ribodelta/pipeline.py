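"""Configuration-driven orchestration of the full analysis.

``run_joint_analysis`` wires the per-stage functions for one contrast:
TMM normalization and library equalization per assay, NB exact DE tests on
RNA and RPF, the delta-TE Wald test, and the decoupling classification.
``run_pipeline`` adds simulation (or file input), enrichment, optional qPCR,
TSV outputs and a JSON run manifest, and is what the ``run-all`` CLI
subcommand executes. Identical configuration (including seeds) produces
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .de import equalize_libraries, run_de
from .decoupling import TE_UP as CALL_TE_UP
from .decoupling import classify_regulation, decoupled_fraction
from .enrichment import gsea_preranked, ora_hypergeometric, read_gmt, write_gmt
from .expression import RNA, RPF, CountMatrix, filter_expressed, read_count_matrix, rpkm, tmm_normalize
from .qpcr import fraction_profiles, profile_shift, spike_correct, translation_efficiency_ratio
from .simulate import SimulationConfig, generate_cq_table, generate_gene_sets, generate_joint_counts
from .te import differential_te, global_te_slope

__all__ = ["run_joint_analysis", "run_pipeline", "default_config"]


def default_config(seed: int = 0) -> dict:
    """Default pipeline configuration: simulate the emulated study design."""
    return {
        "seed": seed,
        "simulation": asdict(SimulationConfig(seed=seed)),
        "thresholds": {"fdr": 0.01, "lfc": 1.0, "band": 1.0, "cpm": 1.0, "rpkm": 1.0},
        "classification_mode": "guarded",
        "contrast": None,  # (B, A); default second condition vs first
        "gene_sets": {"n_decoy_sets": 10, "set_size": 50},
        "gsea": {"n_perm": 1000, "weight": 1.0},
        "qpcr": {
            "n_genes": 4,
            "te_ratios": [0.5, 1.0, 2.0, 4.0],
            "noise_sd": 0.2,
            "mono": [7, 8],
            "poly": [9, 10, 11, 12, 13, 14],
        },
    }


def run_joint_analysis(
    rna: CountMatrix,
    rpf: CountMatrix,
    condition_b: str,
    condition_a: str,
    fdr_cut: float = 0.01,
    lfc_cut: float = 1.0,
    band: float = 1.0,
    mode: str = "guarded",
) -> dict:
    """Normalize, test and classify one contrast across both assays."""
    out: dict = {}
    means = {}
    ns = {}
    for label, matrix in ((RNA, rna), (RPF, rpf)):
        norm = tmm_normalize(matrix)
        de, disp = run_de(
            matrix, norm, condition_b, condition_a,
            fdr_cut=fdr_cut, lfc_cut=lfc_cut,
        )
        adjusted, _ = equalize_libraries(matrix, norm)
        cols_a = matrix.condition_samples(condition_a)
        cols_b = matrix.condition_samples(condition_b)
        means[label] = (
            adjusted[cols_a].mean(axis=1).to_numpy(),
            adjusted[cols_b].mean(axis=1).to_numpy(),
        )
        ns[label] = (len(cols_a), len(cols_b))
        out[f"norm_{label.lower()}"] = norm
        out[f"de_{label.lower()}"] = de
        out[f"dispersion_{label.lower()}"] = disp
    dte = differential_te(
        out["de_rna"], out["de_rpf"],
        out["dispersion_rna"].phi, out["dispersion_rpf"].phi,
        means[RNA], means[RPF], ns[RNA], ns[RPF],
    )
    calls = classify_regulation(
        out["de_rna"], out["de_rpf"], band=band, mode=mode,
        dte_fdr=dte.table["FDR"],
    )
    out["dte"] = dte
    out["calls"] = calls
    out["decoupled_fraction"] = decoupled_fraction(calls)
    return out


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Execute the configured stages and write all tables plus a manifest.

    With a ``simulation`` block the input matrices, gene sets and Cq tables
    are generated with known ground truth; alternatively ``counts_rna``,
    ``counts_rpf`` and ``metadata`` paths (plus optional ``gmt`` and ``cq``)
    supply real data. Raises a stage-named RuntimeError on failure.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thresholds = config.get("thresholds", default_config()["thresholds"])
    seed = int(config.get("seed", 0))

    truth = None
    if config.get("simulation"):
        sim = SimulationConfig(**config["simulation"])
        rna, rpf, truth = generate_joint_counts(sim)
        truth.to_csv(outdir / "ground_truth.tsv", sep="\t")
        rna.write(outdir / "counts_rna.tsv", outdir / "metadata_rna.tsv")
        rpf.write(outdir / "counts_rpf.tsv", outdir / "metadata_rpf.tsv")
    elif config.get("counts_rna") and config.get("counts_rpf"):
        rna = read_count_matrix(config["counts_rna"], config["metadata"])
        rpf = read_count_matrix(config["counts_rpf"], config["metadata"])
    else:
        raise RuntimeError("input: config needs either a simulation block or count paths")

    conditions = rna.conditions
    contrast = config.get("contrast") or (conditions[1], conditions[0])
    cond_b, cond_a = contrast

    try:
        result = run_joint_analysis(
            rna, rpf, cond_b, cond_a,
            fdr_cut=thresholds["fdr"], lfc_cut=thresholds["lfc"],
            band=thresholds["band"], mode=config.get("classification_mode", "guarded"),
        )
    except Exception as exc:  # pragma: no cover - stage naming only
        raise RuntimeError(f"differential-analysis stage failed: {exc}") from exc

    for key in ("de_rna", "de_rpf"):
        result[key].write(outdir / f"{key}.tsv")
        result[f"norm_{key.split('_')[1]}"].write(outdir / f"norm_{key.split('_')[1]}.tsv")
    result["dte"].write(outdir / "dte.tsv")
    result["calls"].write(outdir / "calls.tsv")

    # per-condition global TE slopes on the filtered gene set
    slopes = {}
    mask_rna, _ = filter_expressed(rna, thresholds["cpm"])
    rpkm_rna = rpkm(rna, result["norm_rna"].effective_sizes)
    rpkm_rpf = rpkm(rpf, result["norm_rpf"].effective_sizes)
    for cond in conditions:
        cols_rna = rna.condition_samples(cond)
        cols_rpf = rpf.condition_samples(cond)
        fit = global_te_slope(
            rpkm_rna.loc[mask_rna, cols_rna], rpkm_rpf.loc[mask_rna, cols_rpf]
        )
        slopes[cond] = fit
    pd.DataFrame(
        {c: asdict(s) for c, s in slopes.items()}
    ).T.to_csv(outdir / "te_slopes.tsv", sep="\t")
    result["slopes"] = slopes

    # enrichment on the delta-TE ranking
    if truth is not None:
        gs_cfg = config.get("gene_sets", {})
        collection = generate_gene_sets(
            truth,
            n_decoy_sets=gs_cfg.get("n_decoy_sets", 10),
            set_size=gs_cfg.get("set_size", 50),
            seed=seed,
        )
        write_gmt(collection, outdir / "gene_sets.gmt")
    elif config.get("gmt"):
        collection = read_gmt(config["gmt"])
    else:
        collection = None
    if collection is not None:
        gsea_cfg = config.get("gsea", {})
        ranking = result["dte"].table["delta_te"]
        rows = []
        for name, members in collection:
            res = gsea_preranked(
                ranking, members,
                n_perm=gsea_cfg.get("n_perm", 1000),
                p=gsea_cfg.get("weight", 1.0),
                seed=seed,
            )
            rows.append(
                {"set": name, "size": len(members), "overlap": res.overlap,
                 "ES": res.es, "NES": res.nes, "pvalue": res.pvalue,
                 "direction": res.direction}
            )
        pd.DataFrame(rows).set_index("set").to_csv(outdir / "gsea.tsv", sep="\t")
        te_up_called = set(result["calls"].table.index[result["calls"].table["class"] == CALL_TE_UP])
        if te_up_called:
            ora = ora_hypergeometric(te_up_called, set(rna.gene_ids), collection)
            ora.to_csv(outdir / "ora.tsv", sep="\t")
            result["ora"] = ora
        result["gene_sets"] = collection

    # qPCR stage (simulated Cq table, or a user-provided one)
    qcfg = config.get("qpcr")
    if qcfg:
        if config.get("cq"):
            table = pd.read_csv(config["cq"], sep="\t")
        else:
            table, q_truth = generate_cq_table(
                n_genes=qcfg.get("n_genes", 4),
                te_ratio_truth=np.asarray(qcfg.get("te_ratios", [1.0]), dtype=float),
                noise_sd=qcfg.get("noise_sd", 0.2),
                seed=seed,
            )
            q_truth.to_csv(outdir / "qpcr_truth.tsv", sep="\t")
        corrected = spike_correct(table)
        profiles = fraction_profiles(corrected)
        mono = tuple(qcfg.get("mono", [7, 8]))
        poly = tuple(qcfg.get("poly", [9, 10, 11, 12, 13, 14]))
        rows = []
        for sample, gene in sorted(
            {(s, g) for s, g, _ in profiles.quantities.index}
        ):
            est = translation_efficiency_ratio(profiles, sample, gene, mono, poly)
            rows.append(
                {"sample": sample, "gene": gene, "te_ratio": est.te_ratio, "te_sd": est.te_sd}
            )
        pd.DataFrame(rows).to_csv(outdir / "qpcr_te.tsv", sep="\t", index=False)
        result["qpcr_profiles"] = profiles

    manifest = {
        "package": "ribodelta",
        "version": __version__,
        "seed": seed,
        "contrast": [cond_b, cond_a],
        "thresholds": thresholds,
        "config": _jsonable(config),
        "decoupled_fraction": result["decoupled_fraction"],
        "class_counts": {
            k: int(v) for k, v in result["calls"].class_counts.items()
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    result["manifest"] = manifest
    result["truth"] = truth
    return result


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
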