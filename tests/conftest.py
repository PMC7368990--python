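import numpy as np
import pandas as pd
import pytest

import ribodelta as rd
from ribodelta.pipeline import run_joint_analysis


@pytest.fixture(scope="session")
def small_sim():
    """800-gene simulated study with all four planted classes."""
    cfg = rd.SimulationConfig(n_genes=800, seed=11)
    rna, rpf, truth = rd.generate_joint_counts(cfg)
    return cfg, rna, rpf, truth


@pytest.fixture(scope="session")
def joint_result(small_sim):
    """Full analysis of the perturbed-vs-control contrast on small_sim."""
    _, rna, rpf, _ = small_sim
    return run_joint_analysis(rna, rpf, "deltaN200", "control")


@pytest.fixture
def tiny_matrix():
    counts = pd.DataFrame(
        {"s1": [5, 0, 100, 7], "s2": [10, 0, 200, 3]},
        index=["g1", "g2", "g3", "g4"],
    )
    samples = pd.DataFrame(
        {
            "condition": ["A", "B"],
            "replicate": [1, 1],
            "assay": ["RNA", "RNA"],
        },
        index=["s1", "s2"],
    )
    lengths = pd.Series([1000, 500, 2000, 1000], index=counts.index)
    return rd.CountMatrix(counts=counts, samples=samples, gene_lengths=lengths)


def random_nb_matrix(rng, n_genes=200, n_samples=6, mean_log=5.0, sd_log=1.0, phi=0.1):
    """Random NB count matrix wrapped as a CountMatrix (3+3 replicates)."""
    base = np.exp(rng.normal(mean_log, sd_log, n_genes))
    scale = rng.uniform(0.7, 1.3, n_samples)
    mu = base[:, None] * scale[None, :]
    lam = rng.gamma(1.0 / phi, mu * phi) if phi > 0 else mu
    counts = rng.poisson(lam)
    names = [f"s{j}" for j in range(n_samples)]
    samples = pd.DataFrame(
        {
            "condition": ["A"] * (n_samples // 2) + ["B"] * (n_samples - n_samples // 2),
            "replicate": list(range(1, n_samples // 2 + 1))
            + list(range(1, n_samples - n_samples // 2 + 1)),
            "assay": ["RNA"] * n_samples,
        },
        index=names,
    )
    return rd.CountMatrix(
        counts=pd.DataFrame(counts, index=[f"g{i}" for i in range(n_genes)], columns=names),
        samples=samples,
    )
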