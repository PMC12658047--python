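import numpy as np
import pandas as pd
import pytest

from presig.io import CountMatrix
from presig.simulate import (
    PlantedBiomarker,
    PlantedPathway,
    SimulationConfig,
    generate_dataset,
    simulate_qc_table,
)


@pytest.fixture(scope="session")
def small_study():
    """Reduced-scale study with planted programs, biomarker, and bias."""
    cfg = SimulationConfig(
        n_samples_pe=12,
        n_samples_np=52,
        n_genes=2500,
        n_spikeins=60,
        bias_sd=0.25,
        planted_pathways=(
            PlantedPathway("UP1", 25, 1.0),
            PlantedPathway("DOWN1", 25, -1.0),
        ),
        planted_biomarkers=(PlantedBiomarker("", 1.6),),
        n_decoy_sets=20,
        decoy_set_size=25,
        seed=11,
    )
    cm, meta, sets, truth = generate_dataset(cfg)
    return cfg, cm, meta, sets, truth


@pytest.fixture(scope="session")
def small_qc(small_study):
    _, cm, _, _, _ = small_study
    return simulate_qc_table(cm, seed=11, n_outliers=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def nb_counts(rng, mu, alpha):
    """NB(mu, alpha) helper with Poisson limit at alpha == 0."""
    mu = np.asarray(mu, dtype=float)
    if np.isscalar(alpha) and alpha == 0:
        return rng.poisson(mu)
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mu))


def toy_count_matrix(values, gene_ids=None, sample_ids=None, spike=None, library=None):
    values = np.asarray(values)
    g, s = values.shape
    gene_ids = gene_ids or [f"G{i}" for i in range(g)]
    sample_ids = sample_ids or [f"S{i}" for i in range(s)]
    df = pd.DataFrame(values, index=pd.Index(gene_ids), columns=pd.Index(sample_ids))
    if spike is None:
        spike = [gid.startswith("ERCC-") for gid in gene_ids]
    lib = None
    if library is not None:
        lib = pd.Series(library, index=df.columns)
    return CountMatrix(df, pd.Series(spike, index=df.index), lib)
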