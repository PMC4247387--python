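import numpy as np
import pandas as pd
import pytest

from stromage.config import AnalysisConfig
from stromage.data import CohortDesign, FeatureTable, Layer
from stromage.simulate import SimulationParams, generate_dataset


@pytest.fixture(scope="session")
def design15() -> CohortDesign:
    """Hand-written 15-donor cohort: 5 per age band, fixed ages."""
    return CohortDesign(
        donor_id=tuple(f"{p}{i}" for p in "YMO" for i in range(1, 6)),
        age_years=(22, 24, 26, 28, 30, 41, 43, 45, 47, 49, 61, 63, 65, 67, 69),
        age_group=tuple(["young"] * 5 + ["middle"] * 5 + ["old"] * 5),
    )


@pytest.fixture(scope="session")
def config() -> AnalysisConfig:
    return AnalysisConfig()


def make_protein_table(values: np.ndarray, design: CohortDesign,
                       peptides=None, identified=None, genes=None) -> FeatureTable:
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    ids = [f"P{i:03d}" for i in range(1, n + 1)]
    meta = pd.DataFrame(
        {
            "unique_peptide_count": peptides if peptides is not None else [3] * n,
            "n_samples_identified": (
                identified if identified is not None else [len(design)] * n
            ),
            "gene_symbol": genes if genes is not None else [f"G{i:03d}" for i in range(1, n + 1)],
        },
        index=ids,
    )
    return FeatureTable(
        layer=Layer.protein,
        values=pd.DataFrame(values, index=ids, columns=list(design.donor_id)),
        meta=meta,
    )


@pytest.fixture(scope="session")
def default_dataset():
    """Full synthetic cohort at study-design defaults, seed 42."""
    params = SimulationParams(seed=42)
    return params, generate_dataset(params)


@pytest.fixture(scope="session")
def small_params() -> SimulationParams:
    """Reduced problem size for fast structural tests."""
    return SimulationParams(
        n_proteins=400,
        n_mirnas=20,
        n_age_mirnas=4,
        n_prior_edges_per_mirna=8,
        n_decoy_edges_per_mirna=4,
        n_extra_mrna_genes=150,
        n_random_gene_sets=8,
        seed=7,
    )
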