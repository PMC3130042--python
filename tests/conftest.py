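import numpy as np
import pandas as pd
import pytest

from metapqtl.simulate import SimConfig, simulate_dataset
from metapqtl.tables import CohortTable, IsotopeGroupTable


@pytest.fixture(scope="session")
def default_sim():
    """Desk-scale dataset under the default (pleiotropy) study conditions."""
    config = SimConfig(seed=11)
    table, cohort, truth = simulate_dataset(config)
    return config, table, cohort, truth


@pytest.fixture(scope="session")
def clean_sim():
    """Low-noise, complete, non-promiscuous dataset for factor-model checks."""
    config = SimConfig(
        n_samples=50, residual_sd=0.2, missing_rate=0.0, promiscuous_fraction=0.0, seed=5
    )
    table, cohort, truth = simulate_dataset(config)
    return config, table, cohort, truth


def make_table(intensity_matrix, protein_ids, sample_ids=None, peptide_labels=None):
    """Build a minimal IsotopeGroupTable from a features x samples array."""
    intensity_matrix = np.asarray(intensity_matrix, dtype=float)
    n_feat, n_samp = intensity_matrix.shape
    sample_ids = sample_ids or [f"S{i}" for i in range(n_samp)]
    feature_ids = [f"F{j}" for j in range(n_feat)]
    labels = peptide_labels or [p if p is not None else "unknown" for p in protein_ids]
    features = pd.DataFrame(
        {
            "peptide_label": labels,
            "protein_id": protein_ids,
            "monoisotopic_mz": np.linspace(400, 900, n_feat),
            "charge_state": [2] * n_feat,
            "peak_centroid_times": [[30.0, 30.1]] * n_feat,
            "peak_time_scores": [[0.9, 0.95]] * n_feat,
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )
    intensities = pd.DataFrame(intensity_matrix, index=features.index, columns=sample_ids)
    return IsotopeGroupTable(features=features, intensities=intensities)


def make_cohort(allele_counts, sex=None, race=None, outcome=None):
    allele_counts = list(allele_counts)
    n = len(allele_counts)
    labels = {2: "CC", 1: "CT", 0: "TT"}
    data = pd.DataFrame(
        {
            "genotype": [labels[c] for c in allele_counts],
            "allele_count": allele_counts,
            "sex": sex or ["male"] * n,
            "race": race or ["Caucasian"] * n,
            "outcome": outcome if outcome is not None else [np.nan] * n,
        },
        index=pd.Index([f"S{i}" for i in range(n)], name="sample_id"),
    )
    return CohortTable(data=data)
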