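"""Shared fixtures: a small deterministic synthetic cohort and helpers."""

import numpy as np
import pandas as pd
import pytest

from crlmkit.io import OmicsMatrix
from crlmkit.simulate import SyntheticConfig, generate_cohort


def small_config(seed: int = 7, **overrides) -> SyntheticConfig:
    """A fast cohort: 20 patients, 600 genes, all planted structure present."""
    params = dict(
        seed=seed, n_patients=20, n_genes=600, metabolism_block=60,
        rna_function_block=60, n_lm_enriched=50, n_t_enriched=30,
        n_cis_genes=120, n_protein_biomarkers=8, n_as_events=40,
        n_subtype_events=12, n_factor_edges=6)
    params.update(overrides)
    return SyntheticConfig(**params)


@pytest.fixture(scope="session")
def bundle():
    return generate_cohort(small_config())


@pytest.fixture()
def toy_matrix():
    data = pd.DataFrame(
        [[1.0, 2.0, np.nan], [0.0, -1.0, 4.0], [2.5, 2.5, 2.5]],
        index=["GA", "GB", "GC"], columns=["S1", "S2", "S3"])
    return OmicsMatrix("protein", data, is_normalized=True)
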