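import numpy as np
import pandas as pd
import pytest

from dualnet import (
    AlignedStudy,
    FeatureMatrix,
    ResponseMatrix,
    SynthConfig,
    generate_study,
    normalize_study,
)


def make_toy_study(
    n_cells=6, n_drugs=4, n_genes=12, n_descriptors=8, seed=0, missing=None
) -> AlignedStudy:
    """Small dense study with unstructured random features and responses."""
    rng = np.random.default_rng(seed)
    cells = [f"c{i}" for i in range(n_cells)]
    drugs = [f"d{j}" for j in range(n_drugs)]
    expr = pd.DataFrame(
        rng.normal(size=(n_cells, n_genes)), index=cells,
        columns=[f"g{k}" for k in range(n_genes)],
    )
    desc = pd.DataFrame(
        rng.normal(size=(n_drugs, n_descriptors)), index=drugs,
        columns=[f"x{k}" for k in range(n_descriptors)],
    )
    resp = pd.DataFrame(rng.uniform(0, 8, size=(n_cells, n_drugs)), index=cells, columns=drugs)
    if missing:
        for c, d in missing:
            resp.iloc[c, d] = np.nan
    return AlignedStudy(
        expression=FeatureMatrix(expr),
        descriptors=FeatureMatrix(desc),
        responses=ResponseMatrix(resp),
    )


@pytest.fixture
def toy_study() -> AlignedStudy:
    return make_toy_study()


@pytest.fixture(scope="session")
def default_study():
    """Seeded default-size synthetic study, shared where read-only."""
    study, truth = generate_study(SynthConfig(seed=42))
    return normalize_study(study), truth


class IdentityRng:
    """Stands in for a Generator whose permutations are the identity."""

    def permutation(self, n):
        return np.arange(n)
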