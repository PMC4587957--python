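"""Similarity networks and Gaussian-kernel neighbor weights.

The cell line similarity network (CSN) is the complete graph over cell
lines weighted by the Pearson correlation of their expression profiles;
the drug similarity network (DSN) is the complete graph over drugs
weighted by the Pearson correlation of their 1-D/2-D chemical
descriptor vectors.  Correlations are converted to neighbor weights by
the Gaussian kernel

    w(i, j) = exp(-(1 - rho_ij)^2 / (2 b^2))

with bandwidth b (sigma for cells, tau for drugs) controlling how fast
influence decays as similarity drops.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import FeatureMatrix, StudyInputError


@dataclass
class SimilarityNetwork:
    """Symmetric Pearson-correlation matrix over entities, unit diagonal."""

    rho: pd.DataFrame  # entities x entities

    def __post_init__(self) -> None:
        vals = self.rho.to_numpy(float)
        if not np.isfinite(vals).all():
            raise ValueError("similarity matrix contains non-finite entries")
        if not np.allclose(vals, vals.T):
            raise ValueError("similarity matrix is not symmetric")
        if not np.allclose(np.diag(vals), 1.0):
            raise ValueError("similarity matrix diagonal is not 1")

    @property
    def entity_ids(self) -> pd.Index:
        return self.rho.index

    def to_csv(self, path, sep: str = "\t") -> None:
        self.rho.to_csv(path, sep=sep)


def build_similarity(fm: FeatureMatrix, standardize: bool = False) -> SimilarityNetwork:
    """Pairwise Pearson correlation of entity profiles over usable features.

    ``standardize=True`` z-scores each feature over entities first;
    used for chemical descriptors, whose raw magnitudes span orders of
    magnitude (atom counts vs topological indices) and would otherwise
    dominate the correlation.  Expression profiles are used as given.
    """
    usable = fm.usable
    if usable.shape[0] < 2:
        raise StudyInputError("need at least 2 entities to build a similarity network")
    if usable.shape[1] < 2:
        raise StudyInputError("need at least 2 usable features to build a similarity network")
    x = usable.to_numpy(float)
    if standardize:
        x = (x - x.mean(axis=0)) / x.std(axis=0)
    sd = x.std(axis=1)
    if (sd == 0).any():
        flat = list(usable.index[sd == 0])
        raise StudyInputError(f"entities with zero feature variance: {flat}")
    rho = np.corrcoef(x)
    rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return SimilarityNetwork(pd.DataFrame(rho, index=usable.index, columns=usable.index))


@dataclass
class KernelWeights:
    """Gaussian-kernel neighbor weights derived from a similarity network.

    Weights are held as exponents -(1 - rho)^2 / (2 b^2); the ``weights``
    property exponentiates them.  Keeping exponents allows weighted
    means to be evaluated exactly at very small bandwidths, where the
    raw weights underflow to zero.
    """

    entity_ids: pd.Index
    bandwidth: float
    exponents: np.ndarray  # entities x entities, 0 on the diagonal
    layer: str = ""  # "CSN" or "DSN"

    @property
    def weights(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.exp(self.exponents), index=self.entity_ids, columns=self.entity_ids
        )


def kernel_weights(sn: SimilarityNetwork, bandwidth: float, layer: str = "") -> KernelWeights:
    """Convert correlations to Gaussian-kernel weights at the given bandwidth."""
    if not bandwidth > 0:
        raise ValueError(f"bandwidth must be positive, got {bandwidth}")
    rho = sn.rho.to_numpy(float)
    expo = -((1.0 - rho) ** 2) / (2.0 * bandwidth * bandwidth)
    np.fill_diagonal(expo, 0.0)
    return KernelWeights(sn.entity_ids, float(bandwidth), expo, layer)
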