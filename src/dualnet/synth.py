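"""Synthetic pharmacogenomic studies with the structure the model assumes.

The generator emulates the two empirical regularities the dual-layer
model rests on: cell lines with similar expression profiles respond
similarly to the same drug, and structurally similar drugs act
similarly across cell lines.  Cells and drugs carry cluster-structured
latents; expression and descriptor matrices are noisy linear readouts
of those latents, and the response surface is

    Sens(C, D) = baseline + offset_D
                 + cell_signal * u(C) . a_D      (smooth across cells)
                 + drug_signal * b_C . v(D)      (smooth across drugs)
                 + noise

where a_D is drawn independently per drug and b_C independently per
cell.  The first term is therefore predictable only from similar cell
lines (the CSN layer) and the second only from similar drugs (the DSN
layer), so the two signal strengths independently control which layer
carries information and which way the per-drug mixing weight lambda
should fall.  A configurable fraction of entries is masked uniformly
at random.  All randomness flows from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import AlignedStudy, FeatureMatrix, ResponseMatrix, _flag_features


@dataclass
class SynthConfig:
    """Study-generation settings.

    Defaults give a desk-scale screen (60 cell lines x 20 drugs, 200
    genes, 40 descriptors, 4 clusters per axis) with equal layer
    signals, moderate noise and a complete response grid.
    """

    n_cells: int = 60
    n_drugs: int = 20
    n_genes: int = 200
    n_descriptors: int = 40
    n_cell_clusters: int = 4
    n_drug_clusters: int = 4
    cell_signal: float = 1.0  # strength of the CSN-predictable component
    drug_signal: float = 1.0  # strength of the DSN-predictable component
    noise_sd: float = 0.3  # measurement noise on responses
    missing_fraction: float = 0.0
    baseline: float = 3.0  # activity-area-like offset
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cells", "n_drugs", "n_genes", "n_descriptors",
                     "n_cell_clusters", "n_drug_clusters"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        if self.n_cell_clusters > self.n_cells or self.n_drug_clusters > self.n_drugs:
            raise ValueError("cluster counts cannot exceed entity counts")
        if self.cell_signal < 0 or self.drug_signal < 0:
            raise ValueError("signal strengths must be >= 0")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must be in [0, 1)")


def _latents(rng, n: int, k: int, jitter: float = 0.3) -> tuple[np.ndarray, np.ndarray]:
    """Cluster-structured latent vectors: cluster centers plus jitter."""
    clusters = np.arange(n) % k
    centers = rng.normal(size=(k, k))
    z = centers[clusters] + jitter * rng.normal(size=(n, k))
    return z, clusters


def _readout(rng, z: np.ndarray, n_features: int, noise: float = 1.0) -> np.ndarray:
    """Noisy linear readout of latents into an observed feature matrix."""
    loadings = rng.normal(size=(z.shape[1], n_features))
    return z @ loadings + noise * rng.normal(size=(z.shape[0], n_features))


def generate_study(cfg: SynthConfig) -> tuple[AlignedStudy, ResponseMatrix]:
    """Generate an aligned study plus its noise-free true response matrix.

    Responses in the study are raw (unnormalized) with Gaussian noise
    and optional uniform missingness; the returned truth matrix is
    fully observed and noise-free.
    """
    rng = np.random.default_rng(cfg.seed)
    cells = [f"C{i:03d}" for i in range(cfg.n_cells)]
    drugs = [f"D{j:02d}" for j in range(cfg.n_drugs)]
    genes = [f"G{k:04d}" for k in range(cfg.n_genes)]
    descs = [f"X{k:03d}" for k in range(cfg.n_descriptors)]

    u, _ = _latents(rng, cfg.n_cells, cfg.n_cell_clusters)
    v, _ = _latents(rng, cfg.n_drugs, cfg.n_drug_clusters)

    expr = _readout(rng, u, cfg.n_genes)
    desc = _readout(rng, v, cfg.n_descriptors)
    # descriptor columns span orders of magnitude, as 1-D/2-D chemical
    # descriptors do (atom counts vs topological indices)
    desc = desc * (10.0 ** rng.uniform(-2, 2, size=cfg.n_descriptors))

    a = rng.normal(size=(cfg.n_drugs, u.shape[1]))  # per-drug cell-readout
    b = rng.normal(size=(cfg.n_cells, v.shape[1]))  # per-cell drug-readout
    f = (u @ a.T) / np.sqrt(u.shape[1])  # cells x drugs, smooth over cells
    g = (b @ v.T) / np.sqrt(v.shape[1])  # cells x drugs, smooth over drugs
    offset = rng.normal(scale=0.5, size=cfg.n_drugs)
    true = cfg.baseline + offset + cfg.cell_signal * f + cfg.drug_signal * g

    observed = true + cfg.noise_sd * rng.normal(size=true.shape)
    if cfg.missing_fraction > 0:
        n_mask = int(round(cfg.missing_fraction * true.size))
        flat = rng.choice(true.size, size=n_mask, replace=False)
        observed.ravel()[flat] = np.nan

    expr_fm = FeatureMatrix(pd.DataFrame(expr, index=cells, columns=genes))
    desc_df = pd.DataFrame(desc, index=drugs, columns=descs)
    desc_fm = FeatureMatrix(desc_df, excluded_features=_flag_features(desc_df))
    responses = ResponseMatrix(pd.DataFrame(observed, index=cells, columns=drugs))
    truth = ResponseMatrix(pd.DataFrame(true, index=cells, columns=drugs))
    study = AlignedStudy(expression=expr_fm, descriptors=desc_fm, responses=responses)
    return study, truth


def generate_labels(
    study: AlignedStudy,
    cfg: SynthConfig,
    effect: float,
    drug: str | None = None,
) -> tuple[dict[str, bool], AlignedStudy]:
    """Binary cell-line labels with a sensitization effect on one drug.

    A random half of the cell lines is labeled positive and the
    designated drug's responses for them are shifted by ``-effect``
    (more sensitive, IC50-like direction).  Returns the label map and
    a study with the shifted responses.
    """
    if not np.isfinite(effect):
        raise ValueError("effect must be finite")
    rng = np.random.default_rng(cfg.seed + 1)
    cells = list(study.responses.cell_ids)
    drug = drug or str(study.responses.drug_ids[0])
    pos = set(rng.permutation(cells)[: len(cells) // 2])
    labels = {c: c in pos for c in cells}
    data = study.responses.data.copy()
    mask = data.index.isin(pos)
    data.loc[mask, drug] = data.loc[mask, drug] - effect
    shifted = study.with_responses(
        ResponseMatrix(data, norm_record=study.responses.norm_record)
    )
    return labels, shifted
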