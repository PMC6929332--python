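"""Laplacian normalization and individual-length bi-random walks with restart.

Each side of the heterogeneous network runs its own restart walk: the
drug-side walk propagates every drug's association profile through the
normalized disease similarity, the disease-side walk mirrors that through
the normalized drug similarity.  A node stops propagating as soon as the
iteration index exceeds its floored walk budget, which is the method's
central departure from fixed-length bi-random walks; the two score
matrices are averaged once at the end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from birwalk.net_core import (
    DISEASE,
    DRUG,
    AssociationMatrix,
    FeatureMatrix,
    ScoreMatrix,
    SimilarityMatrix,
    ensure_same_index,
)
from birwalk.similarity import SimilarityConfig, composite_similarity
from birwalk.walk_length import WalkLengthVector, walk_lengths_from_associations

MODE_INDIVIDUAL = "individual"
MODE_FIXED = "fixed"


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed for a deterministic end-to-end run."""

    alpha: float = 0.1
    mode: str = MODE_INDIVIDUAL
    fixed_l_r: int = 0
    fixed_l_d: int = 0
    similarity: SimilarityConfig = field(default_factory=SimilarityConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.mode not in (MODE_INDIVIDUAL, MODE_FIXED):
            raise ValueError(f"unknown walk mode {self.mode!r}")
        if self.fixed_l_r < 0 or self.fixed_l_d < 0:
            raise ValueError("fixed walk lengths must be >= 0")
        # route the global seed into the similarity stage
        if self.similarity.seed != self.seed:
            object.__setattr__(
                self, "similarity", replace(self.similarity, seed=self.seed)
            )


@dataclass(frozen=True)
class PipelineResult:
    """Final scores plus the intermediate artifacts of one run."""

    scores: ScoreMatrix
    scores_drug_walk: ScoreMatrix
    scores_disease_walk: ScoreMatrix
    similarity_drug: SimilarityMatrix
    similarity_disease: SimilarityMatrix
    lengths_drug: WalkLengthVector | int
    lengths_disease: WalkLengthVector | int


def laplacian_normalize(similarity: SimilarityMatrix) -> SimilarityMatrix:
    """Symmetric normalization D^(-1/2) S D^(-1/2); zero-degree rows stay zero."""
    s = similarity.values
    degree = s.sum(axis=1)
    inv_sqrt = np.where(degree > 0, 1.0 / np.sqrt(np.where(degree > 0, degree, 1.0)), 0.0)
    normalized = inv_sqrt[:, None] * s * inv_sqrt[None, :]
    normalized = (normalized + normalized.T) / 2.0
    return SimilarityMatrix(index=similarity.index, values=normalized, stage="normalized")


def _floors(lengths: WalkLengthVector | int | np.ndarray, n: int) -> np.ndarray:
    if isinstance(lengths, WalkLengthVector):
        floors = lengths.floored
    else:
        floors = np.floor(np.broadcast_to(np.asarray(lengths, dtype=float), (n,))).astype(int)
    if floors.shape != (n,):
        raise ValueError("walk-length vector does not match matrix dimension")
    if (floors < 0).any():
        raise ValueError("walk lengths must be >= 0")
    return floors


def _check_alpha(alpha: float) -> None:
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")


def drug_side_walk(
    similarity_disease_norm: SimilarityMatrix,
    assoc: AssociationMatrix,
    lengths_drug: WalkLengthVector | int,
    alpha: float = 0.1,
) -> ScoreMatrix:
    """Restart walk through the disease similarity, row i frozen after floor(L_r[i]) steps."""
    _check_alpha(alpha)
    ensure_same_index(similarity_disease_norm.index, assoc.disease_index, "drug_side_walk")
    w = assoc.values.astype(float)
    s = similarity_disease_norm.values
    floors = _floors(lengths_drug, assoc.drug_index.size)
    f = w.copy()
    for t in range(1, int(floors.max(initial=0)) + 1):
        candidate = alpha * (f @ s) + (1.0 - alpha) * w
        active = floors >= t
        f[active, :] = candidate[active, :]
    return ScoreMatrix(drug_index=assoc.drug_index, disease_index=assoc.disease_index, values=f)


def disease_side_walk(
    similarity_drug_norm: SimilarityMatrix,
    assoc: AssociationMatrix,
    lengths_disease: WalkLengthVector | int,
    alpha: float = 0.1,
) -> ScoreMatrix:
    """Mirror walk through the drug similarity, column j frozen after floor(L_d[j]) steps."""
    _check_alpha(alpha)
    ensure_same_index(similarity_drug_norm.index, assoc.drug_index, "disease_side_walk")
    w = assoc.values.astype(float)
    s = similarity_drug_norm.values
    floors = _floors(lengths_disease, assoc.disease_index.size)
    f = w.copy()
    for t in range(1, int(floors.max(initial=0)) + 1):
        candidate = alpha * (s @ f) + (1.0 - alpha) * w
        active = floors >= t
        f[:, active] = candidate[:, active]
    return ScoreMatrix(drug_index=assoc.drug_index, disease_index=assoc.disease_index, values=f)


def integrate(f_drug: ScoreMatrix, f_disease: ScoreMatrix) -> ScoreMatrix:
    """Average the two one-sided score matrices into the final prediction."""
    ensure_same_index(f_drug.drug_index, f_disease.drug_index, "integrate")
    ensure_same_index(f_drug.disease_index, f_disease.disease_index, "integrate")
    return ScoreMatrix(
        drug_index=f_drug.drug_index,
        disease_index=f_drug.disease_index,
        values=(f_drug.values + f_disease.values) / 2.0,
    )


def dr_ibrw(
    features_drug: FeatureMatrix,
    features_disease: FeatureMatrix,
    assoc: AssociationMatrix,
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """Composite similarities -> walk budgets -> normalized bi-random walks -> integration."""
    ensure_same_index(features_drug.index, assoc.drug_index, "dr_ibrw")
    ensure_same_index(features_disease.index, assoc.disease_index, "dr_ibrw")

    sim_drug = composite_similarity(features_drug, assoc, DRUG, config.similarity)
    sim_disease = composite_similarity(features_disease, assoc, DISEASE, config.similarity)

    lengths_drug: WalkLengthVector | int
    lengths_disease: WalkLengthVector | int
    if config.mode == MODE_INDIVIDUAL:
        lengths_drug, lengths_disease = walk_lengths_from_associations(assoc)
    else:
        lengths_drug, lengths_disease = config.fixed_l_r, config.fixed_l_d

    norm_drug = laplacian_normalize(sim_drug)
    norm_disease = laplacian_normalize(sim_disease)
    f_drug = drug_side_walk(norm_disease, assoc, lengths_drug, config.alpha)
    f_disease = disease_side_walk(norm_drug, assoc, lengths_disease, config.alpha)
    return PipelineResult(
        scores=integrate(f_drug, f_disease),
        scores_drug_walk=f_drug,
        scores_disease_walk=f_disease,
        similarity_drug=sim_drug,
        similarity_disease=sim_disease,
        lengths_drug=lengths_drug,
        lengths_disease=lengths_disease,
    )
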