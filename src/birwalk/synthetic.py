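"""Seeded planted-block generator of heterogeneous-network fixtures.

Drugs and diseases are partitioned into co-modules; each module has a
characteristic binary feature template (individual profiles flip template
bits at a small rate) and associations are much denser inside a module
than across modules.  This directly instantiates the guilt-by-association
premise -- similar drugs treat similar diseases -- that the walk-based
ranking is supposed to exploit, so recovery of held-out in-module pairs is
a meaningful end-to-end test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from birwalk.net_core import (
    DISEASE,
    DRUG,
    AssociationMatrix,
    EntityIndex,
    FeatureMatrix,
)


@dataclass(frozen=True)
class SyntheticConfig:
    n_drugs: int = 60
    n_diseases: int = 50
    n_features_drug: int = 64
    n_features_disease: int = 48
    n_blocks: int = 5
    within_assoc_prob: float = 0.3
    cross_assoc_prob: float = 0.01
    feature_flip_prob: float = 0.05
    holdout_frac: float = 0.2
    seed: int = 7

    def __post_init__(self) -> None:
        for name in ("within_assoc_prob", "cross_assoc_prob", "feature_flip_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.holdout_frac < 1.0:
            raise ValueError("holdout_frac must lie in (0, 1)")
        if self.within_assoc_prob <= self.cross_assoc_prob:
            raise ValueError("within_assoc_prob must exceed cross_assoc_prob")
        if self.n_blocks < 1 or self.n_blocks > min(self.n_drugs, self.n_diseases):
            raise ValueError("n_blocks must fit inside both entity sets")


def _block_labels(n: int, n_blocks: int) -> np.ndarray:
    """Contiguous near-equal block assignment for n entities."""
    return np.concatenate(
        [np.full(len(chunk), b) for b, chunk in enumerate(np.array_split(np.arange(n), n_blocks))]
    )


def _templates(rng: np.random.Generator, n_blocks: int, n_features: int) -> np.ndarray:
    templates = rng.integers(0, 2, size=(n_blocks, n_features), dtype=np.int8)
    for b in range(n_blocks):  # an all-zero template would break cosine similarity
        if templates[b].sum() == 0:
            templates[b, rng.integers(0, n_features)] = 1
    return templates


def _features(
    rng: np.random.Generator,
    labels: np.ndarray,
    templates: np.ndarray,
    flip_prob: float,
) -> np.ndarray:
    profiles = templates[labels].copy()
    flips = rng.random(profiles.shape) < flip_prob
    return np.bitwise_xor(profiles, flips.astype(np.int8))


def _draw_associations(
    rng: np.random.Generator, config: SyntheticConfig,
    drug_labels: np.ndarray, disease_labels: np.ndarray,
) -> np.ndarray:
    prob = np.where(
        drug_labels[:, None] == disease_labels[None, :],
        config.within_assoc_prob,
        config.cross_assoc_prob,
    )
    return (rng.random(prob.shape) < prob).astype(np.int8)


def generate(
    config: SyntheticConfig = SyntheticConfig(),
) -> tuple[FeatureMatrix, FeatureMatrix, AssociationMatrix, AssociationMatrix]:
    """Deterministic (features, features, observed, held-out truth) quadruple."""
    rng = np.random.default_rng(config.seed)
    drug_labels = _block_labels(config.n_drugs, config.n_blocks)
    disease_labels = _block_labels(config.n_diseases, config.n_blocks)

    drug_index = EntityIndex(
        kind=DRUG, ids=tuple(f"r{i:03d}" for i in range(config.n_drugs))
    )
    disease_index = EntityIndex(
        kind=DISEASE, ids=tuple(f"d{j:03d}" for j in range(config.n_diseases))
    )

    features_drug = FeatureMatrix(
        index=drug_index,
        values=_features(
            rng,
            drug_labels,
            _templates(rng, config.n_blocks, config.n_features_drug),
            config.feature_flip_prob,
        ),
        feature_names=tuple(f"rf{k}" for k in range(config.n_features_drug)),
    )
    features_disease = FeatureMatrix(
        index=disease_index,
        values=_features(
            rng,
            disease_labels,
            _templates(rng, config.n_blocks, config.n_features_disease),
            config.feature_flip_prob,
        ),
        feature_names=tuple(f"df{k}" for k in range(config.n_features_disease)),
    )

    planted = _draw_associations(rng, config, drug_labels, disease_labels)
    if planted.sum() == 0:  # one retry, then give up
        planted = _draw_associations(rng, config, drug_labels, disease_labels)
        if planted.sum() == 0:
            raise ValueError("generated association matrix has no associations")

    rows, cols = np.nonzero(planted)
    n_pos = rows.size
    n_hold = int(round(config.holdout_frac * n_pos))
    n_hold = min(n_hold, n_pos - 1)  # observed must keep at least one association
    held_idx = rng.choice(n_pos, size=n_hold, replace=False)

    observed_values = planted.copy()
    held_values = np.zeros_like(planted)
    for idx in held_idx.tolist():
        observed_values[rows[idx], cols[idx]] = 0
        held_values[rows[idx], cols[idx]] = 1

    observed = AssociationMatrix(
        drug_index=drug_index, disease_index=disease_index, values=observed_values
    )
    held_out = AssociationMatrix(
        drug_index=drug_index, disease_index=disease_index, values=held_values
    )
    return features_drug, features_disease, observed, held_out


def block_labels(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """The planted module assignment used by ``generate`` (drugs, diseases)."""
    return (
        _block_labels(config.n_drugs, config.n_blocks),
        _block_labels(config.n_diseases, config.n_blocks),
    )
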