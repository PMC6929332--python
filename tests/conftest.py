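import numpy as np
import pytest

from birwalk.net_core import (
    AssociationMatrix,
    EntityIndex,
    FeatureMatrix,
)
from birwalk.synthetic import SyntheticConfig, generate


@pytest.fixture
def drug_index() -> EntityIndex:
    return EntityIndex(kind="drug", ids=("r1", "r2"))


@pytest.fixture
def disease_index() -> EntityIndex:
    return EntityIndex(kind="disease", ids=("d1", "d2"))


@pytest.fixture
def small_assoc(drug_index, disease_index) -> AssociationMatrix:
    return AssociationMatrix(
        drug_index=drug_index,
        disease_index=disease_index,
        values=np.array([[1, 1], [0, 1]], dtype=np.int8),
    )


def make_assoc(values: np.ndarray) -> AssociationMatrix:
    values = np.asarray(values, dtype=np.int8)
    n_r, n_d = values.shape
    return AssociationMatrix(
        drug_index=EntityIndex(kind="drug", ids=tuple(f"r{i}" for i in range(n_r))),
        disease_index=EntityIndex(
            kind="disease", ids=tuple(f"d{j}" for j in range(n_d))
        ),
        values=values,
    )


def make_features(values: np.ndarray, kind: str = "drug") -> FeatureMatrix:
    values = np.asarray(values, dtype=np.int8)
    n, m = values.shape
    prefix = "r" if kind == "drug" else "d"
    return FeatureMatrix(
        index=EntityIndex(kind=kind, ids=tuple(f"{prefix}{i}" for i in range(n))),
        values=values,
        feature_names=tuple(f"f{k}" for k in range(m)),
    )


@pytest.fixture(scope="session")
def planted_fixture():
    """Small deterministic planted-block fixture shared across test modules."""
    config = SyntheticConfig(
        n_drugs=24,
        n_diseases=20,
        n_blocks=4,
        within_assoc_prob=0.5,
        cross_assoc_prob=0.02,
        feature_flip_prob=0.05,
        holdout_frac=0.2,
        seed=11,
    )
    features_drug, features_disease, observed, held_out = generate(config)
    return config, features_drug, features_disease, observed, held_out


@pytest.fixture(scope="session")
def default_fixture():
    """The default-size planted fixture used by the acceptance tests."""
    config = SyntheticConfig()
    return (config, *generate(config))
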