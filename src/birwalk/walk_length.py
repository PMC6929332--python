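"""Bipartite Jaccard influence and per-node walk-length quantification.

A drug's one-hop neighbourhood is its set of associated diseases; a
disease's two-hop neighbourhood is the union of the disease sets of its
associated drugs.  The bipartite Jaccard index compares those commensurate
disease sets, and per-node walk budgets are its row/column sums.  The raw
index matrix doubles as the standalone "JI" link-prediction baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from birwalk.net_core import AssociationMatrix, EntityIndex, ScoreMatrix


@dataclass(frozen=True)
class NeighborSets:
    """One-hop and two-hop neighbourhoods of every drug and disease.

    ``drug_neighbors[i]`` holds disease column indices associated with drug
    i; ``drug_two_hop[i]`` holds drug row indices reachable through any of
    those diseases (and symmetrically for diseases).
    """

    drug_neighbors: tuple[frozenset[int], ...]
    disease_neighbors: tuple[frozenset[int], ...]
    drug_two_hop: tuple[frozenset[int], ...]
    disease_two_hop: tuple[frozenset[int], ...]


@dataclass(frozen=True)
class WalkLengthVector:
    """Per-node real walk budgets with their floored integer companions."""

    kind: str
    index: EntityIndex
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (self.index.size,):
            raise ValueError("walk-length vector shape does not match index")
        if (vals < 0).any():
            raise ValueError("walk lengths must be nonnegative")
        object.__setattr__(self, "values", vals)

    @property
    def floored(self) -> np.ndarray:
        return np.floor(self.values).astype(int)


def neighbor_sets(assoc: AssociationMatrix) -> NeighborSets:
    w = assoc.values
    drug_nb = tuple(frozenset(np.nonzero(w[i])[0].tolist()) for i in range(w.shape[0]))
    dis_nb = tuple(frozenset(np.nonzero(w[:, j])[0].tolist()) for j in range(w.shape[1]))
    drug_two = tuple(
        frozenset().union(*(dis_nb[d] for d in nb)) if nb else frozenset()
        for nb in drug_nb
    )
    dis_two = tuple(
        frozenset().union(*(drug_nb[r] for r in nb)) if nb else frozenset()
        for nb in dis_nb
    )
    return NeighborSets(
        drug_neighbors=drug_nb,
        disease_neighbors=dis_nb,
        drug_two_hop=drug_two,
        disease_two_hop=dis_two,
    )


def jaccard_bipartite(assoc: AssociationMatrix) -> np.ndarray:
    """Jaccard index between each drug's disease set and each disease's two-hop disease set.

    Entry (i, j) compares N(r_i) -- the diseases associated with drug i --
    against the union of disease sets of the drugs associated with disease
    j.  Both operands are disease sets, so intersection and union are well
    defined on the bipartite graph; 0/0 is taken as 0 for isolated nodes.
    """
    w = assoc.values.astype(np.int64)
    # reach[j, k] == 1 iff disease k is treatable by some drug associated with disease j
    reach = ((w.T @ w) > 0).astype(np.int64)
    inter = w @ reach.T
    drug_deg = w.sum(axis=1)
    reach_size = reach.sum(axis=1)
    union = drug_deg[:, None] + reach_size[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        ji = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    return ji.astype(float)


def walk_lengths(
    ji: np.ndarray, drug_index: EntityIndex, disease_index: EntityIndex
) -> tuple[WalkLengthVector, WalkLengthVector]:
    """Row/column sums of the bipartite Jaccard matrix as per-node walk budgets."""
    ji = np.asarray(ji, dtype=float)
    if ji.shape != (drug_index.size, disease_index.size):
        raise ValueError("Jaccard matrix shape does not match indices")
    if ji.min(initial=0.0) < 0 or ji.max(initial=0.0) > 1 + 1e-12:
        raise ValueError("Jaccard entries must lie in [0, 1]")
    l_r = WalkLengthVector(kind="drug", index=drug_index, values=ji.sum(axis=1))
    l_d = WalkLengthVector(kind="disease", index=disease_index, values=ji.sum(axis=0))
    return l_r, l_d


def walk_lengths_from_associations(
    assoc: AssociationMatrix,
) -> tuple[WalkLengthVector, WalkLengthVector]:
    ji = jaccard_bipartite(assoc)
    return walk_lengths(ji, assoc.drug_index, assoc.disease_index)


def jaccard_scores(assoc: AssociationMatrix) -> ScoreMatrix:
    """The Jaccard matrix packaged as a score matrix (the "JI" baseline ranker)."""
    return ScoreMatrix(
        drug_index=assoc.drug_index,
        disease_index=assoc.disease_index,
        values=jaccard_bipartite(assoc),
    )
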