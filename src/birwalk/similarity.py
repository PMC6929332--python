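"""Four-stage composite similarity between drugs (or diseases).

Stage 1 is cosine similarity of binary feature vectors; stage 2 shrinks
non-informative similarities through a logistic transform whose midpoint
sits at a data-driven threshold; stage 3 boosts pairs that co-occur in
cohesive clusters of the association-sharing graph; stage 4 averages the
result with a Gaussian kernel on association profiles.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from birwalk.net_core import (
    DISEASE,
    DRUG,
    AssociationMatrix,
    EntityIndex,
    FeatureMatrix,
    SimilarityMatrix,
    ensure_same_index,
)

logger = logging.getLogger(__name__)

DEFAULT_LOGISTIC_D = math.log(999.0)

#: subrange upper bounds used by the informativeness test, (0,0.1] ... (0.9,1.0]
SUBRANGE_EDGES = np.linspace(0.0, 1.0, 11)


@dataclass(frozen=True)
class LogisticParams:
    """Parameters of the shrinking logistic: midpoint ``x_star``, offset ``d``."""

    x_star: float
    d: float = DEFAULT_LOGISTIC_D

    def __post_init__(self) -> None:
        if not self.d > 0:
            raise ValueError("logistic offset d must be positive")
        if not 0.0 < self.x_star <= 1.0:
            raise ValueError("threshold x_star must lie in (0, 1]")

    @property
    def steepness(self) -> float:
        """Effective steepness making the logistic increasing with midpoint x_star."""
        return -self.d / self.x_star


@dataclass(frozen=True)
class GIPParams:
    """Bandwidth parameters of the Gaussian association-profile kernel."""

    gamma_tilde: float = 1.0

    def __post_init__(self) -> None:
        if not self.gamma_tilde > 0:
            raise ValueError("gamma_tilde must be positive")

    def bandwidth(self, mean_sq_norm: float) -> float:
        if mean_sq_norm <= 0:
            raise ValueError("GIP undefined: no associations")
        return self.gamma_tilde / mean_sq_norm


@dataclass(frozen=True)
class Cluster:
    members: frozenset[str]
    cohesiveness: float


@dataclass(frozen=True)
class ClusterSet:
    clusters: tuple[Cluster, ...]
    penalty_per_node: float = 0.0

    def __len__(self) -> int:
        return len(self.clusters)


@dataclass(frozen=True)
class SimilarityConfig:
    """Step toggles + stage parameters of the composite pipeline."""

    step2_enabled: bool = True
    step3_enabled: bool = True
    step4_enabled: bool = True
    logistic_d: float = DEFAULT_LOGISTIC_D
    n_shuffles: int = 20
    clusterone_penalty: float = 2.0
    clusterone_min_size: int = 2
    clusterone_overlap: float = 0.8
    gip_gamma_tilde: float = 1.0
    seed: int = 0


def cosine_similarity(features: FeatureMatrix) -> SimilarityMatrix:
    """Stage-1 cosine similarity; rows that are all zero yield similarity 0."""
    x = features.values.astype(float)
    norms = np.linalg.norm(x, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    unit = x / safe[:, None]
    sim = unit @ unit.T
    zero = norms == 0
    sim[zero, :] = 0.0
    sim[:, zero] = 0.0
    np.clip(sim, 0.0, 1.0, out=sim)
    sim = (sim + sim.T) / 2.0
    return SimilarityMatrix(index=features.index, values=sim, stage="raw")


def _shared_counterpart_mask(assoc: AssociationMatrix, kind: str) -> np.ndarray:
    """Boolean n x n matrix: pair (i, j) shares >= 1 associated counterpart."""
    w = assoc.values.astype(np.int64)
    if kind == DRUG:
        common = w @ w.T
    elif kind == DISEASE:
        common = w.T @ w
    else:  # pragma: no cover - guarded by EntityIndex kinds
        raise ValueError(f"unknown kind {kind!r}")
    return common > 0


def _subrange_of(values: np.ndarray) -> np.ndarray:
    """Map similarity values to subrange indices 0..9 for (0,0.1]..(0.9,1]; -1 if <= 0."""
    idx = np.ceil(values * 10.0 - 1e-12).astype(int) - 1
    idx[values <= 0.0] = -1
    idx[idx > 9] = 9
    return idx


def informative_threshold(
    s1: SimilarityMatrix,
    assoc: AssociationMatrix,
    n_shuffles: int = 20,
    seed: int = 0,
) -> float:
    """Data-driven boundary ``x_star`` between non-informative and informative similarity.

    Off-diagonal pairs are partitioned into ten similarity subranges.  Each
    subrange is scored by the average similarity contributed by pairs that
    share at least one associated counterpart (the sum of shared-pair
    similarities over the number of pairs in the subrange, so sparsely
    shared subranges score low).  A subrange is non-informative when that
    statistic does not beat its value after randomly permuting similarity
    values among pairs (averaged over ``n_shuffles`` permutations).  The
    returned threshold is the upper bound of the maximal run of
    non-informative subranges starting from the bottom; 0.1 is returned
    with a warning when the bottom subrange is already informative or no
    pair shares any counterpart.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if s1.index.kind == DRUG:
        ensure_same_index(s1.index, assoc.drug_index, "informative_threshold")
    else:
        ensure_same_index(s1.index, assoc.disease_index, "informative_threshold")

    n = s1.index.size
    iu = np.triu_indices(n, k=1)
    vals = s1.values[iu]
    shared = _shared_counterpart_mask(assoc, s1.index.kind)[iu]
    if not shared.any():
        logger.warning("no pair shares an association; falling back to x* = 0.1")
        return 0.1

    # canonical ordering makes the shuffle test invariant to entity ordering
    order = np.lexsort((shared, vals))
    vals = vals[order]
    shared = shared[order]

    def per_bin_shared_mass(v: np.ndarray) -> np.ndarray:
        bins = _subrange_of(v)
        out = np.full(10, np.nan)
        for k in range(10):
            in_bin = bins == k
            if in_bin.any():
                out[k] = float((v * shared)[in_bin].sum() / in_bin.sum())
        return out

    observed = per_bin_shared_mass(vals)

    rng = np.random.default_rng(seed)
    shuffled = np.full((n_shuffles, 10), np.nan)
    for s in range(n_shuffles):
        shuffled[s] = per_bin_shared_mass(vals[rng.permutation(vals.size)])
    # nanmean over shuffles; a bin empty in every shuffle stays NaN
    valid = ~np.isnan(shuffled)
    counts = valid.sum(axis=0)
    sums = np.where(valid, shuffled, 0.0).sum(axis=0)
    shuffled_mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    informative = np.zeros(10, dtype=bool)
    for k in range(10):
        if np.isnan(observed[k]):
            informative[k] = False  # no pairs land here in the real data
        elif np.isnan(shuffled_mean[k]):
            informative[k] = observed[k] > 0  # populated only in the real data
        else:
            informative[k] = observed[k] >= shuffled_mean[k]

    run = 0
    while run < 10 and not informative[run]:
        run += 1
    if run == 0:
        logger.warning("lowest subrange already informative; falling back to x* = 0.1")
        return 0.1
    return float(SUBRANGE_EDGES[run])


def logistic_adjust(s1: SimilarityMatrix, params: LogisticParams) -> SimilarityMatrix:
    """Stage-2 logistic shrink/enlarge; strictly increasing with midpoint at x_star."""
    x = s1.values
    if x.max(initial=0.0) > 1.0 + 1e-9:
        raise ValueError("logistic_adjust expects similarities in [0, 1]")
    adjusted = 1.0 / (1.0 + np.exp(params.steepness * x + params.d))
    np.fill_diagonal(adjusted, 1.0)
    return SimilarityMatrix(index=s1.index, values=adjusted, stage="adjusted")


def sharing_graph(assoc: AssociationMatrix, kind: str) -> nx.Graph:
    """Weighted graph over one kind; weight = number of shared counterparts."""
    w = assoc.values.astype(np.int64)
    if kind == DRUG:
        common = w @ w.T
        ids = assoc.drug_index.ids
    elif kind == DISEASE:
        common = w.T @ w
        ids = assoc.disease_index.ids
    else:
        raise ValueError(f"unknown kind {kind!r}")
    g = nx.Graph()
    g.add_nodes_from(ids)
    rows, cols = np.nonzero(np.triu(common, k=1))
    for i, j in zip(rows.tolist(), cols.tolist()):
        g.add_edge(ids[i], ids[j], weight=int(common[i, j]))
    return g


def _cohesiveness(
    w_in: float, w_bound: float, size: int, penalty_per_node: float
) -> float:
    denom = w_in + w_bound + penalty_per_node * size
    return w_in / denom if denom > 0 else 0.0


def cluster_cohesiveness(
    g: nx.Graph, members: frozenset[str], penalty_per_node: float
) -> float:
    """Recompute f(C) = W_in / (W_in + W_bound + penalty * |C|) from scratch."""
    w_in = 0.0
    w_bound = 0.0
    for u in members:
        for v, data in g.adj[u].items():
            w = data.get("weight", 1.0)
            if v in members:
                w_in += w / 2.0
            else:
                w_bound += w
    return _cohesiveness(w_in, w_bound, len(members), penalty_per_node)


def cluster_one(
    g: nx.Graph,
    penalty_per_node: float = 2.0,
    min_size: int = 2,
    overlap_threshold: float = 0.8,
    seed: int = 0,
) -> ClusterSet:
    """Greedy cohesiveness-maximising clustering of a weighted sharing graph.

    Seeds are unclaimed highest-degree nodes; clusters grow or shrink by the
    single node move that most increases cohesiveness; highly overlapping
    clusters (overlap score |A&B|^2 / (|A||B|) above ``overlap_threshold``)
    are merged; clusters below ``min_size`` are discarded.  The procedure is
    deterministic -- ties are broken by node id -- so ``seed`` only exists
    for interface symmetry.
    """
    del seed  # deterministic tie-breaking; kept for a stable interface
    if g.number_of_nodes() == 0:
        return ClusterSet(clusters=(), penalty_per_node=penalty_per_node)

    degree = {u: float(d) for u, d in g.degree(weight="weight")}
    order = sorted(g.nodes, key=lambda u: (-degree[u], u))
    claimed: set[str] = set()
    raw_clusters: list[frozenset[str]] = []

    for seed_node in order:
        if seed_node in claimed or degree[seed_node] == 0:
            continue
        members: set[str] = {seed_node}
        f = _cohesiveness(0.0, degree[seed_node], 1, penalty_per_node)
        while True:
            best_f = f
            best_move: tuple[str, str] | None = None  # (op, node)
            boundary = sorted(
                {v for u in members for v in g.adj[u] if v not in members}
            )
            for v in boundary:
                trial = frozenset(members | {v})
                fv = cluster_cohesiveness(g, trial, penalty_per_node)
                if fv > best_f + 1e-12:
                    best_f, best_move = fv, ("add", v)
            if len(members) > 1:
                for v in sorted(members):
                    trial = frozenset(members - {v})
                    fv = cluster_cohesiveness(g, trial, penalty_per_node)
                    if fv > best_f + 1e-12:
                        best_f, best_move = fv, ("remove", v)
            if best_move is None:
                break
            op, node = best_move
            if op == "add":
                members.add(node)
            else:
                members.remove(node)
            f = best_f
        claimed.update(members)
        raw_clusters.append(frozenset(members))

    # merge highly overlapping clusters until stable
    merged = True
    while merged:
        merged = False
        for a_pos in range(len(raw_clusters)):
            for b_pos in range(a_pos + 1, len(raw_clusters)):
                a, b = raw_clusters[a_pos], raw_clusters[b_pos]
                inter = len(a & b)
                if inter == 0:
                    continue
                if inter * inter / (len(a) * len(b)) > overlap_threshold:
                    raw_clusters[a_pos] = a | b
                    del raw_clusters[b_pos]
                    merged = True
                    break
            if merged:
                break

    clusters = tuple(
        Cluster(members=c, cohesiveness=cluster_cohesiveness(g, c, penalty_per_node))
        for c in sorted(
            (c for c in raw_clusters if len(c) >= min_size),
            key=lambda c: sorted(c),
        )
    )
    return ClusterSet(clusters=clusters, penalty_per_node=penalty_per_node)


def cluster_boost(s2: SimilarityMatrix, clusters: ClusterSet) -> SimilarityMatrix:
    """Stage-3 boost: multiply co-clustered pairs by (1 + max shared cohesiveness)."""
    n = s2.index.size
    factor = np.ones((n, n))
    for cluster in clusters.clusters:
        pos = sorted(
            s2.index.position(m) for m in cluster.members if m in s2.index
        )
        for a_i, i in enumerate(pos):
            for j in pos[a_i + 1 :]:
                boost = 1.0 + cluster.cohesiveness
                if boost > factor[i, j]:
                    factor[i, j] = boost
                    factor[j, i] = boost
    boosted = s2.values * factor
    np.fill_diagonal(boosted, 1.0)
    return SimilarityMatrix(index=s2.index, values=boosted, stage="boosted")


def gip_kernel(
    assoc: AssociationMatrix, kind: str, params: GIPParams = GIPParams()
) -> SimilarityMatrix:
    """Gaussian kernel on binary association profiles, bandwidth per mean profile norm."""
    if kind == DRUG:
        profiles = assoc.values.astype(float)
        index = assoc.drug_index
    elif kind == DISEASE:
        profiles = assoc.values.T.astype(float)
        index = assoc.disease_index
    else:
        raise ValueError(f"unknown kind {kind!r}")
    sq_norms = (profiles**2).sum(axis=1)
    mean_sq = float(sq_norms.mean())
    gamma = params.bandwidth(mean_sq)
    sq_dist = sq_norms[:, None] + sq_norms[None, :] - 2.0 * (profiles @ profiles.T)
    np.clip(sq_dist, 0.0, None, out=sq_dist)
    kernel = np.exp(-gamma * sq_dist)
    kernel = (kernel + kernel.T) / 2.0
    np.fill_diagonal(kernel, 1.0)
    return SimilarityMatrix(index=index, values=kernel, stage="gip")


def combine(s3: SimilarityMatrix, s_gip: SimilarityMatrix) -> SimilarityMatrix:
    """Stage-4 composite: arithmetic mean of boosted and kernel similarity."""
    ensure_same_index(s3.index, s_gip.index, "combine")
    return SimilarityMatrix(
        index=s3.index, values=(s3.values + s_gip.values) / 2.0, stage="composite"
    )


def composite_similarity(
    features: FeatureMatrix,
    assoc: AssociationMatrix,
    kind: str,
    config: SimilarityConfig = SimilarityConfig(),
) -> SimilarityMatrix:
    """Full stage 1 -> 2 -> 3 -> 4 pipeline with per-stage toggles.

    Disabling stage 2 passes the raw cosine similarity through unchanged;
    disabling stage 3 skips the cluster boost; disabling stage 4 skips both
    the kernel and the combine, so the output is the stage-3 matrix.
    """
    if kind == DRUG:
        ensure_same_index(features.index, assoc.drug_index, "composite_similarity")
    else:
        ensure_same_index(features.index, assoc.disease_index, "composite_similarity")

    s1 = cosine_similarity(features)
    if config.step2_enabled:
        x_star = informative_threshold(
            s1, assoc, n_shuffles=config.n_shuffles, seed=config.seed
        )
        s2 = logistic_adjust(s1, LogisticParams(x_star=x_star, d=config.logistic_d))
    else:
        s2 = s1
    if config.step3_enabled:
        graph = sharing_graph(assoc, kind)
        clusters = cluster_one(
            graph,
            penalty_per_node=config.clusterone_penalty,
            min_size=config.clusterone_min_size,
            overlap_threshold=config.clusterone_overlap,
            seed=config.seed,
        )
        s3 = cluster_boost(s2, clusters)
    else:
        s3 = s2
    if not config.step4_enabled:
        return s3
    s_gip = gip_kernel(assoc, kind, GIPParams(gamma_tilde=config.gip_gamma_tilde))
    return combine(s3, s_gip)
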