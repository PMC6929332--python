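"""Domain types, identifier alignment and TSV readers/writers.

Conventions used throughout the package:

* drugs on rows, diseases on columns, everywhere;
* identifier matching is exact-string and case-sensitive;
* feature tables are tab-separated with a mandatory header row,
  association pair lists are two-column tab-separated without a header.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

DRUG = "drug"
DISEASE = "disease"
_KINDS = (DRUG, DISEASE)

#: tolerance used when validating symmetry of similarity matrices
SYMMETRY_TOL = 1e-9


class FormatError(ValueError):
    """Raised when an input file violates the documented format."""


class IndexMismatchError(ValueError):
    """Raised when two objects built over different entity indices meet."""


@dataclass(frozen=True)
class EntityIndex:
    """Ordered, immutable set of entity identifiers of one kind."""

    kind: str
    ids: tuple[str, ...]
    _pos: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown entity kind {self.kind!r}")
        if len(self.ids) == 0:
            raise ValueError("EntityIndex requires at least one id")
        if len(set(self.ids)) != len(self.ids):
            seen: set[str] = set()
            dup = next(i for i in self.ids if i in seen or seen.add(i))
            raise ValueError(f"duplicate {self.kind} id {dup!r}")
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(self, "_pos", {i: p for p, i in enumerate(self.ids)})

    @property
    def size(self) -> int:
        return len(self.ids)

    def position(self, entity_id: str) -> int:
        try:
            return self._pos[entity_id]
        except KeyError:
            raise KeyError(f"unknown {self.kind} id {entity_id!r}") from None

    def __contains__(self, entity_id: object) -> bool:
        return entity_id in self._pos

    def __len__(self) -> int:
        return len(self.ids)


def ensure_same_index(a: EntityIndex, b: EntityIndex, context: str = "") -> None:
    """Fail loudly when two indices are not identical (same kind, ids, order)."""
    if a.kind != b.kind or a.ids != b.ids:
        where = f" in {context}" if context else ""
        raise IndexMismatchError(
            f"entity index mismatch{where}: "
            f"{a.kind}[{a.size}] vs {b.kind}[{b.size}]"
        )


def _as_binary(values: np.ndarray, what: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.ndim != 2:
        raise ValueError(f"{what} must be 2-D, got shape {arr.shape}")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{what} entries must be 0/1")
    return arr.astype(np.int8)


@dataclass(frozen=True)
class FeatureMatrix:
    """Binary entity x feature matrix (fingerprints or symptoms)."""

    index: EntityIndex
    values: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        vals = _as_binary(self.values, "feature matrix")
        if vals.shape[0] != self.index.size:
            raise ValueError("row count does not match entity index")
        if vals.shape[1] != len(self.feature_names):
            raise ValueError("column count does not match feature names")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "feature_names", tuple(self.feature_names))

    @property
    def feature_count(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class AssociationMatrix:
    """Binary drugs x diseases matrix of known associations."""

    drug_index: EntityIndex
    disease_index: EntityIndex
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = _as_binary(self.values, "association matrix")
        if vals.shape != (self.drug_index.size, self.disease_index.size):
            raise ValueError(
                f"association matrix shape {vals.shape} does not match "
                f"indices ({self.drug_index.size}, {self.disease_index.size})"
            )
        object.__setattr__(self, "values", vals)

    @property
    def n_associations(self) -> int:
        return int(self.values.sum())

    def pairs(self) -> list[tuple[str, str]]:
        """Known (drug id, disease id) pairs in row-major order."""
        rows, cols = np.nonzero(self.values)
        return [
            (self.drug_index.ids[i], self.disease_index.ids[j])
            for i, j in zip(rows.tolist(), cols.tolist())
        ]


SIMILARITY_STAGES = ("raw", "adjusted", "boosted", "gip", "composite", "normalized")


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric nonnegative similarity over one node kind at a pipeline stage."""

    index: EntityIndex
    values: np.ndarray
    stage: str

    def __post_init__(self) -> None:
        if self.stage not in SIMILARITY_STAGES:
            raise ValueError(f"unknown similarity stage {self.stage!r}")
        vals = np.asarray(self.values, dtype=float)
        n = self.index.size
        if vals.shape != (n, n):
            raise ValueError(f"similarity shape {vals.shape} != ({n}, {n})")
        if not np.isfinite(vals).all():
            raise ValueError("similarity entries must be finite")
        if (vals < -SYMMETRY_TOL).any():
            raise ValueError("similarity entries must be nonnegative")
        if np.abs(vals - vals.T).max(initial=0.0) > SYMMETRY_TOL:
            raise ValueError("similarity matrix is not symmetric within 1e-9")
        object.__setattr__(self, "values", np.clip(vals, 0.0, None))


@dataclass(frozen=True)
class ScoreMatrix:
    """Real drugs x diseases relevance matrix produced by the walks."""

    drug_index: EntityIndex
    disease_index: EntityIndex
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (self.drug_index.size, self.disease_index.size):
            raise ValueError("score matrix shape does not match indices")
        if not np.isfinite(vals).all():
            raise ValueError("score matrix entries must be finite")
        object.__setattr__(self, "values", vals)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_feature_table(path: str | Path, kind: str) -> FeatureMatrix:
    """Read a TSV feature table (header row, first column id, binary cells)."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty feature table") from None
        if len(header) < 2:
            raise FormatError(f"{path}: feature table needs an id column plus features")
        feature_names = tuple(header[1:])
        ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(header)} columns, got {len(row)}"
                )
            entity_id = row[0]
            if entity_id in ids:
                raise FormatError(f"{path}:{lineno}: duplicate id {entity_id!r}")
            parsed: list[int] = []
            for col, cell in zip(feature_names, row[1:]):
                if cell not in ("0", "1"):
                    raise FormatError(
                        f"{path}:{lineno}: non-binary value {cell!r} "
                        f"in column {col!r} (row id {entity_id!r})"
                    )
                parsed.append(int(cell))
            ids.append(entity_id)
            rows.append(parsed)
    if not ids:
        raise FormatError(f"{path}: feature table has no data rows")
    index = EntityIndex(kind=kind, ids=tuple(ids))
    return FeatureMatrix(index=index, values=np.array(rows, dtype=np.int8),
                         feature_names=feature_names)


def write_feature_table(features: FeatureMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["id", *features.feature_names])
        for entity_id, row in zip(features.index.ids, features.values):
            writer.writerow([entity_id, *(int(v) for v in row)])


def read_association_pairs(path: str | Path) -> list[tuple[str, str]]:
    """Read a headerless two-column TSV of (drug id, disease id) pairs."""
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with path.open(newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row:
                continue
            if len(row) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(row)}")
            pairs.append((row[0], row[1]))
    return pairs


def associations_from_pairs(
    pairs: Iterable[tuple[str, str]],
    drugs: EntityIndex,
    diseases: EntityIndex,
) -> AssociationMatrix:
    values = np.zeros((drugs.size, diseases.size), dtype=np.int8)
    seen: set[tuple[str, str]] = set()
    for drug_id, disease_id in pairs:
        if drug_id not in drugs or disease_id not in diseases:
            raise FormatError(
                f"association pair ({drug_id!r}, {disease_id!r}) references an unknown id"
            )
        if (drug_id, disease_id) in seen:
            logger.warning(
                "duplicate association pair (%s, %s) collapsed", drug_id, disease_id
            )
            continue
        seen.add((drug_id, disease_id))
        values[drugs.position(drug_id), diseases.position(disease_id)] = 1
    return AssociationMatrix(drug_index=drugs, disease_index=diseases, values=values)


def read_associations(
    path: str | Path, drugs: EntityIndex, diseases: EntityIndex
) -> AssociationMatrix:
    """Read a pair list and align it to the given entity indices."""
    return associations_from_pairs(read_association_pairs(path), drugs, diseases)


def write_associations(associations: AssociationMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for drug_id, disease_id in associations.pairs():
            writer.writerow([drug_id, disease_id])


def rank_unknown_pairs(
    scores: ScoreMatrix, known: AssociationMatrix, k: int | None = None
) -> list[tuple[int, str, str, float]]:
    """Rank pairs unknown in ``known`` by score, ties broken lexicographically."""
    ensure_same_index(scores.drug_index, known.drug_index, "rank_unknown_pairs")
    ensure_same_index(scores.disease_index, known.disease_index, "rank_unknown_pairs")
    rows, cols = np.nonzero(known.values == 0)
    candidates = sorted(
        (
            (
                -scores.values[i, j],
                scores.drug_index.ids[i],
                scores.disease_index.ids[j],
            )
            for i, j in zip(rows.tolist(), cols.tolist())
        )
    )
    if k is not None:
        if k < 1:
            raise ValueError("k must be >= 1")
        if k > len(candidates):
            logger.warning(
                "requested top-%d but only %d unknown pairs exist; truncating",
                k,
                len(candidates),
            )
        candidates = candidates[:k]
    return [
        (rank, drug_id, disease_id, -neg_score)
        for rank, (neg_score, drug_id, disease_id) in enumerate(candidates, start=1)
    ]


def write_ranked_predictions(
    scores: ScoreMatrix, known: AssociationMatrix, k: int, path: str | Path
) -> None:
    """Write the top-k not-yet-known pairs as a TSV of rank/drug/disease/score."""
    ranked = rank_unknown_pairs(scores, known, k)
    if not ranked:
        logger.warning("no unknown pairs to rank; writing empty prediction table")
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["rank", "drug", "disease", "score"])
        for rank, drug_id, disease_id, score in ranked:
            writer.writerow([rank, drug_id, disease_id, f"{score:.6g}"])


def write_score_matrix(scores: ScoreMatrix, path: str | Path) -> None:
    """Write a full score matrix as TSV (drugs on rows, header of disease ids)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["drug", *scores.disease_index.ids])
        for drug_id, row in zip(scores.drug_index.ids, scores.values):
            writer.writerow([drug_id, *(f"{v:.10g}" for v in row)])


def make_index(kind: str, ids: Sequence[str]) -> EntityIndex:
    return EntityIndex(kind=kind, ids=tuple(ids))
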