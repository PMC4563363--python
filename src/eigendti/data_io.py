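"""Labeled matrix and edge-list I/O plus ID-space alignment.

All on-disk formats are plain TSV:

* **similarity / kernel / score matrix** — first header cell empty, remaining
  header cells are column-axis IDs, first column of each body row is the
  row-axis ID, body cells are floats ('.' decimal, UTF-8);
* **interaction edge list** — two headerless columns ``drug_id<TAB>target_id``;
* **ranked edge list** — four columns ``rank, drug_id, target_id, score``
  sorted by descending score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_SIG_DIGITS = 15  # written precision for scores; lossless for float64 ranking


def _check_unique(ids: Sequence[str], axis: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise ValueError(f"duplicate {axis} IDs: {sorted(set(dups))}")


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square labeled similarity matrix; may be asymmetric or indefinite."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"similarity matrix shape {self.values.shape} does not match "
                f"{n} IDs"
            )
        _check_unique(self.ids, "entity")

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class InteractionMatrix:
    """Binary drug x target adjacency Y over labeled ID axes."""

    drug_ids: tuple[str, ...]
    target_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "drug_ids", tuple(str(i) for i in self.drug_ids))
        object.__setattr__(self, "target_ids", tuple(str(i) for i in self.target_ids))
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.drug_ids), len(self.target_ids)):
            raise ValueError(
                f"interaction matrix shape {vals.shape} does not match ID axes "
                f"({len(self.drug_ids)}, {len(self.target_ids)})"
            )
        if not np.isin(vals, (0.0, 1.0)).all():
            bad = vals[~np.isin(vals, (0.0, 1.0))]
            raise ValueError(f"interaction entries must be 0 or 1; found {bad[:5]}")
        object.__setattr__(self, "values", vals)
        _check_unique(self.drug_ids, "drug")
        _check_unique(self.target_ids, "target")

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_targets(self) -> int:
        return len(self.target_ids)


@dataclass(frozen=True)
class ScoreMatrix:
    """Real-valued prediction scores aligned to an interaction matrix."""

    drug_ids: tuple[str, ...]
    target_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "drug_ids", tuple(str(i) for i in self.drug_ids))
        object.__setattr__(self, "target_ids", tuple(str(i) for i in self.target_ids))
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.drug_ids), len(self.target_ids)):
            raise ValueError(
                f"score matrix shape {vals.shape} does not match ID axes"
            )
        if not np.isfinite(vals).all():
            raise ValueError("score matrix contains non-finite entries")
        object.__setattr__(self, "values", vals)
        _check_unique(self.drug_ids, "drug")
        _check_unique(self.target_ids, "target")


def read_similarity(path: str | Path, format: str = "tsv_matrix") -> SimilarityMatrix:
    """Read a labeled square similarity matrix from TSV.

    Row IDs define the ID order; row and column ID sets must coincide
    (columns are permuted to row order if needed).
    """
    if format != "tsv_matrix":
        raise ValueError(f"unknown similarity format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows
        raise ValueError(f"{path}: malformed TSV matrix: {exc}") from exc
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    _check_unique(row_ids, "row")
    _check_unique(col_ids, "column")
    if set(row_ids) != set(col_ids):
        raise ValueError(f"{path}: row/column ID mismatch")
    df = df[row_ids]  # permute columns into row order
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        for rid in row_ids:
            for cid in row_ids:
                try:
                    float(df.at[rid, cid])
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric cell at row {rid!r}, column {cid!r}"
                    ) from exc
        raise
    return SimilarityMatrix(ids=tuple(row_ids), values=values)


def write_similarity(sim: SimilarityMatrix, path: str | Path) -> None:
    """Write a labeled matrix as TSV (mirrors :func:`read_similarity`)."""
    df = pd.DataFrame(sim.values, index=list(sim.ids), columns=list(sim.ids))
    df.to_csv(path, sep="\t", float_format=f"%.{_SIG_DIGITS}g")


def read_interactions(
    path: str | Path,
    format: str = "edge_list",
    drug_ids: Iterable[str] | None = None,
    target_ids: Iterable[str] | None = None,
) -> InteractionMatrix:
    """Read known interactions as an edge list or labeled 0/1 matrix.

    Edge-list semantics: listed (drug, target) pairs are 1, all other pairs 0.
    When ID universes are not given they default to the sorted distinct
    endpoints; duplicate edges collapse to a single 1.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv_matrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        d_ids = tuple(str(i) for i in df.index)
        t_ids = tuple(str(c) for c in df.columns)
        if drug_ids is not None or target_ids is not None:
            raise ValueError("explicit ID lists only apply to edge_list input")
        return InteractionMatrix(d_ids, t_ids, df.to_numpy(dtype=float))
    if format != "edge_list":
        raise ValueError(f"unknown interaction format {format!r}")
    edges_df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if edges_df.shape[1] < 2:
        raise ValueError(f"{path}: edge list needs two tab-separated columns")
    edges = list(zip(edges_df[0], edges_df[1]))
    return interactions_from_edges(edges, drug_ids=drug_ids, target_ids=target_ids)


def interactions_from_edges(
    edges: Sequence[tuple[str, str]],
    drug_ids: Iterable[str] | None = None,
    target_ids: Iterable[str] | None = None,
) -> InteractionMatrix:
    """Build a dense adjacency from (drug_id, target_id) pairs."""
    edges = [(str(d), str(t)) for d, t in edges]
    if len(set(edges)) < len(edges):
        logger.warning(
            "edge list contains %d duplicate pair(s); collapsing",
            len(edges) - len(set(edges)),
        )
    d_ids = (
        tuple(str(i) for i in drug_ids)
        if drug_ids is not None
        else tuple(sorted({d for d, _ in edges}))
    )
    t_ids = (
        tuple(str(i) for i in target_ids)
        if target_ids is not None
        else tuple(sorted({t for _, t in edges}))
    )
    d_index = {d: i for i, d in enumerate(d_ids)}
    t_index = {t: j for j, t in enumerate(t_ids)}
    Y = np.zeros((len(d_ids), len(t_ids)))
    for d, t in edges:
        if d not in d_index:
            raise ValueError(f"edge references unknown drug ID {d!r}")
        if t not in t_index:
            raise ValueError(f"edge references unknown target ID {t!r}")
        Y[d_index[d], t_index[t]] = 1.0
    return InteractionMatrix(d_ids, t_ids, Y)


def write_interactions(inter: InteractionMatrix, path: str | Path,
                       format: str = "edge_list") -> None:
    path = Path(path)
    if format == "edge_list":
        rows = [
            (inter.drug_ids[i], inter.target_ids[j])
            for i, j in zip(*np.nonzero(inter.values))
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
    elif format == "tsv_matrix":
        df = pd.DataFrame(
            inter.values.astype(int),
            index=list(inter.drug_ids),
            columns=list(inter.target_ids),
        )
        df.to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown interaction format {format!r}")


def align(similarity: SimilarityMatrix, ids: Sequence[str]) -> SimilarityMatrix:
    """Permute-and-subset a similarity matrix to a requested ID order."""
    ids = [str(i) for i in ids]
    index = {e: i for i, e in enumerate(similarity.ids)}
    missing = [i for i in ids if i not in index]
    if missing:
        raise KeyError(f"IDs absent from similarity matrix, missing: {missing}")
    idx = np.array([index[i] for i in ids], dtype=int)
    return SimilarityMatrix(ids=tuple(ids), values=similarity.values[np.ix_(idx, idx)])


def average_similarities(mats: Sequence[SimilarityMatrix]) -> SimilarityMatrix:
    """Entrywise mean of similarity matrices over an identical ID set.

    This is how complementary drug-similarity sources (e.g. chemical-structure
    and ATC-taxonomy similarity) are combined into a single S_d.
    """
    if not mats:
        raise ValueError("cannot average an empty list of similarity matrices")
    ref = mats[0]
    for m in mats[1:]:
        if set(m.ids) != set(ref.ids):
            raise ValueError("similarity matrices have different ID sets; align first")
    aligned = [align(m, ref.ids) for m in mats]
    mean = np.mean([m.values for m in aligned], axis=0)
    return SimilarityMatrix(ids=ref.ids, values=mean)


def write_scores(scores: ScoreMatrix, path: str | Path,
                 format: str = "tsv_matrix") -> None:
    """Write prediction scores as a labeled matrix or a ranked edge list."""
    path = Path(path)
    if format == "tsv_matrix":
        df = pd.DataFrame(
            scores.values, index=list(scores.drug_ids), columns=list(scores.target_ids)
        )
        df.to_csv(path, sep="\t", float_format=f"%.{_SIG_DIGITS}g")
    elif format == "ranked_edge_list":
        n_d, n_t = scores.values.shape
        flat = [
            (scores.drug_ids[i], scores.target_ids[j], scores.values[i, j])
            for i in range(n_d)
            for j in range(n_t)
        ]
        flat.sort(key=lambda r: (-r[2], r[0], r[1]))
        df = pd.DataFrame(
            [(k + 1, d, t, s) for k, (d, t, s) in enumerate(flat)],
            columns=["rank", "drug_id", "target_id", "score"],
        )
        df.to_csv(path, sep="\t", index=False, float_format=f"%.{_SIG_DIGITS}g")
    else:
        raise ValueError(f"unknown score format {format!r}")


def read_scores(path: str | Path) -> ScoreMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ScoreMatrix(
        drug_ids=tuple(str(i) for i in df.index),
        target_ids=tuple(str(c) for c in df.columns),
        values=df.to_numpy(dtype=float),
    )
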