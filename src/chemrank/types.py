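"""Core domain types for indication ranking from chemical interaction data.

The model operates on four kinds of objects: a fixed ordered catalogue of
indication categories, a set of drugs carrying binary label vectors over that
catalogue, a symmetric non-negative interaction network between compounds
(absent pair == score 0), and optionally a dense numeric descriptor matrix.
Predictions are full-length rankings of the catalogue (``RankedPrediction``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LabelCatalog",
    "LabelledDrugSet",
    "InteractionNetwork",
    "DescriptorMatrix",
    "ScoreVector",
    "RankedPrediction",
]


class LabelCatalog:
    """An ordered, fixed set of indication category tags (C1...CM).

    The catalogue order is fixed at construction and is the tie-breaking and
    reporting order everywhere downstream: equal-score categories are always
    listed in ascending catalogue position.
    """

    __slots__ = ("_categories", "_index")

    def __init__(self, categories: Sequence[str]):
        cats = tuple(str(c) for c in categories)
        if len(cats) < 1:
            raise ValueError("catalog needs at least one category")
        if any(not c for c in cats):
            raise ValueError("category identifiers must be non-empty")
        if len(set(cats)) != len(cats):
            raise ValueError("category identifiers must be unique")
        self._categories = cats
        self._index = {c: i for i, c in enumerate(cats)}

    @property
    def categories(self) -> tuple[str, ...]:
        return self._categories

    def index(self, tag: str) -> int:
        try:
            return self._index[tag]
        except KeyError:
            raise KeyError(
                f"unknown category {tag!r}; catalog is {list(self._categories)}"
            ) from None

    def __contains__(self, tag: object) -> bool:
        return tag in self._index

    def __len__(self) -> int:
        return len(self._categories)

    def __iter__(self) -> Iterator[str]:
        return iter(self._categories)

    def __getitem__(self, i: int) -> str:
        return self._categories[i]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, LabelCatalog) and other._categories == self._categories

    def __hash__(self) -> int:
        return hash(self._categories)

    def __repr__(self) -> str:
        return f"LabelCatalog({list(self._categories)!r})"


class LabelledDrugSet:
    """Drugs with binary indication vectors over a :class:`LabelCatalog`.

    Each drug carries an indicator vector y of length M with y_k = 1 iff the
    drug treats category k; every drug must have at least one positive label
    (multi-label is allowed, so the total label-pair count is >= n_drugs).
    """

    def __init__(
        self,
        catalog: LabelCatalog,
        drug_ids: Sequence[str],
        labels: np.ndarray | Sequence[Sequence[int]],
    ):
        ids = tuple(str(d) for d in drug_ids)
        if len(set(ids)) != len(ids):
            dupes = sorted({d for d in ids if ids.count(d) > 1})
            raise ValueError(f"duplicate drug ids: {dupes}")
        y = np.asarray(labels, dtype=np.int8)
        if y.size == 0:
            y = y.reshape(0, len(catalog))
        if y.ndim != 2 or y.shape != (len(ids), len(catalog)):
            raise ValueError(
                f"label matrix shape {y.shape} != ({len(ids)}, {len(catalog)})"
            )
        if not np.isin(y, (0, 1)).all():
            raise ValueError("labels must be binary")
        if len(ids) and (y.sum(axis=1) == 0).any():
            bad = [ids[i] for i in np.flatnonzero(y.sum(axis=1) == 0)]
            raise ValueError(f"drugs with no indication are rejected: {bad}")
        self.catalog = catalog
        self.drug_ids = ids
        self.labels = y
        self._row = {d: i for i, d in enumerate(ids)}

    @classmethod
    def from_pairs(
        cls, catalog: LabelCatalog, pairs: Iterable[tuple[str, str]]
    ) -> "LabelledDrugSet":
        """Build from (drug_id, category_tag) pairs, preserving first-seen drug order."""
        order: list[str] = []
        rows: dict[str, set[int]] = {}
        for drug, tag in pairs:
            k = catalog.index(tag)
            if drug not in rows:
                rows[drug] = set()
                order.append(drug)
            rows[drug].add(k)
        y = np.zeros((len(order), len(catalog)), dtype=np.int8)
        for i, d in enumerate(order):
            y[i, sorted(rows[d])] = 1
        return cls(catalog, order, y)

    def __len__(self) -> int:
        return len(self.drug_ids)

    def __contains__(self, drug_id: object) -> bool:
        return drug_id in self._row

    def row(self, drug_id: str) -> int:
        try:
            return self._row[drug_id]
        except KeyError:
            raise KeyError(f"drug {drug_id!r} not in labelled set") from None

    def label_vector(self, drug_id: str) -> np.ndarray:
        return self.labels[self.row(drug_id)]

    def label_set(self, drug_id: str) -> frozenset[str]:
        y = self.label_vector(drug_id)
        return frozenset(self.catalog[k] for k in np.flatnonzero(y))

    def label_sets(self) -> dict[str, frozenset[str]]:
        return {d: self.label_set(d) for d in self.drug_ids}

    @property
    def n_label_pairs(self) -> int:
        """Total label count sum_i n_i (>= number of drugs)."""
        return int(self.labels.sum())

    @property
    def avg_labels(self) -> float:
        """Average number of indications per drug."""
        if not self.drug_ids:
            raise ValueError("empty drug set has no average label count")
        return self.n_label_pairs / len(self.drug_ids)

    def drop(self, drug_ids: Iterable[str]) -> "LabelledDrugSet":
        omit = set(drug_ids)
        keep = [i for i, d in enumerate(self.drug_ids) if d not in omit]
        return LabelledDrugSet(
            self.catalog,
            [self.drug_ids[i] for i in keep],
            self.labels[keep] if keep else np.zeros((0, len(self.catalog)), np.int8),
        )

    def subset(self, drug_ids: Iterable[str]) -> "LabelledDrugSet":
        wanted = [d for d in drug_ids]
        idx = [self.row(d) for d in wanted]
        return LabelledDrugSet(self.catalog, wanted, self.labels[idx])

    def category_counts(self) -> np.ndarray:
        """Per-category drug counts (column sums of the label matrix)."""
        return self.labels.sum(axis=0)

    def __repr__(self) -> str:
        return (
            f"<LabelledDrugSet n_drugs={len(self)} M={len(self.catalog)} "
            f"n_label_pairs={self.n_label_pairs}>"
        )


class InteractionNetwork:
    """Symmetric map from unordered compound pairs to positive confidence scores.

    Mirrors the interactivity convention of chemical-chemical interaction
    databases: two compounds are interactive iff their (combined) score is
    greater than zero, so only positive scores are stored and ``score`` on an
    absent pair returns exactly 0.  Self-pairs are never stored; a self-edge
    offered at construction is dropped with a warning.
    """

    def __init__(self, edges: Mapping[tuple[str, str], float] | None = None):
        self._adj: dict[str, dict[str, float]] = {}
        self._n_edges = 0
        if edges:
            for (a, b), q in edges.items():
                self.add_edge(a, b, q)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add_edge(self, a: str, b: str, q: float, *, on_duplicate: str = "max") -> None:
        a, b = str(a), str(b)
        q = float(q)
        if not math.isfinite(q):
            raise ValueError(f"non-finite score for pair ({a}, {b})")
        if a == b:
            logger.warning("ignoring self-edge on %r", a)
            return
        if q <= 0:
            return  # zero/absent are equivalent and never stored
        cur = self._adj.get(a, {}).get(b)
        if cur is not None:
            if cur != q:
                logger.warning(
                    "duplicate pair (%s, %s) with scores %g and %g; keeping max",
                    a, b, cur, q,
                )
            q = max(cur, q)
        else:
            self._n_edges += 1
        self._adj.setdefault(a, {})[b] = q
        self._adj.setdefault(b, {})[a] = q

    def score(self, a: str, b: str) -> float:
        """Confidence score Q(a, b); 0 for absent pairs and self-pairs."""
        if a == b:
            return 0.0
        return self._adj.get(a, {}).get(b, 0.0)

    def neighbors(self, a: str) -> Mapping[str, float]:
        return self._adj.get(a, {})

    @property
    def n_edges(self) -> int:
        """Number of unordered interactive pairs."""
        return self._n_edges

    @property
    def compounds(self) -> frozenset[str]:
        return frozenset(self._adj)

    def edges(self) -> Iterator[tuple[str, str, float]]:
        """Iterate unordered edges as (a, b, score) with a < b."""
        for a, nbrs in self._adj.items():
            for b, q in nbrs.items():
                if a < b:
                    yield a, b, q

    def score_multiset(self) -> list[float]:
        return sorted(q for _, _, q in self.edges())

    def scale(self, factor: float) -> "InteractionNetwork":
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return InteractionNetwork({(a, b): q * factor for a, b, q in self.edges()})

    def induced(self, drug_ids: Iterable[str]) -> "InteractionNetwork":
        keep = set(drug_ids)
        return InteractionNetwork(
            {(a, b): q for a, b, q in self.edges() if a in keep and b in keep}
        )

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, InteractionNetwork)
            and sorted(self.edges()) == sorted(other.edges())
        )

    def __repr__(self) -> str:
        return f"<InteractionNetwork {len(self.compounds)} compounds, {self.n_edges} edges>"


class DescriptorMatrix:
    """Dense numeric molecular-descriptor matrix, drugs x descriptors.

    Backed by a :class:`pandas.DataFrame` indexed by drug id; all vectors share
    one dimension and contain no missing values (the loader drops any column
    with a missing entry before construction).
    """

    def __init__(self, frame: pd.DataFrame):
        if frame.isna().any().any():
            raise ValueError("descriptor matrix must not contain missing values")
        if frame.shape[1] == 0:
            raise ValueError("no usable descriptors")
        if frame.index.has_duplicates:
            raise ValueError("duplicate drug ids in descriptor matrix")
        self.frame = frame.astype(float)

    @property
    def drug_ids(self) -> tuple[str, ...]:
        return tuple(str(d) for d in self.frame.index)

    @property
    def dimension(self) -> int:
        return self.frame.shape[1]

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(str(c) for c in self.frame.columns)

    def __contains__(self, drug_id: object) -> bool:
        return drug_id in self.frame.index

    def vector(self, drug_id: str) -> np.ndarray:
        try:
            return self.frame.loc[drug_id].to_numpy(dtype=float)
        except KeyError:
            raise KeyError(f"no descriptor row for drug {drug_id!r}") from None

    def __repr__(self) -> str:
        return f"<DescriptorMatrix {self.frame.shape[0]} drugs x {self.dimension}-D>"


@dataclass(frozen=True)
class ScoreVector:
    """Per-category likelihood scores for one query drug, in catalogue order."""

    query_id: str
    scores: np.ndarray
    catalog: LabelCatalog

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.shape != (len(self.catalog),):
            raise ValueError(
                f"score vector length {s.shape} != catalog size {len(self.catalog)}"
            )
        object.__setattr__(self, "scores", s)

    def as_dict(self) -> dict[str, float]:
        return {c: float(q) for c, q in zip(self.catalog, self.scores)}


@dataclass(frozen=True)
class RankedPrediction:
    """Full descending-score ordering of the catalogue for one query drug.

    ``categories[j-1]`` is the j-th order prediction.  ``tie_groups`` partitions
    the positions 0..M-1 into runs of equal score; within a tie group the
    categories appear in catalogue order, so the ranking is deterministic.
    """

    query_id: str
    categories: tuple[str, ...]
    scores: tuple[float, ...]
    tie_groups: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        if len(self.categories) != len(self.scores):
            raise ValueError("categories and scores must align")
        if any(
            self.scores[i] < self.scores[i + 1] for i in range(len(self.scores) - 1)
        ):
            raise ValueError("scores must be non-increasing along the ranking")

    def order_of(self, category: str) -> int:
        """1-based prediction order of ``category`` within this ranking."""
        return self.categories.index(category) + 1

    def top(self, m: int) -> tuple[str, ...]:
        """The first m predictions (the m lowest-order candidates)."""
        if m < 0:
            raise ValueError("m must be non-negative")
        return self.categories[:m]

    def predicted_set(self, m: int) -> frozenset[str]:
        return frozenset(self.top(m))

    def truncate_zero(self) -> "RankedPrediction":
        """Drop the zero-score tail, keeping only positively scored candidates."""
        keep = sum(1 for q in self.scores if q > 0)
        groups = tuple(
            g for g in self.tie_groups if all(p < keep for p in g)
        )
        return RankedPrediction(
            self.query_id, self.categories[:keep], self.scores[:keep], groups
        )

    def __len__(self) -> int:
        return len(self.categories)
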