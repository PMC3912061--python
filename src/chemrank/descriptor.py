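"""Descriptor-based comparison method: cosine similarity replaces interaction scores.

Each drug is a fixed-dimension numeric vector of molecular descriptors; the
pairwise relationship of two drugs is the cosine of the angle between their
vectors, and category scores are the cosine-weighted vote of the training
drugs, reusing the same ranking machinery as the interaction method.  Cosines
may be negative and are summed as-is — negative structural evidence is
meaningful for ranking, and the score formula has no clipping.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np

from .interaction import rank_categories
from .types import DescriptorMatrix, LabelledDrugSet, RankedPrediction, ScoreVector

logger = logging.getLogger(__name__)

__all__ = ["cosine_similarity", "score_categories_descriptor", "predict_descriptor"]


def cosine_similarity(v1: np.ndarray, v2: np.ndarray) -> float:
    """Cosine of the angle between two descriptor vectors: dot(v1,v2)/(|v1||v2|).

    If either vector has zero norm the similarity is defined as 0 (a neutral
    value; the angle is undefined), with a warning.
    """
    a = np.asarray(v1, dtype=float)
    b = np.asarray(v2, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        logger.warning("zero-norm descriptor vector; cosine defined as 0")
        return 0.0
    return float(a @ b / (na * nb))


def score_categories_descriptor(
    query_id: str, train: LabelledDrugSet, desc: DescriptorMatrix
) -> ScoreVector:
    """Cosine-weighted per-category scores for one query drug.

    score_k = sum over training drugs d != query of cos(query, d) * y_{d,k}.
    Entries may be negative.  Every training drug and the query must have a
    descriptor row; the query is excluded from its own sum.
    """
    if len(train) == 0:
        raise ValueError("training set is empty")
    v_q = desc.vector(query_id)
    w = np.fromiter(
        (
            cosine_similarity(v_q, desc.vector(d)) if d != query_id else 0.0
            for d in train.drug_ids
        ),
        dtype=float,
        count=len(train),
    )
    return ScoreVector(query_id, w @ train.labels, train.catalog)


def predict_descriptor(
    query_ids: Sequence[str] | Iterable[str],
    train: LabelledDrugSet,
    desc: DescriptorMatrix,
    truncate_zero: bool = False,
) -> list[RankedPrediction]:
    """Rank indications for each query drug using descriptor cosines."""
    return [
        rank_categories(
            score_categories_descriptor(q, train, desc), truncate_zero=truncate_zero
        )
        for q in query_ids
    ]
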