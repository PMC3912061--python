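"""Guilt-by-association indication scoring over a chemical interaction network.

For a query drug q and a labelled training set, the likelihood score of
category k is the confidence-weighted vote of the query's interactive training
partners::

    score_k(q) = sum over training drugs d != q of Q(q, d) * y_{d,k}

where Q is the pairwise confidence score (0 for non-interactive pairs) and
y_{d,k} the binary indicator that d treats category k.  Candidates are then
arranged in decreasing score order to give the 1st-, 2nd-, ... order
predictions; equal scores (including the zero tail) are broken by catalogue
position so rankings are deterministic and full length.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np

from .types import (
    InteractionNetwork,
    LabelCatalog,
    LabelledDrugSet,
    RankedPrediction,
    ScoreVector,
)

logger = logging.getLogger(__name__)

__all__ = ["score_categories", "rank_categories", "predict"]


def score_categories(
    query_id: str, train: LabelledDrugSet, net: InteractionNetwork
) -> ScoreVector:
    """Interaction-based per-category likelihood scores for one query drug.

    The query is excluded from the sum if it appears in ``train`` (jackknife
    self-exclusion); a spurious self-edge in the network is likewise ignored.
    A query with no interactive training partners scores zero everywhere —
    the probability it treats any category is zero under this model.
    """
    if len(train) == 0:
        raise ValueError("training set is empty")
    nbrs = net.neighbors(query_id)
    scores = np.zeros(len(train.catalog), dtype=float)
    if nbrs:
        w = np.fromiter(
            (nbrs.get(d, 0.0) if d != query_id else 0.0 for d in train.drug_ids),
            dtype=float,
            count=len(train),
        )
        scores = w @ train.labels
    return ScoreVector(query_id, scores, train.catalog)


def rank_categories(
    scores: ScoreVector, catalog: LabelCatalog | None = None, truncate_zero: bool = False
) -> RankedPrediction:
    """Arrange all categories by decreasing score into a :class:`RankedPrediction`.

    Ties (equal scores) are broken by ascending catalogue position and recorded
    as tie groups.  By default the ranking is full length — zero-score
    categories form the tail — matching an evaluation that inspects all M
    orders; ``truncate_zero`` drops the zero tail instead.
    """
    if catalog is None:
        catalog = scores.catalog
    elif catalog != scores.catalog:
        raise ValueError("scores are not aligned to the given catalog")
    s = scores.scores
    order = sorted(range(len(catalog)), key=lambda k: (-s[k], k))
    ranked_scores = tuple(float(s[k]) for k in order)
    groups: list[tuple[int, ...]] = []
    start = 0
    for pos in range(1, len(order) + 1):
        if pos == len(order) or ranked_scores[pos] != ranked_scores[start]:
            groups.append(tuple(range(start, pos)))
            start = pos
    pred = RankedPrediction(
        query_id=scores.query_id,
        categories=tuple(catalog[k] for k in order),
        scores=ranked_scores,
        tie_groups=tuple(groups),
    )
    return pred.truncate_zero() if truncate_zero else pred


def predict(
    query_ids: Sequence[str] | Iterable[str],
    train: LabelledDrugSet,
    net: InteractionNetwork,
    truncate_zero: bool = False,
) -> list[RankedPrediction]:
    """Rank indications for each query drug, in input order."""
    return [
        rank_categories(score_categories(q, train, net), truncate_zero=truncate_zero)
        for q in query_ids
    ]
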