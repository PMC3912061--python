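"""Jackknife harness and ordered-prediction evaluation statistics.

The evaluation treats each prediction as a full descending ranking of the M
categories.  Headline statistics:

* **j-th order accuracy** Q_j — fraction of drugs whose j-th ranked category
  is one of their true indications; Q_1 is the headline number.
* **per-category order accuracy** A[i, k] — among drugs that truly treat
  category k, the fraction whose i-th ranked category equals k (undefined,
  not zero, when no drug treats k).
* **coverage ratio** r(m) — fraction of all true drug-indication pairs that
  fall inside each drug's first m predictions; m defaults to the ceiling of
  the dataset's average number of indications per drug.
* **precision / recall** over per-drug predicted label sets, averaged per
  drug; with singleton first-order sets precision coincides with Q_1.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .descriptor import score_categories_descriptor
from .interaction import rank_categories, score_categories
from .types import (
    DescriptorMatrix,
    InteractionNetwork,
    LabelledDrugSet,
    RankedPrediction,
)

logger = logging.getLogger(__name__)

__all__ = [
    "jackknife",
    "order_accuracy",
    "per_category_order_accuracy",
    "per_category_matrix",
    "coverage_ratio",
    "choose_m",
    "precision_recall",
    "uniform_guess_rate",
    "evaluate",
    "EvaluationReport",
]


def jackknife(
    data: LabelledDrugSet,
    evidence: InteractionNetwork | DescriptorMatrix,
    truncate_zero: bool = False,
) -> list[RankedPrediction]:
    """Leave-one-out predictions: each drug is ranked by a model trained on the rest.

    The scorer is chosen by evidence type (interaction network or descriptor
    matrix).  Self-exclusion inside the scorers makes the left-out drug's own
    labels invisible to its prediction, so the procedure is deterministic and
    needs no data copying.
    """
    if len(data) < 2:
        raise ValueError("jackknife needs at least two drugs")
    if isinstance(evidence, InteractionNetwork):
        scorer = lambda q: score_categories(q, data, evidence)
    elif isinstance(evidence, DescriptorMatrix):
        scorer = lambda q: score_categories_descriptor(q, data, evidence)
    else:
        raise TypeError(f"unsupported evidence type {type(evidence).__name__}")
    return [
        rank_categories(scorer(q), truncate_zero=truncate_zero) for q in data.drug_ids
    ]


def _check_alignment(
    preds: Sequence[RankedPrediction], truth: LabelledDrugSet
) -> None:
    if len(preds) != len(truth):
        raise ValueError(
            f"{len(preds)} predictions for {len(truth)} drugs; one per drug required"
        )
    for p in preds:
        if p.query_id not in truth:
            raise ValueError(f"prediction for unknown drug {p.query_id!r}")


def order_accuracy(
    preds: Sequence[RankedPrediction], truth: LabelledDrugSet, j: int
) -> float:
    """Q_j: fraction of drugs whose j-th order prediction is a true indication.

    Predictions shorter than j (possible with zero-truncated rankings) cannot
    score a hit at order j.
    """
    M = len(truth.catalog)
    if not 1 <= j <= M:
        raise ValueError(f"order j={j} out of range 1..{M}")
    _check_alignment(preds, truth)
    hits = sum(
        1
        for p in preds
        if len(p) >= j and p.categories[j - 1] in truth.label_set(p.query_id)
    )
    return hits / len(preds)


def per_category_order_accuracy(
    preds: Sequence[RankedPrediction],
    truth: LabelledDrugSet,
    i: int,
    category: str,
) -> float | None:
    """Among drugs truly treating ``category``, the fraction ranking it i-th.

    Returns ``None`` (undefined, distinct from 0) when no drug in the dataset
    treats the category.
    """
    M = len(truth.catalog)
    if not 1 <= i <= M:
        raise ValueError(f"order i={i} out of range 1..{M}")
    k = truth.catalog.index(category)
    _check_alignment(preds, truth)
    carriers = [p for p in preds if truth.label_vector(p.query_id)[k] == 1]
    if not carriers:
        return None
    hits = sum(
        1 for p in carriers if len(p) >= i and p.categories[i - 1] == category
    )
    return hits / len(carriers)


def per_category_matrix(
    preds: Sequence[RankedPrediction], truth: LabelledDrugSet
) -> np.ndarray:
    """M x M matrix A[i-1, k] of i-th order accuracy on category k (NaN if undefined)."""
    M = len(truth.catalog)
    out = np.full((M, M), np.nan)
    for k, cat in enumerate(truth.catalog):
        for i in range(1, M + 1):
            a = per_category_order_accuracy(preds, truth, i, cat)
            if a is not None:
                out[i - 1, k] = a
    return out


def coverage_ratio(
    preds: Sequence[RankedPrediction], truth: LabelledDrugSet, m: int
) -> float:
    """r(m): share of all true drug-indication pairs found in the first m predictions.

    r(m) = sum_i |top-m(i) ∩ true(i)| / sum_i n_i; with full-length rankings
    r(M) = 1 since every true label appears somewhere in the ranking.
    """
    M = len(truth.catalog)
    if not 1 <= m <= M:
        raise ValueError(f"m={m} out of range 1..{M}")
    _check_alignment(preds, truth)
    covered = sum(
        len(p.predicted_set(m) & truth.label_set(p.query_id)) for p in preds
    )
    return covered / truth.n_label_pairs


def choose_m(truth: LabelledDrugSet) -> int:
    """Smallest integer no less than the dataset's average indications per drug."""
    if len(truth) == 0:
        raise ValueError("empty drug set")
    return math.ceil(truth.avg_labels)


def precision_recall(
    pred_sets: Mapping[str, frozenset[str] | set[str]], truth: LabelledDrugSet
) -> tuple[float, float]:
    """Per-drug-averaged precision and recall of predicted label sets.

    precision = (1/N) sum_i c_i / p_i and recall = (1/N) sum_i c_i / n_i where
    c_i = |predicted_i ∩ true_i|.  A drug with an empty predicted set
    contributes 0 to precision (logged).  Every drug in ``truth`` must have an
    entry in ``pred_sets``.
    """
    if len(truth) == 0:
        raise ValueError("empty drug set")
    prec = rec = 0.0
    for d in truth.drug_ids:
        true = truth.label_set(d)
        try:
            pred = frozenset(pred_sets[d])
        except KeyError:
            raise ValueError(f"no predicted set for drug {d!r}") from None
        c = len(pred & true)
        if pred:
            prec += c / len(pred)
        else:
            logger.warning("drug %r has an empty predicted set; precision term 0", d)
        rec += c / len(true)
    n = len(truth)
    return prec / n, rec / n


def uniform_guess_rate(
    truth: LabelledDrugSet, rounded_intermediate: bool = False
) -> float:
    """Expected success rate of a uniform single-category random guess.

    Equals (average indications per drug) / M.  With ``rounded_intermediate``
    the average is first rounded to two decimals, matching the arithmetic
    convention sometimes used when such rates are quoted from a table.
    """
    avg = truth.avg_labels
    if rounded_intermediate:
        avg = round(avg, 2)
    return avg / len(truth.catalog)


@dataclass
class EvaluationReport:
    """Aggregated evaluation of a set of ranked predictions against truth."""

    order_accuracy: np.ndarray  # Q_1..Q_M
    per_category: np.ndarray  # M x M, NaN where undefined
    coverage_m: int
    coverage: float
    avg_labels: float
    n_drugs: int
    n_label_pairs: int
    precision: float  # singleton first-order predicted sets
    recall: float
    categories: tuple[str, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        pc = [
            [None if np.isnan(v) else float(v) for v in row] for row in self.per_category
        ]
        return {
            "order_accuracy": [float(q) for q in self.order_accuracy],
            "per_category": pc,
            "categories": list(self.categories),
            "coverage_m": self.coverage_m,
            "coverage": float(self.coverage),
            "avg_labels": float(self.avg_labels),
            "n_drugs": self.n_drugs,
            "n_label_pairs": self.n_label_pairs,
            "precision": float(self.precision),
            "recall": float(self.recall),
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def to_tsv(self) -> str:
        """Human-readable report with 2-decimal percentages."""
        lines = [f"n_drugs\t{self.n_drugs}", f"n_label_pairs\t{self.n_label_pairs}"]
        lines.append(f"avg_labels\t{self.avg_labels:.2f}")
        for j, q in enumerate(self.order_accuracy, start=1):
            lines.append(f"order_{j}_accuracy\t{100 * q:.2f}%")
        lines.append(f"coverage_m\t{self.coverage_m}")
        lines.append(f"coverage\t{100 * self.coverage:.2f}%")
        lines.append(f"precision_top1\t{100 * self.precision:.2f}%")
        lines.append(f"recall_top1\t{100 * self.recall:.2f}%")
        header = "per_category_order_accuracy\t" + "\t".join(self.categories)
        lines.append(header)
        for i, row in enumerate(self.per_category, start=1):
            cells = ["NA" if np.isnan(v) else f"{100 * v:.2f}%" for v in row]
            lines.append(f"order_{i}\t" + "\t".join(cells))
        return "\n".join(lines) + "\n"


def evaluate(
    preds: Sequence[RankedPrediction],
    truth: LabelledDrugSet,
    m: int | None = None,
) -> EvaluationReport:
    """Compute the full report; ``m`` defaults to :func:`choose_m` on ``truth``."""
    _check_alignment(preds, truth)
    M = len(truth.catalog)
    m_used = choose_m(truth) if m is None else m
    top1_sets = {p.query_id: p.predicted_set(1) for p in preds}
    precision, recall = precision_recall(top1_sets, truth)
    return EvaluationReport(
        order_accuracy=np.array(
            [order_accuracy(preds, truth, j) for j in range(1, M + 1)]
        ),
        per_category=per_category_matrix(preds, truth),
        coverage_m=m_used,
        coverage=coverage_ratio(preds, truth, m_used),
        avg_labels=truth.avg_labels,
        n_drugs=len(truth),
        n_label_pairs=truth.n_label_pairs,
        precision=precision,
        recall=recall,
        categories=truth.catalog.categories,
    )
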