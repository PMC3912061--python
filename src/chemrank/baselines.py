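"""Null controls for the interaction-based ranking model.

Three baselines probe different parts of the signal:

* :func:`random_label_guess` — a uniform single-category guess per drug; its
  expected hit rate is (average indications per drug) / M, the floor any
  informative first-order prediction must beat.
* :func:`random_guess` — label transfer from one uniformly drawn *other*
  training drug (jackknife style); evaluated with set precision/recall since
  the copied set carries no order.
* :func:`permute_confidences` — keeps the interaction graph but reassigns the
  confidence scores to edges by a uniform random permutation, destroying the
  alignment between score magnitude and shared indications while conserving
  the degree structure and the score multiset.
"""

from __future__ import annotations

import numpy as np

from .types import InteractionNetwork, LabelCatalog, LabelledDrugSet

__all__ = ["random_guess", "random_label_guess", "permute_confidences"]


def random_guess(
    data: LabelledDrugSet, seed: int | np.random.Generator
) -> dict[str, frozenset[str]]:
    """For each drug, copy the true label set of one uniformly drawn other drug."""
    if len(data) < 2:
        raise ValueError("random label transfer needs at least two drugs")
    rng = np.random.default_rng(seed)
    out: dict[str, frozenset[str]] = {}
    n = len(data)
    for i, d in enumerate(data.drug_ids):
        j = int(rng.integers(n - 1))
        if j >= i:  # uniform over the n-1 others
            j += 1
        out[d] = data.label_set(data.drug_ids[j])
    return out


def random_label_guess(
    data: LabelledDrugSet,
    catalog: LabelCatalog | None = None,
    seed: int | np.random.Generator = 0,
) -> dict[str, str]:
    """Assign one uniformly drawn category to each drug."""
    catalog = catalog or data.catalog
    rng = np.random.default_rng(seed)
    draws = rng.integers(len(catalog), size=len(data))
    return {d: catalog[int(k)] for d, k in zip(data.drug_ids, draws)}


def permute_confidences(
    net: InteractionNetwork, seed: int | np.random.Generator, fraction: float = 1.0
) -> InteractionNetwork:
    """Reassign confidence scores to edges by a uniform random permutation.

    The edge set (the unordered pairs) and the multiset of scores are both
    conserved exactly; only the pairing between them is randomised.
    ``fraction`` < 1 permutes the scores of a uniformly chosen subset of edges
    of that relative size, leaving the rest in place.
    """
    if net.n_edges == 0:
        raise ValueError("cannot permute an empty network")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    edges = sorted(net.edges())
    pairs = [(a, b) for a, b, _ in edges]
    scores = np.array([q for _, _, q in edges])
    idx = np.arange(len(edges))
    if fraction < 1.0:
        k = max(2, round(fraction * len(edges)))
        idx = rng.choice(len(edges), size=min(k, len(edges)), replace=False)
    perm = rng.permutation(idx)
    scores[idx] = scores[perm]
    return InteractionNetwork(
        {pair: float(q) for pair, q in zip(pairs, scores)}
    )
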