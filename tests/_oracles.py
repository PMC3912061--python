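"""Independent brute-force oracles used to cross-check the library.

Everything here is written as plain double loops over dicts and lists, with
no shared code with the package internals, so agreement is meaningful.
"""

from __future__ import annotations

import math


def brute_scores(
    query: str,
    drug_labels: dict[str, set[str]],
    edges: dict[frozenset, float],
    categories: list[str],
) -> dict[str, float]:
    """Direct double-loop evaluation of the interaction vote sum."""
    out = {c: 0.0 for c in categories}
    for d, labs in drug_labels.items():
        if d == query:
            continue
        q = edges.get(frozenset((query, d)), 0.0)
        for c in labs:
            out[c] += q
    return out


def brute_descriptor_scores(
    query: str,
    drug_labels: dict[str, set[str]],
    vectors: dict[str, list[float]],
    categories: list[str],
) -> dict[str, float]:
    """Direct evaluation of the cosine vote sum."""
    out = {c: 0.0 for c in categories}
    vq = vectors[query]
    nq = math.sqrt(sum(x * x for x in vq))
    for d, labs in drug_labels.items():
        if d == query:
            continue
        vd = vectors[d]
        nd = math.sqrt(sum(x * x for x in vd))
        if nq == 0 or nd == 0:
            cos = 0.0
        else:
            cos = sum(a * b for a, b in zip(vq, vd)) / (nq * nd)
        for c in labs:
            out[c] += cos
    return out


def brute_rank(scores: dict[str, float], categories: list[str]) -> list[str]:
    """Stable sort by (-score, catalog position)."""
    pos = {c: i for i, c in enumerate(categories)}
    return sorted(categories, key=lambda c: (-scores[c], pos[c]))


def brute_order_accuracy(
    rankings: dict[str, list[str]], truth: dict[str, set[str]], j: int
) -> float:
    hits = 0
    for d, order in rankings.items():
        if len(order) >= j and order[j - 1] in truth[d]:
            hits += 1
    return hits / len(rankings)


def brute_per_category(
    rankings: dict[str, list[str]], truth: dict[str, set[str]], i: int, cat: str
):
    carriers = [d for d in rankings if cat in truth[d]]
    if not carriers:
        return None
    hits = sum(
        1 for d in carriers if len(rankings[d]) >= i and rankings[d][i - 1] == cat
    )
    return hits / len(carriers)


def brute_coverage(
    rankings: dict[str, list[str]], truth: dict[str, set[str]], m: int
) -> float:
    covered = 0
    total = 0
    for d, order in rankings.items():
        covered += len(set(order[:m]) & truth[d])
        total += len(truth[d])
    return covered / total


def brute_precision_recall(
    pred_sets: dict[str, set[str]], truth: dict[str, set[str]]
) -> tuple[float, float]:
    prec = rec = 0.0
    for d, true in truth.items():
        pred = pred_sets[d]
        c = len(pred & true)
        if pred:
            prec += c / len(pred)
        rec += c / len(true)
    return prec / len(truth), rec / len(truth)


def random_instance(rng, max_drugs: int = 10, max_cats: int = 4):
    """Random tiny instance: (categories, drug_labels, edges)."""
    m = int(rng.integers(2, max_cats + 1))
    n = int(rng.integers(2, max_drugs + 1))
    categories = [f"C{k + 1}" for k in range(m)]
    drug_labels = {}
    for i in range(n):
        n_labs = 1 + int(rng.random() < 0.35)
        labs = rng.choice(m, size=min(n_labs, m), replace=False)
        drug_labels[f"d{i + 1}"] = {categories[k] for k in labs}
    ids = list(drug_labels)
    edges = {}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.5:
                edges[frozenset((ids[i], ids[j]))] = float(rng.integers(1, 1000))
    return categories, drug_labels, edges
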