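"""Synthetic fixture generator with label-homophilous network structure.

The generator emulates the statistical situation the interaction method
relies on: drugs carry one or two indication labels, interactive pairs are
enriched among drugs sharing a label (edge probability ``p_within`` vs
``p_between``), edge confidence scores follow a database-like integer scale,
and descriptor vectors of same-category drugs point in correlated directions.

Defaults mirror a small oncology benchmark: 68 drugs over 8 cancer
categories with category weights (9, 13, 30, 19, 10, 14, 7, 9)/111 and an
18/68 chance of a second label.  An exact-count mode deals labels without
replacement so that per-category column sums hit requested marginals exactly,
which is the mode used for table-shaped fixtures.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .io import write_descriptors, write_labels, write_stitch_tsv
from .types import DescriptorMatrix, InteractionNetwork, LabelCatalog, LabelledDrugSet

__all__ = ["SyntheticConfig", "SyntheticBundle", "generate", "write_fixture"]

_DEFAULT_WEIGHTS = tuple(c / 111 for c in (9, 13, 30, 19, 10, 14, 7, 9))


class SyntheticBundle(NamedTuple):
    labels: LabelledDrugSet
    network: InteractionNetwork
    descriptors: DescriptorMatrix
    config: "SyntheticConfig"


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic dataset.

    ``category_counts`` switches on exact-count mode: per-category column sums
    equal the given counts exactly and ``category_weights`` /
    ``multi_label_prob`` are ignored.  Scores are integers drawn uniformly on
    ``[score_low, score_high]`` (a 0-1000 confidence scale by default); when
    ``within_score_low``/``within_score_high`` are set, same-label pairs draw
    from that elevated range instead, putting homophily into the score
    magnitudes themselves (edge-presence homophily alone is invisible to a
    score permutation, so score-carried homophily is what the permutation
    null destroys).  ``descriptor_effect`` is the standard deviation of the per-category mean
    descriptor directions relative to unit per-drug noise, so the expected
    within-category cosine is roughly effect^2 / (1 + effect^2).
    """

    n_drugs: int = 68
    M: int = 8
    category_weights: tuple[float, ...] | None = None
    multi_label_prob: float = 18 / 68
    p_within: float = 0.35
    p_between: float = 0.15
    score_low: int = 150
    score_high: int = 999
    within_score_low: int | None = None
    within_score_high: int | None = None
    descriptor_dim: int = 355
    descriptor_effect: float = 1.0
    category_counts: tuple[int, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.n_drugs < 1:
            raise ValueError("n_drugs must be >= 1")
        for name in ("multi_label_prob", "p_within", "p_between"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.category_weights is not None:
            w = np.asarray(self.category_weights, float)
            if w.shape != (self.M,) or (w < 0).any() or not np.isclose(w.sum(), 1.0):
                raise ValueError("category_weights must be M non-negative values summing to 1")
        if self.category_counts is not None:
            c = self.category_counts
            if len(c) != self.M or any(k < 0 for k in c):
                raise ValueError("category_counts must be M non-negative integers")
            if sum(c) < self.n_drugs:
                raise ValueError("category_counts must total at least n_drugs")
            if any(k > self.n_drugs for k in c):
                raise ValueError("a category cannot exceed n_drugs drugs")
        if self.score_low < 1 or self.score_high < self.score_low:
            raise ValueError("need 1 <= score_low <= score_high")
        if (self.within_score_low is None) != (self.within_score_high is None):
            raise ValueError("set both or neither of within_score_low/high")
        if self.within_score_low is not None and not (
            1 <= self.within_score_low <= self.within_score_high
        ):
            raise ValueError("need 1 <= within_score_low <= within_score_high")
        if self.descriptor_dim < 1:
            raise ValueError("descriptor_dim must be >= 1")

    @property
    def weights(self) -> np.ndarray:
        if self.category_weights is not None:
            return np.asarray(self.category_weights, float)
        if self.M == 8:
            return np.asarray(_DEFAULT_WEIGHTS)
        return np.full(self.M, 1.0 / self.M)


def _sample_labels(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    y = np.zeros((cfg.n_drugs, cfg.M), np.int8)
    w = cfg.weights
    primary = rng.choice(cfg.M, size=cfg.n_drugs, p=w)
    y[np.arange(cfg.n_drugs), primary] = 1
    if cfg.M > 1:
        second_mask = rng.random(cfg.n_drugs) < cfg.multi_label_prob
        for i in np.flatnonzero(second_mask):
            w2 = w.copy()
            w2[primary[i]] = 0.0
            if w2.sum() == 0:
                continue
            y[i, rng.choice(cfg.M, p=w2 / w2.sum())] = 1
    return y


def _deal_exact_labels(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Deal category slots without replacement so column sums match exactly."""
    counts = list(cfg.category_counts)  # type: ignore[arg-type]
    for _ in range(1000):
        slots = np.repeat(np.arange(cfg.M), counts)
        rng.shuffle(slots)
        y = np.zeros((cfg.n_drugs, cfg.M), np.int8)
        y[np.arange(cfg.n_drugs), slots[: cfg.n_drugs]] = 1
        ok = True
        for k in slots[cfg.n_drugs :]:
            lacking = np.flatnonzero(y[:, k] == 0)
            if lacking.size == 0:
                ok = False
                break
            # spread extra labels: prefer drugs with the fewest labels so the
            # multi-label drug count stays minimal, as in curated benchmarks
            loads = y[lacking].sum(axis=1)
            cands = lacking[loads == loads.min()]
            y[rng.choice(cands), k] = 1
        if ok:
            return y
    raise RuntimeError("could not satisfy exact category counts; infeasible config?")


def generate(config: SyntheticConfig) -> SyntheticBundle:
    """Draw one reproducible (labels, network, descriptors) bundle.

    Labels, edges and descriptors use independent substreams of the config
    seed, so e.g. changing ``descriptor_dim`` does not perturb the network.
    """
    root = np.random.SeedSequence(config.seed)
    rng_labels, rng_edges, rng_desc = (
        np.random.default_rng(s) for s in root.spawn(3)
    )

    if config.category_counts is not None:
        y = _deal_exact_labels(config, rng_labels)
    else:
        y = _sample_labels(config, rng_labels)
    width = max(3, len(str(config.n_drugs)))
    ids = [f"D{i + 1:0{width}d}" for i in range(config.n_drugs)]
    catalog = LabelCatalog([f"C{k + 1}" for k in range(config.M)])
    labels = LabelledDrugSet(catalog, ids, y)

    share = (y @ y.T) > 0
    net = InteractionNetwork()
    n = config.n_drugs
    iu, ju = np.triu_indices(n, k=1)
    pair_within = share[iu, ju]
    p = np.where(pair_within, config.p_within, config.p_between)
    present = rng_edges.random(iu.size) < p
    scores = rng_edges.integers(config.score_low, config.score_high + 1, size=iu.size)
    if config.within_score_low is not None:
        # score-carried homophily: same-label pairs draw from an elevated range
        elevated = rng_edges.integers(
            config.within_score_low, config.within_score_high + 1, size=iu.size
        )
        scores = np.where(pair_within, elevated, scores)
    for a, b, q in zip(iu[present], ju[present], scores[present]):
        net.add_edge(ids[a], ids[b], float(q))

    mu = rng_desc.normal(0.0, config.descriptor_effect, (config.M, config.descriptor_dim))
    noise = rng_desc.normal(0.0, 1.0, (n, config.descriptor_dim))
    centers = (y @ mu) / y.sum(axis=1, keepdims=True)
    X = centers + noise
    frame = pd.DataFrame(
        X,
        index=pd.Index(ids, name="drug_id"),
        columns=[f"desc_{j + 1:03d}" for j in range(config.descriptor_dim)],
    )
    desc = DescriptorMatrix(frame)
    return SyntheticBundle(labels, net, desc, config)


def write_fixture(bundle: SyntheticBundle, directory: str | os.PathLike) -> dict[str, str]:
    """Write the bundle as the three standard files; returns the paths.

    Files are ``network.tsv`` (interaction dialect, score in the combined
    channel), ``labels.csv`` (long form) and ``descriptors.csv``; all three
    round-trip exactly through the package loaders, and the same config seed
    yields byte-identical files.
    """
    os.makedirs(directory, exist_ok=True)
    paths = {
        "network": os.path.join(directory, "network.tsv"),
        "labels": os.path.join(directory, "labels.csv"),
        "descriptors": os.path.join(directory, "descriptors.csv"),
    }
    write_stitch_tsv(bundle.network, paths["network"])
    write_labels(bundle.labels, paths["labels"], form="long")
    write_descriptors(bundle.descriptors, paths["descriptors"])
    return paths
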