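from __future__ import annotations

import numpy as np
import pytest

from chemrank import (
    InteractionNetwork,
    LabelCatalog,
    LabelledDrugSet,
)


@pytest.fixture
def catalog8() -> LabelCatalog:
    return LabelCatalog([f"C{i}" for i in range(1, 9)])


@pytest.fixture
def toy_train(catalog8) -> LabelledDrugSet:
    """Two training drugs: d1 treats C3; d2 treats C3 and C4."""
    return LabelledDrugSet.from_pairs(
        catalog8, [("d1", "C3"), ("d2", "C3"), ("d2", "C4")]
    )


@pytest.fixture
def toy_net() -> InteractionNetwork:
    return InteractionNetwork({("q", "d1"): 300.0, ("q", "d2"): 200.0})


def as_drugset(catalog, drug_labels: dict[str, set[str]]) -> LabelledDrugSet:
    pairs = [(d, c) for d, labs in drug_labels.items() for c in sorted(labs)]
    return LabelledDrugSet.from_pairs(catalog, pairs)


def as_network(edges: dict[frozenset, float]) -> InteractionNetwork:
    return InteractionNetwork({tuple(sorted(pair)): q for pair, q in edges.items()})


@pytest.fixture
def stitch_file(tmp_path):
    """3-row interaction fixture with combined scores {150, 0, 700}."""
    path = tmp_path / "links.tsv"
    path.write_text(
        "chemical1\tchemical2\tsimilarity\texperimental\tdatabase\ttextmining\tcombined_score\n"
        "a\tb\t0\t0\t0\t0\t150\n"
        "a\tc\t0\t0\t0\t0\t0\n"
        "b\tc\t0\t0\t0\t300\t700\n"
    )
    return path
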