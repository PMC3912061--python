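import json

import numpy as np
import pytest

from chemrank import (
    InteractionNetwork,
    LabelCatalog,
    choose_m,
    coverage_ratio,
    evaluate,
    jackknife,
    order_accuracy,
    per_category_matrix,
    per_category_order_accuracy,
    precision_recall,
    predict,
    rank_categories,
    score_categories,
    uniform_guess_rate,
)
from _oracles import (
    brute_coverage,
    brute_order_accuracy,
    brute_per_category,
    brute_precision_recall,
    brute_rank,
    brute_scores,
    random_instance,
)
from conftest import as_drugset, as_network


class TestJackknife:
    def test_two_drug_case_uses_only_the_other_drug(self, catalog8):
        data = as_drugset(catalog8, {"a": {"C1"}, "b": {"C5"}})
        net = InteractionNetwork({("a", "b"): 700.0})
        preds = jackknife(data, net)
        assert preds[0].categories[0] == "C5"  # a sees only b's labels
        assert preds[1].categories[0] == "C1"

    def test_isolated_drug_gets_all_tied_catalog_order(self, catalog8):
        data = as_drugset(catalog8, {"a": {"C1"}, "b": {"C5"}, "x": {"C2"}})
        net = InteractionNetwork({("a", "b"): 700.0})
        pred_x = next(p for p in jackknife(data, net) if p.query_id == "x")
        assert pred_x.categories == catalog8.categories
        assert pred_x.tie_groups == (tuple(range(8)),)

    def test_matches_manual_leave_one_out_enumeration(self):
        rng = np.random.default_rng(42)
        cats, labels, edges = random_instance(rng, max_drugs=5)
        catalog = LabelCatalog(cats)
        data = as_drugset(catalog, labels)
        net = as_network(edges)
        preds = {p.query_id: p for p in jackknife(data, net)}
        for held_out in labels:
            rest = {d: l for d, l in labels.items() if d != held_out}
            expected = brute_scores(held_out, rest, edges, cats)
            assert list(preds[held_out].categories) == brute_rank(expected, cats)

    def test_singleton_dataset_is_an_error(self, catalog8):
        data = as_drugset(catalog8, {"a": {"C1"}})
        with pytest.raises(ValueError, match="two"):
            jackknife(data, InteractionNetwork({("a", "b"): 1.0}))


def rankings_of(preds):
    return {p.query_id: list(p.categories) for p in preds}


@pytest.fixture
def hand_instance(catalog8):
    """4 drugs with deterministic rankings driven by an explicit network."""
    labels = {
        "a": {"C3"},
        "b": {"C3", "C4"},
        "c": {"C1"},
        "d": {"C2", "C5"},
    }
    data = as_drugset(catalog8, labels)
    net = InteractionNetwork(
        {
            ("a", "b"): 800.0,
            ("a", "c"): 100.0,
            ("b", "c"): 300.0,
            ("c", "d"): 500.0,
            ("b", "d"): 200.0,
        }
    )
    return data, net, labels


class TestOrderAccuracy:
    def test_perfect_first_order(self, catalog8):
        net = InteractionNetwork({("a", "b"): 5.0})
        data = as_drugset(catalog8, {"a": {"C2"}, "b": {"C2"}})
        preds = jackknife(data, net)
        assert order_accuracy(preds, data, 1) == 1.0

    def test_hit_counts_at_each_order(self, hand_instance, catalog8):
        data, net, labels = hand_instance
        preds = jackknife(data, net)
        ranks = rankings_of(preds)
        for j in range(1, 9):
            assert order_accuracy(preds, data, j) == pytest.approx(
                brute_order_accuracy(ranks, labels, j)
            )

    def test_out_of_range_order_rejected(self, hand_instance):
        data, net, _ = hand_instance
        preds = jackknife(data, net)
        for j in (0, 9):
            with pytest.raises(ValueError):
                order_accuracy(preds, data, j)


class TestPerCategory:
    def test_matrix_matches_exhaustive_count(self, hand_instance, catalog8):
        data, net, labels = hand_instance
        preds = jackknife(data, net)
        ranks = rankings_of(preds)
        mat = per_category_matrix(preds, data)
        for k, cat in enumerate(catalog8):
            for i in range(1, 9):
                expected = brute_per_category(ranks, labels, i, cat)
                if expected is None:
                    assert np.isnan(mat[i - 1, k])
                else:
                    assert mat[i - 1, k] == pytest.approx(expected)

    def test_empty_category_is_undefined_not_zero(self, hand_instance):
        data, net, _ = hand_instance
        preds = jackknife(data, net)
        assert per_category_order_accuracy(preds, data, 1, "C8") is None

    def test_orders_sum_to_one_for_carried_categories(self, hand_instance):
        data, net, _ = hand_instance
        preds = jackknife(data, net)
        mat = per_category_matrix(preds, data)
        carried = ~np.isnan(mat[0])
        assert np.allclose(mat[:, carried].sum(axis=0), 1.0)


class TestCoverage:
    def test_full_length_rankings_cover_everything_at_m_equals_M(self, hand_instance):
        data, net, _ = hand_instance
        preds = jackknife(data, net)
        assert coverage_ratio(preds, data, 8) == 1.0

    def test_single_drug_half_covered(self, catalog8):
        data = as_drugset(catalog8, {"a": {"C3", "C7"}, "b": {"C3"}})
        net = InteractionNetwork({("a", "b"): 10.0})
        preds = jackknife(data, net)
        # a's top-2 = (C3, C1): one of its two true labels covered
        p_a = next(p for p in preds if p.query_id == "a")
        assert p_a.predicted_set(2) == {"C3", "C1"}
        assert sum(
            len(p.predicted_set(2) & data.label_set(p.query_id)) for p in [p_a]
        ) == 1

    def test_matches_count_oracle_and_monotone_in_m(self, hand_instance):
        data, net, labels = hand_instance
        preds = jackknife(data, net)
        ranks = rankings_of(preds)
        prev = 0.0
        for m in range(1, 9):
            r = coverage_ratio(preds, data, m)
            assert r == pytest.approx(brute_coverage(ranks, labels, m))
            assert r >= prev
            prev = r


class TestChooseM:
    @pytest.mark.parametrize(
        "counts,n_drugs,expected_avg,expected_m",
        [
            ((8, 8, 24, 13, 4, 9, 5, 6), 59, 77 / 59, 2),
            ((1, 5, 6, 6, 6, 5, 2, 3), 9, 34 / 9, 4),
            ((1, 6, 21, 11, 2, 9, 1, 7), 44, 58 / 44, 2),
        ],
    )
    def test_ceiling_of_average_on_benchmark_margins(
        self, catalog8, counts, n_drugs, expected_avg, expected_m
    ):
        from chemrank import SyntheticConfig, generate

        ds = generate(
            SyntheticConfig(n_drugs=n_drugs, M=8, category_counts=counts, seed=1)
        ).labels
        assert ds.avg_labels == pytest.approx(expected_avg)
        assert choose_m(ds) == expected_m

    def test_all_single_label_gives_one(self, catalog8):
        ds = as_drugset(catalog8, {"a": {"C1"}, "b": {"C2"}})
        assert choose_m(ds) == 1


class TestPrecisionRecall:
    def test_perfect_sets(self, catalog8):
        ds = as_drugset(catalog8, {"a": {"C1", "C2"}, "b": {"C3"}})
        p, r = precision_recall(ds.label_sets(), ds)
        assert p == r == 1.0

    def test_singleton_first_order_precision_equals_q1(self, hand_instance):
        data, net, _ = hand_instance
        preds = jackknife(data, net)
        sets = {p.query_id: p.predicted_set(1) for p in preds}
        p, _ = precision_recall(sets, data)
        assert p == order_accuracy(preds, data, 1)

    def test_mixed_label_counts_match_direct_formula(self, catalog8):
        labels = {"a": {"C1"}, "b": {"C2", "C3"}, "c": {"C4"}}
        ds = as_drugset(catalog8, labels)
        sets = {"a": {"C1", "C5"}, "b": {"C2"}, "c": {"C7"}}
        p, r = precision_recall(sets, ds)
        ep, er = brute_precision_recall(sets, labels)
        assert (p, r) == (pytest.approx(ep), pytest.approx(er))
        assert p == pytest.approx((0.5 + 1.0 + 0.0) / 3)
        assert r == pytest.approx((1.0 + 0.5 + 0.0) / 3)

    def test_empty_predicted_set_contributes_zero_precision(self, catalog8, caplog):
        ds = as_drugset(catalog8, {"a": {"C1"}, "b": {"C2"}})
        with caplog.at_level("WARNING"):
            p, r = precision_recall({"a": set(), "b": {"C2"}}, ds)
        assert p == 0.5 and r == 0.5


class TestUniformGuessRate:
    def test_full_precision_and_rounded_intermediate(self, catalog8):
        from chemrank import SyntheticConfig, generate

        tr = generate(
            SyntheticConfig(
                n_drugs=59, M=8, category_counts=(8, 8, 24, 13, 4, 9, 5, 6), seed=2
            )
        ).labels
        assert uniform_guess_rate(tr) == pytest.approx(77 / 59 / 8)
        assert uniform_guess_rate(tr, rounded_intermediate=True) == pytest.approx(
            1.31 / 8
        )


class TestEvaluateReport:
    def test_aggregates_all_fields_consistently(self, hand_instance):
        data, net, _ = hand_instance
        preds = jackknife(data, net)
        rep = evaluate(preds, data)
        assert rep.n_drugs == 4 and rep.n_label_pairs == 6
        assert rep.coverage_m == choose_m(data) == 2
        assert rep.coverage == coverage_ratio(preds, data, 2)
        assert rep.precision == rep.order_accuracy[0]
        assert ((rep.order_accuracy >= 0) & (rep.order_accuracy <= 1)).all()
        # label-placement conservation: summed order hits = all label pairs
        hits = rep.order_accuracy.sum() * rep.n_drugs
        assert hits == pytest.approx(rep.n_label_pairs)

    def test_report_serialises_to_json_and_tsv(self, hand_instance):
        data, net, _ = hand_instance
        rep = evaluate(jackknife(data, net), data)
        d = json.loads(rep.to_json())
        assert len(d["order_accuracy"]) == 8
        text = rep.to_tsv()
        assert "order_1_accuracy" in text and "%" in text

    def test_validation_protocol_scores_queries_against_full_training_set(
        self, catalog8
    ):
        """Held-out queries are scored against all training drugs (no leave-one-out)."""
        train = as_drugset(catalog8, {"a": {"C2"}, "b": {"C2"}, "c": {"C6"}})
        test = as_drugset(catalog8, {"t": {"C2"}})
        net = InteractionNetwork({("t", "a"): 100.0, ("t", "c"): 90.0})
        preds = predict(test.drug_ids, train, net)
        rep = evaluate(preds, test, m=1)
        assert rep.order_accuracy[0] == 1.0
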