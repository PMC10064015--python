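"""Association-rule mining, rare-occurrence filter, outstrength network."""

import itertools

import numpy as np
import pandas as pd
import pytest

from boutonsort.association import (
    TransactionSet,
    build_network,
    build_transactions,
    lift_matrix,
    mine_rules,
)
from boutonsort.errors import ConfigurationError, DataIntegrityError
from boutonsort.synthetic import SegmentGenConfig, generate_segment_dataset


def tx_from_sets(sets, alphabet=("A", "B", "C")):
    return TransactionSet(
        itemsets=tuple(frozenset(s) for s in sets),
        segment_ids=tuple(range(len(sets))),
        alphabet=tuple(alphabet),
    )


def brute_force_rules(sets, alphabet):
    """Independent enumeration oracle for pairwise support/confidence/lift."""
    n = len(sets)
    rows = {}
    for a, b in itertools.permutations(alphabet, 2):
        ca = sum(1 for s in sets if a in s)
        cb = sum(1 for s in sets if b in s)
        cab = sum(1 for s in sets if a in s and b in s)
        if ca == 0:
            continue
        conf = cab / ca
        lift = (cab / n) / ((ca / n) * (cb / n)) if cb else np.nan
        rows[(a, b)] = (ca / n, cb / n, cab / n, conf, lift)
    return rows


class TestMineRules:
    def test_hand_enumerated_example(self):
        tx = tx_from_sets([{"A", "B"}, {"A", "B"}, {"A"}, {"B"}], ("A", "B"))
        rules = mine_rules(tx).set_index(["antecedent", "consequent"])
        row = rules.loc[("A", "B")]
        assert row["confidence"] == pytest.approx(2 / 3)
        assert row["lift"] == pytest.approx(8 / 9)

    def test_saturated_items_have_unit_confidence_and_lift(self):
        tx = tx_from_sets([{"A", "B"}] * 5, ("A", "B"))
        rules = mine_rules(tx)
        assert (rules["confidence"] == 1.0).all()
        assert (rules["lift"] == 1.0).all()

    def test_never_co_occurring_items_have_zero_lift(self):
        tx = tx_from_sets([{"A"}, {"B"}, {"A"}, {"B"}], ("A", "B"))
        rules = mine_rules(tx).set_index(["antecedent", "consequent"])
        assert rules.loc[("A", "B"), "lift"] == 0.0

    def test_empty_transaction_set_rejected(self):
        with pytest.raises(ConfigurationError):
            mine_rules(tx_from_sets([]))

    def test_matches_brute_force_oracle_on_random_sets(self):
        """Exact agreement with full pair-count enumeration on random
        transaction sets."""
        rng = np.random.default_rng(0)
        alphabet = ("LM", "DM1", "DM2", "DM3", "DM4", "DM5")
        for _ in range(25):
            n = int(rng.integers(3, 60))
            sets = [
                {a for a in alphabet if rng.random() < 0.4} or {"LM"}
                for _ in range(n)
            ]
            rules = mine_rules(tx_from_sets(sets, alphabet))
            oracle = brute_force_rules(sets, alphabet)
            assert len(rules) == len(oracle)
            for _, r in rules.iterrows():
                exp = oracle[(r["antecedent"], r["consequent"])]
                assert (
                    r["support_a"],
                    r["support_b"],
                    r["support_ab"],
                    r["confidence"],
                ) == exp[:4]
                assert r["lift"] == pytest.approx(exp[4], nan_ok=True)

    def test_lift_symmetric_in_arguments(self):
        rng = np.random.default_rng(3)
        alphabet = ("A", "B", "C", "D")
        sets = [
            {a for a in alphabet if rng.random() < 0.5} or {"A"} for _ in range(40)
        ]
        rules = mine_rules(tx_from_sets(sets, alphabet)).set_index(
            ["antecedent", "consequent"]
        )
        for a, b in itertools.combinations(alphabet, 2):
            if (a, b) in rules.index and (b, a) in rules.index:
                assert rules.loc[(a, b), "lift"] == pytest.approx(
                    rules.loc[(b, a), "lift"]
                )

    def test_lift_matrix_pivots_if_then(self):
        tx = tx_from_sets([{"A", "B"}, {"A"}], ("A", "B"))
        m = lift_matrix(mine_rules(tx))
        assert m.loc["A", "B"] == pytest.approx(m.loc["B", "A"])


class TestBuildTransactions:
    def _boutons(self, per_segment):
        rows = []
        for seg, labels in per_segment.items():
            rows += [(seg, l) for l in labels]
        return pd.DataFrame(rows, columns=["segment_id", "subpop"])

    def test_presence_coding_groups_lm(self):
        df = self._boutons({0: ["LM1", "LM3", "LM1", "DM1", "DM1"]})
        tx = build_transactions(df)
        assert tx.itemsets[0] == frozenset({"LM", "DM1"})

    def test_rare_type_dropped_on_large_segments(self):
        df = self._boutons({0: ["LM1"] * 49 + ["DM5"]})  # 1/50 = 2% < 2.5%
        tx = build_transactions(df)
        assert tx.itemsets[0] == frozenset({"LM"})

    def test_rare_type_kept_on_small_segments(self):
        df = self._boutons({0: ["LM1", "LM2", "DM1", "DM2", "DM5"]})
        tx = build_transactions(df)
        assert "DM5" in tx.itemsets[0]

    def test_unlabeled_bouton_rejected(self):
        df = pd.DataFrame({"segment_id": [0], "subpop": [None]})
        with pytest.raises(DataIntegrityError):
            build_transactions(df)

    def test_missing_segment_id_rejected(self):
        df = pd.DataFrame({"segment_id": [pd.NA], "subpop": ["LM1"]})
        with pytest.raises(DataIntegrityError):
            build_transactions(df)


class TestNetwork:
    def test_outstrength_sums_retained_confidences(self):
        rules = pd.DataFrame(
            {
                "antecedent": ["A", "A", "B"],
                "consequent": ["B", "C", "A"],
                "support_a": [0.5, 0.5, 0.4],
                "support_b": [0.4, 0.3, 0.5],
                "support_ab": [0.3, 0.2, 0.3],
                "confidence": [0.5, 0.3, 0.75],
                "lift": [1.0, 1.0, 1.0],
            }
        )
        net = build_network(rules, min_support=0.0)
        assert net.outstrength["A"] == pytest.approx(0.8)
        assert net.outstrength["B"] == pytest.approx(0.75)
        assert net.outstrength["C"] == 0.0

    def test_all_rules_filtered_gives_empty_edges(self):
        rules = pd.DataFrame(
            {
                "antecedent": ["A"],
                "consequent": ["B"],
                "support_a": [0.5],
                "support_b": [0.5],
                "support_ab": [0.05],
                "confidence": [0.1],
                "lift": [0.4],
            }
        )
        net = build_network(rules, min_support=0.1)
        assert net.graph.number_of_edges() == 0
        assert all(v == 0.0 for v in net.outstrength.values())

    def test_segregated_x_like_data_lacks_lm_dm1_edge(self):
        """With full segregation the LM -> DM1 co-support is zero, so the
        network omits the edge in both directions."""
        cfg = SegmentGenConfig(n_segments={"X_like": 150}, epsilon=1.0, seed=2)
        _, boutons = generate_segment_dataset(cfg)
        boutons = boutons.rename(columns={"true_component": "subpop"})
        rules = mine_rules(build_transactions(boutons))
        net = build_network(rules, min_support=0.0, min_confidence=0.0)
        assert not net.graph.has_edge("LM", "DM1")
        assert not net.graph.has_edge("DM1", "LM")
        lm_dm1 = rules.query("antecedent == 'LM' and consequent == 'DM1'")
        assert (lm_dm1["lift"] == 0.0).all()

    def test_independent_y_like_lift_near_unity(self):
        """Independent composition draws give lift(LM, DM1) in [0.8, 1.2]
        for >= 9/10 fixed seeds at 300 segments."""
        hits = 0
        for seed in range(10):
            cfg = SegmentGenConfig(
                n_segments={"Y_like": 300}, epsilon=0.0, seed=seed
            )
            _, boutons = generate_segment_dataset(cfg)
            boutons = boutons.rename(columns={"true_component": "subpop"})
            rules = mine_rules(build_transactions(boutons)).set_index(
                ["antecedent", "consequent"]
            )
            hits += 0.8 <= rules.loc[("LM", "DM1"), "lift"] <= 1.2
        assert hits >= 9
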