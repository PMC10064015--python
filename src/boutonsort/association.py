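"""Association-rule mining on per-segment terminal co-occurrence.

Each dendrite segment is a transaction; the terminal types synapsing on it
are the items (retinal subpopulations LM1-4 grouped into a single LM item by
default, alongside DM1-5).  For every ordered item pair the support,
confidence and lift are computed by exact counting over the transactions:

    support(A)    = fraction of segments carrying A
    confidence(A->B) = support(A and B) / support(A)
    lift(A, B)    = support(A and B) / (support(A) * support(B))

A lift of 1 means chance-level co-occurrence, above 1 positive association,
below 1 avoidance; lift is symmetric in its arguments.  A confidence-
weighted directed graph over the item alphabet summarizes the rules, with
each node's outstrength (sum of outgoing edge weights) measuring how
strongly the presence of that terminal type predicts the others.

Rare-occurrence filter: on segments receiving many terminals
(>= ``min_terminals``, default 40) a type whose share of the segment's
terminals falls below ``filter_threshold`` (default 0.025) is dropped from
that segment's itemset, excluding rare occurrences on heavily innervated
segments while leaving sparsely innervated segments untouched.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataIntegrityError

#: Default grouping: all retinal subpopulations become one LM item.
DEFAULT_GROUPING = {
    "LM1": "LM",
    "LM2": "LM",
    "LM3": "LM",
    "LM4": "LM",
    "DM1": "DM1",
    "DM2": "DM2",
    "DM3": "DM3",
    "DM4": "DM4",
    "DM5": "DM5",
}

DEFAULT_FILTER_THRESHOLD = 0.025
DEFAULT_MIN_TERMINALS = 40


@dataclass(frozen=True)
class TransactionSet:
    """Per-segment itemsets over a fixed item alphabet."""

    itemsets: tuple  # tuple of frozensets
    segment_ids: tuple
    alphabet: tuple
    filter_threshold: float = DEFAULT_FILTER_THRESHOLD
    min_terminals: int = DEFAULT_MIN_TERMINALS

    def __len__(self) -> int:
        return len(self.itemsets)


@dataclass
class NetworkModel:
    """Confidence-weighted directed graph over the item alphabet."""

    graph: nx.DiGraph
    outstrength: dict

    @property
    def nodes(self) -> tuple:
        return tuple(self.graph.nodes)


def build_transactions(
    boutons: pd.DataFrame,
    grouping: dict | None = None,
    filter_threshold: float = DEFAULT_FILTER_THRESHOLD,
    min_terminals: int = DEFAULT_MIN_TERMINALS,
    label_column: str = "subpop",
) -> TransactionSet:
    """Turn a labeled, segment-linked bouton table into transactions.

    Every bouton must carry a subpopulation label and a segment id.  The
    grouping map (default: LM1-4 -> LM) is applied before presence coding;
    multiplicity within a segment is used only by the rare-occurrence
    filter.
    """
    grouping = DEFAULT_GROUPING if grouping is None else grouping
    if label_column not in boutons.columns:
        raise DataIntegrityError(f"bouton table lacks column {label_column!r}")
    if "segment_id" not in boutons.columns:
        raise DataIntegrityError("bouton table lacks column 'segment_id'")
    if boutons[label_column].isna().any():
        raise DataIntegrityError("unlabeled bouton in transaction input")
    if boutons["segment_id"].isna().any():
        raise DataIntegrityError("bouton without segment id in transaction input")

    items = boutons[label_column].map(lambda s: grouping.get(s, s))
    alphabet = tuple(sorted(set(grouping.values())))
    df = pd.DataFrame({"segment_id": boutons["segment_id"], "item": items})
    itemsets, seg_ids = [], []
    for seg, sub in df.groupby("segment_id"):
        counts = sub["item"].value_counts()
        total = counts.sum()
        if total >= min_terminals:
            counts = counts[counts / total >= filter_threshold]
        if counts.empty:
            warnings.warn(f"segment {seg}: no items survive the filter; dropped")
            continue
        itemsets.append(frozenset(counts.index))
        seg_ids.append(seg)
    return TransactionSet(
        itemsets=tuple(itemsets),
        segment_ids=tuple(seg_ids),
        alphabet=alphabet,
        filter_threshold=filter_threshold,
        min_terminals=min_terminals,
    )


def mine_rules(tx: TransactionSet) -> pd.DataFrame:
    """Exact support/confidence/lift for every ordered item pair.

    Pairs whose antecedent never occurs are omitted.  Counting is exact over
    all transactions (no sampling); the result matches brute-force
    enumeration bit for bit.
    """
    n = len(tx)
    if n == 0:
        raise ConfigurationError("empty transaction set")
    single = {a: sum(a in s for s in tx.itemsets) for a in tx.alphabet}
    rows = []
    for a, b in itertools.permutations(tx.alphabet, 2):
        if single[a] == 0:
            continue
        ab = sum((a in s) and (b in s) for s in tx.itemsets)
        supp_a = single[a] / n
        supp_b = single[b] / n
        supp_ab = ab / n
        # ratios of integer counts, so results match enumeration exactly
        confidence = ab / single[a]
        lift = ab * n / (single[a] * single[b]) if single[b] > 0 else np.nan
        rows.append((a, b, supp_a, supp_b, supp_ab, confidence, lift))
    return pd.DataFrame(
        rows,
        columns=[
            "antecedent",
            "consequent",
            "support_a",
            "support_b",
            "support_ab",
            "confidence",
            "lift",
        ],
    )


def lift_matrix(rules: pd.DataFrame) -> pd.DataFrame:
    """Heat-map-ready lift matrix (rows = IF item, columns = THEN item)."""
    return rules.pivot(index="antecedent", columns="consequent", values="lift")


def build_network(
    rules: pd.DataFrame,
    min_support: float = 0.1,
    min_confidence: float = 0.0,
    alphabet: tuple | None = None,
) -> NetworkModel:
    """Confidence-weighted directed graph with per-node outstrength.

    Edges whose pair support or confidence falls below the thresholds are
    omitted; nodes with no surviving outgoing edges have outstrength 0.
    """
    g = nx.DiGraph()
    nodes = alphabet or tuple(
        sorted(set(rules["antecedent"]) | set(rules["consequent"]))
    )
    g.add_nodes_from(nodes)
    for _, r in rules.iterrows():
        if r["support_ab"] >= min_support and r["confidence"] >= min_confidence:
            if r["confidence"] > 0:
                g.add_edge(r["antecedent"], r["consequent"], weight=r["confidence"])
    outstrength = {
        node: float(sum(d["weight"] for _, _, d in g.out_edges(node, data=True)))
        for node in g.nodes
    }
    return NetworkModel(graph=g, outstrength=outstrength)
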