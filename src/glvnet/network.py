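"""Ecological classification and export of the inferred interaction network.

Every unordered taxon pair {i, j} carries two directed coefficients: a_ij
(effect of j on i) and a_ji (effect of i on j).  Their significance-resolved
signs place the pair in one of six ecological relationships:

    +/+  mutualism       -/-  competition    +/-  parasitism
    +/0  commensalism    -/0  amensalism     0/0  neutral

A directed edge j → i exists in the network exactly when a_ij is significant;
its weight is the aggregated (mean) coefficient.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import networkx as nx
import pandas as pd

__all__ = ["InteractionNetwork", "classify_pair", "build_network"]

_LABELS = {
    (1, 1): "mutualism",
    (-1, -1): "competition",
    (1, -1): "parasitism",
    (-1, 1): "parasitism",
    (1, 0): "commensalism",
    (0, 1): "commensalism",
    (-1, 0): "amensalism",
    (0, -1): "amensalism",
    (0, 0): "neutral",
}

_SIGN_ALIASES = {"+": 1, "-": -1, "−": -1, "0": 0, 1: 1, -1: -1, 0: 0}

# a significant mean this close to zero carries no usable sign
ZERO_SIGN_TOL = 1e-12


def classify_pair(a_ij_sign, a_ji_sign) -> str:
    """Six-way ecological label from the two significance-resolved signs.

    Signs may be given as -1/0/+1 or '-'/'0'/'+' (0 = not significant).
    Symmetric in argument order.
    """
    try:
        s1 = _SIGN_ALIASES[a_ij_sign]
        s2 = _SIGN_ALIASES[a_ji_sign]
    except KeyError as exc:
        raise ValueError(f"invalid sign {exc.args[0]!r}; use -1/0/+1 or '-'/'0'/'+'") from None
    return _LABELS[(s1, s2)]


@dataclass(frozen=True)
class Edge:
    """Directed interaction: ``source`` acts on ``target`` with coefficient a_(target,source)."""

    source: str
    target: str
    weight: float
    p_value: float
    selection_frequency: float


@dataclass(frozen=True)
class InteractionNetwork:
    """Significant directed interactions plus six-way pair classification.

    Edge direction convention: an edge j → i encodes a_ij, the effect OF the
    source taxon j ON the target taxon i.  ``pair_labels`` maps each
    unordered pair (as a sorted 2-tuple of taxon names) to its ecological
    label; ``nodes`` maps taxon -> (growth-rate mean, standard error).
    """

    taxa: tuple
    nodes: dict
    edges: tuple
    pair_labels: dict

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph(direction_convention="edge j->i encodes a_ij (effect of j on i)")
        for taxon in self.taxa:
            mean, se = self.nodes[taxon]
            g.add_node(taxon, growth_rate_mean=mean, growth_rate_se=se)
        for e in self.edges:
            pair = tuple(sorted((e.source, e.target)))
            g.add_edge(
                e.source,
                e.target,
                weight=e.weight,
                p_value=e.p_value,
                selection_frequency=e.selection_frequency,
                pair_label=self.pair_labels[pair],
            )
        return g

    def edges_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "source": e.source,
                "target": e.target,
                "coefficient_mean": e.weight,
                "p_value": e.p_value,
                "selection_frequency": e.selection_frequency,
                "pair_label": self.pair_labels[tuple(sorted((e.source, e.target)))],
            }
            for e in self.edges
        ]
        df = pd.DataFrame(
            rows,
            columns=[
                "source",
                "target",
                "coefficient_mean",
                "p_value",
                "selection_frequency",
                "pair_label",
            ],
        )
        return df.sort_values(["source", "target"]).reset_index(drop=True)

    def nodes_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "taxon": t,
                    "growth_rate_mean": self.nodes[t][0],
                    "growth_rate_se": self.nodes[t][1],
                }
                for t in self.taxa
            ]
        )

    def write_edges_tsv(self, path) -> None:
        self.edges_dataframe().to_csv(path, sep="\t", index=False)

    def write_nodes_tsv(self, path) -> None:
        self.nodes_dataframe().to_csv(path, sep="\t", index=False)

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    def to_json(self) -> str:
        payload = {
            "direction_convention": "edge j->i encodes a_ij (effect of j on i)",
            "taxa": list(self.taxa),
            "nodes": {t: {"growth_rate_mean": v[0], "growth_rate_se": v[1]} for t, v in self.nodes.items()},
            "edges": [
                {
                    "source": e.source,
                    "target": e.target,
                    "weight": e.weight,
                    "p_value": e.p_value,
                    "selection_frequency": e.selection_frequency,
                }
                for e in self.edges
            ],
            "pair_labels": {f"{a}|{b}": lab for (a, b), lab in sorted(self.pair_labels.items())},
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "InteractionNetwork":
        d = json.loads(text)
        return cls(
            taxa=tuple(d["taxa"]),
            nodes={t: (v["growth_rate_mean"], v["growth_rate_se"]) for t, v in d["nodes"].items()},
            edges=tuple(
                Edge(e["source"], e["target"], e["weight"], e["p_value"], e["selection_frequency"])
                for e in d["edges"]
            ),
            pair_labels={tuple(k.split("|")): lab for k, lab in d["pair_labels"].items()},
        )


def _resolved_sign(coef) -> int:
    """Sign used for classification: 0 unless significant with usable magnitude."""
    if not coef.significant or abs(coef.mean) <= ZERO_SIGN_TOL:
        return 0
    return 1 if coef.mean > 0 else -1


def build_network(aggregated, growth: dict, taxa) -> InteractionNetwork:
    """Assemble the interaction network from aggregated coefficients.

    ``aggregated`` must cover all ordered pairs (i, j); an edge j → i is
    emitted for each significant a_ij, weighted by its mean coefficient.
    Pair labels follow :func:`classify_pair` on the significance-resolved
    signs.
    """
    taxa = tuple(taxa)
    by_pair = {c.pair: c for c in aggregated}
    n = len(taxa)
    expected = {(i, j) for i in range(n) for j in range(n) if i != j}
    if set(by_pair) != expected:
        missing = expected - set(by_pair)
        raise ValueError(f"aggregated coefficients must cover all ordered pairs; missing {sorted(missing)}")

    edges = []
    pair_labels = {}
    for i in range(n):
        for j in range(i + 1, n):
            c_ij, c_ji = by_pair[(i, j)], by_pair[(j, i)]
            s_ij, s_ji = _resolved_sign(c_ij), _resolved_sign(c_ji)
            pair_labels[tuple(sorted((taxa[i], taxa[j])))] = classify_pair(s_ij, s_ji)
            if s_ij != 0:
                edges.append(
                    Edge(taxa[j], taxa[i], c_ij.mean, c_ij.p_value, c_ij.selection_frequency)
                )
            if s_ji != 0:
                edges.append(
                    Edge(taxa[i], taxa[j], c_ji.mean, c_ji.p_value, c_ji.selection_frequency)
                )
    nodes = {t: (float(growth[t][0]), float(growth[t][1])) for t in taxa}
    return InteractionNetwork(taxa=taxa, nodes=nodes, edges=tuple(edges), pair_labels=pair_labels)
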