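"""Signed directed regulatory networks and the union-merge of evidence layers.

Edges carry a sign (``+`` activation, ``-`` inhibition, ``?`` unknown) and a
provenance set (``tfbs`` for binding-site predictions, ``literature`` for
curated interactions).  Edge identity is the ordered (source, target) pair:
the Boolean contextualization genome is per-edge and a duplicated pair would
double-count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import pandas as pd

SIGNS = ("+", "-", "?")
PROVENANCES = ("tfbs", "literature")


@dataclass(frozen=True)
class Interaction:
    """A directed regulatory edge."""

    source: str
    target: str
    sign: str = "?"
    provenance: frozenset = frozenset({"literature"})

    def __post_init__(self) -> None:
        if self.sign not in SIGNS:
            raise ValueError(f"malformed sign {self.sign!r} on {self.source}->{self.target}")
        if not self.source or not self.target:
            raise ValueError("blank node id in interaction")
        prov = frozenset(self.provenance)
        if not prov or not prov <= set(PROVENANCES):
            raise ValueError(f"invalid provenance {set(self.provenance)!r}")
        object.__setattr__(self, "provenance", prov)

    @property
    def key(self) -> tuple[str, str]:
        return (self.source, self.target)


class GRN:
    """A gene regulatory network: node set + at most one edge per ordered pair."""

    def __init__(self, interactions: Iterable[Interaction] = (), nodes: Iterable[str] = ()):
        self.nodes: set[str] = set(nodes)
        self.edges: dict[tuple[str, str], Interaction] = {}
        for ix in interactions:
            self.add(ix)

    def add(self, ix: Interaction, *, allow_self_loops: bool = False) -> None:
        if ix.source == ix.target and not allow_self_loops:
            warnings.warn(f"dropping self-loop {ix.source}->{ix.target}", stacklevel=2)
            return
        existing = self.edges.get(ix.key)
        if existing is not None:
            ix = _resolve(existing, ix)
        self.edges[ix.key] = ix
        self.nodes.add(ix.source)
        self.nodes.add(ix.target)

    def __len__(self) -> int:
        return len(self.edges)

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self.edges

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GRN)
            and self.nodes == other.nodes
            and self.edges == other.edges
        )

    def sorted_edges(self) -> list[Interaction]:
        return [self.edges[k] for k in sorted(self.edges)]

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(sorted(self.nodes))
        for ix in self.sorted_edges():
            g.add_edge(ix.source, ix.target, sign=ix.sign, provenance=sorted(ix.provenance))
        return g

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "source": ix.source,
                "target": ix.target,
                "sign": ix.sign,
                "provenance": ",".join(sorted(ix.provenance)),
            }
            for ix in self.sorted_edges()
        ]
        return pd.DataFrame(rows, columns=["source", "target", "sign", "provenance"])


def _resolve(a: Interaction, b: Interaction) -> Interaction:
    """Key-local sign resolution: a known sign beats '?'; two different known
    signs are an input error rather than silently resolved."""
    if a.sign == b.sign:
        sign = a.sign
    elif a.sign == "?":
        sign = b.sign
    elif b.sign == "?":
        sign = a.sign
    else:
        raise ValueError(
            f"conflicting signs for edge {a.source}->{a.target}: {a.sign!r} vs {b.sign!r}"
        )
    return Interaction(a.source, a.target, sign, a.provenance | b.provenance)


def load_edge_list(path) -> GRN:
    """Read a TSV edge list with columns (source, target, sign, provenance).

    Duplicate rows with identical keys and signs collapse to one edge;
    identical keys carrying conflicting known signs raise, naming the
    offending pair.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"source", "target", "sign", "provenance"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"edge list missing columns: {sorted(missing)}")
    grn = GRN()
    for row in df.itertuples(index=False):
        if pd.isna(row.source) or pd.isna(row.target):
            raise ValueError("dangling blank node id in edge list")
        prov = frozenset(str(row.provenance).split(","))
        grn.add(Interaction(str(row.source), str(row.target), str(row.sign), prov))
    return grn


def write_edge_list(grn: GRN, path) -> None:
    grn.to_frame().to_csv(path, sep="\t", index=False)


def write_sif(grn: GRN, path) -> None:
    """SIF export: source<TAB>relation<TAB>target with relation in
    {activates, inhibits, regulates}."""
    relation = {"+": "activates", "-": "inhibits", "?": "regulates"}
    with open(path, "w") as fh:
        for ix in grn.sorted_edges():
            fh.write(f"{ix.source}\t{relation[ix.sign]}\t{ix.target}\n")


def merge(a: GRN, b: GRN) -> GRN:
    """Union-merge two networks on edge keys.

    Node set is the union; on a shared (source, target) key a known sign wins
    over ``?`` and provenance becomes the union, so
    |edges| = |E_a| + |E_b| − |shared keys|.  Commutative and associative.
    """
    merged = GRN(nodes=a.nodes | b.nodes)
    for ix in list(a.edges.values()) + list(b.edges.values()):
        merged.add(ix)
    return merged
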