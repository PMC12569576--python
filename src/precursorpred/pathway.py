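"""Biosynthetic pathways as directed acyclic graphs and precursor labeling by
reverse depth-first search.

A pathway is a DAG with compounds as nodes and reactions as directed
substrate→product edges.  A compound's precursors are found by walking the
graph backwards from the compound; the walk stops at the first vocabulary
compound along each path (the *nearest-precursor* rule), so that, e.g., a
diterpenoid built via GGPP is labeled with GGPP only and does not inherit the
upstream GPP as well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .errors import CycleError, DataError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PrecursorVocabulary:
    """Ordered list of precursor names; the order fixes label-column order everywhere."""

    names: tuple[str, ...]
    smiles: Mapping[str, str] | None = None

    def __post_init__(self):
        object.__setattr__(self, "names", tuple(self.names))
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if list(self.names).count(n) > 1})
            raise DataError(f"duplicate precursor names: {dupes}")
        if self.smiles is not None:
            unknown = set(self.smiles) - set(self.names)
            if unknown:
                raise DataError(f"smiles map contains names outside the vocabulary: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def index(self, name: str) -> int:
        return self.names.index(name)


class PathwayGraph:
    """A validated pathway DAG backed by a :class:`networkx.DiGraph`."""

    def __init__(self, graph: nx.DiGraph):
        self._g = graph

    @property
    def nx(self) -> nx.DiGraph:
        return self._g

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self._g.edges)

    def __contains__(self, node: str) -> bool:
        return node in self._g

    def reaction(self, substrate: str, product: str) -> str | None:
        return self._g.edges[substrate, product].get("reaction")


def build_graph(edge_list: Iterable[tuple[str, str, str | None]]) -> PathwayGraph:
    """Build a pathway DAG from (substrate, product, reaction) triples.

    Duplicate edges are collapsed.  Self-loops and directed cycles are
    rejected: the error names one offending cycle rather than silently
    accepting a non-DAG.
    """
    g = nx.DiGraph()
    for item in edge_list:
        if len(item) == 2:
            s, p = item
            r = None
        else:
            s, p, r = item
        if not isinstance(s, str) or not isinstance(p, str) or not s or not p:
            raise DataError(f"edge endpoints must be non-empty strings, got ({s!r}, {p!r})")
        if s == p:
            raise CycleError([s])
        g.add_edge(s, p, reaction=r)
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle is not None:
        raise CycleError([u for u, _v in cycle])
    return PathwayGraph(g)


def read_edge_list(path) -> PathwayGraph:
    """Read a TSV edge list with columns substrate_id, product_id, reaction_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"substrate_id", "product_id"}
    if not required.issubset(df.columns):
        raise DataError(f"edge list must have columns {sorted(required)}, got {list(df.columns)}")
    rxn = df["reaction_id"] if "reaction_id" in df.columns else [None] * len(df)
    return build_graph(zip(df["substrate_id"], df["product_id"], rxn))


def precursor_labels(
    graph: PathwayGraph, target: str, vocab: PrecursorVocabulary
) -> set[str]:
    """Precursors of ``target``: reverse DFS stopping at vocabulary nodes.

    Walks substrate←product edges from ``target``.  A vocabulary node reached
    on a path is collected and NOT expanded further (nearest-precursor rule),
    so downstream compounds do not inherit every upstream precursor.  The
    target itself never counts as its own precursor.
    """
    if target not in graph:
        raise DataError(f"target compound {target!r} not in pathway graph")
    g = graph.nx
    found: set[str] = set()
    seen: set[str] = {target}
    stack = list(g.predecessors(target))
    while stack:
        node = stack.pop()
        if node in seen:
            continue
        seen.add(node)
        if node in vocab:
            found.add(node)
            continue  # nearest-precursor rule: do not expand past a vocab node
        stack.extend(g.predecessors(node))
    return found


def label_table(
    graph: PathwayGraph, targets: Sequence[str], vocab: PrecursorVocabulary
) -> pd.DataFrame:
    """0/1 label table (one row per target, one column per vocabulary entry).

    The table metadata records that the nearest-precursor rule was applied.
    """
    rows = []
    for t in targets:
        labels = precursor_labels(graph, t, vocab)
        rows.append([1 if name in labels else 0 for name in vocab])
    df = pd.DataFrame(rows, columns=list(vocab), index=pd.Index(targets, name="compound_id"))
    df.attrs["labeling_rule"] = "nearest_precursor"
    return df
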