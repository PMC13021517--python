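"""The cell-type label hierarchy as a directed acyclic graph.

Cell-type terms form a partial order under the is_a (subtype) relation: a
"CD4-positive, alpha-beta T cell" is_a "T cell" is_a "lymphocyte".  The
:class:`Ontology` stores the terms and their child->parent is_a edges,
assigns every term a fixed index (lexicographic by term ID, so matrices
align across runs and files), and derives the two structures everything
downstream consumes:

* the **reachability matrix** ``R`` with ``R[i, j] = 1`` iff ``j`` is ``i``
  itself or a descendant of ``i`` — the transitive closure of the inverted
  (parent->child) adjacency with the diagonal forced to one; and
* a **node taxonomy** classifying each term as leaf/internal and
  connected/isolated.

Multiple parents are permitted — the cell ontology is a true DAG, not a
tree — and descendant sets are computed by reachability, never by path
counting, so a term reachable along several paths contributes once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import obonet
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["Ontology", "NodeTaxonomy", "CycleError"]


class CycleError(ValueError):
    """Raised when the is_a edges contain a directed cycle."""

    def __init__(self, cycle: Sequence[tuple[str, str]]):
        self.cycle = list(cycle)
        path = " -> ".join([u for u, _ in self.cycle] + [self.cycle[-1][1]])
        super().__init__(f"is_a relations contain a cycle: {path}")


@dataclass(frozen=True)
class NodeTaxonomy:
    """Structural classification of every ontology node.

    A node is a *leaf* if it has no children in the (pruned) graph and
    *internal* otherwise; it is *connected* if at least one parent or child
    is present and *isolated* if none of its ancestors or descendants are.
    """

    node_ids: tuple[str, ...]
    is_leaf: np.ndarray
    is_connected: np.ndarray

    @property
    def is_internal(self) -> np.ndarray:
        return ~self.is_leaf

    @property
    def is_isolated(self) -> np.ndarray:
        return ~self.is_connected

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "is_leaf": self.is_leaf,
                "is_internal": self.is_internal,
                "is_connected": self.is_connected,
                "is_isolated": self.is_isolated,
            },
            index=list(self.node_ids),
        )


class Ontology:
    """A set of cell-type terms with directed child->parent is_a edges.

    Parameters
    ----------
    node_ids
        Term identifiers.  They are stored sorted lexicographically; the
        sorted position of a term is its class index everywhere downstream.
    edges
        ``(child, parent)`` pairs.  Both endpoints must be declared nodes
        and the resulting graph must be acyclic.
    names
        Optional mapping from term ID to a human-readable display name.
    """

    def __init__(
        self,
        node_ids: Iterable[str],
        edges: Iterable[tuple[str, str]] = (),
        names: Mapping[str, str] | None = None,
    ):
        self.node_ids: tuple[str, ...] = tuple(sorted(set(node_ids)))
        self._index = {n: i for i, n in enumerate(self.node_ids)}
        self.names = {n: (names or {}).get(n, n) for n in self.node_ids}

        edge_set = set()
        for child, parent in edges:
            for endpoint in (child, parent):
                if endpoint not in self._index:
                    raise ValueError(
                        f"edge ({child!r}, {parent!r}) references undeclared "
                        f"node {endpoint!r}"
                    )
            if child == parent:
                raise CycleError([(child, parent)])
            edge_set.add((child, parent))
        self.edges: frozenset[tuple[str, str]] = frozenset(edge_set)

        g = nx.DiGraph()
        g.add_nodes_from(self.node_ids)
        g.add_edges_from(self.edges)
        if not nx.is_directed_acyclic_graph(g):
            raise CycleError(nx.find_cycle(g))
        self._graph = g  # edges child -> parent
        self._reachability: np.ndarray | None = None

    # ------------------------------------------------------------------
    # basic accessors
    # ------------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.node_ids)

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._index

    def index(self, node_id: str) -> int:
        """Class index of a term (position in the fixed lexicographic order)."""
        try:
            return self._index[node_id]
        except KeyError:
            raise KeyError(f"unknown ontology term {node_id!r}") from None

    def indices(self, node_ids: Iterable[str]) -> np.ndarray:
        return np.array([self.index(n) for n in node_ids], dtype=np.int64)

    def parents(self, node_id: str) -> set[str]:
        return set(self._graph.successors(node_id))

    def children(self, node_id: str) -> set[str]:
        return set(self._graph.predecessors(node_id))

    def ancestors(self, node_id: str) -> set[str]:
        """All strict ancestors (transitively, along is_a edges)."""
        return set(nx.descendants(self._graph, node_id))

    def descendants(self, node_id: str) -> set[str]:
        """All strict descendants (terms of which ``node_id`` is an ancestor)."""
        return set(nx.ancestors(self._graph, node_id))

    # ------------------------------------------------------------------
    # readers / writers
    # ------------------------------------------------------------------
    @classmethod
    def from_edgelist(cls, path: str | Path) -> "Ontology":
        """Read a two-column child<TAB>parent edge list ('#' starts a comment)."""
        nodes: set[str] = set()
        edges: list[tuple[str, str]] = []
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) == 1:  # isolated node declaration
                nodes.add(fields[0].strip())
                continue
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 'child<TAB>parent', got {raw!r}"
                )
            child, parent = (f.strip() for f in fields)
            nodes.update((child, parent))
            edges.append((child, parent))
        return cls(nodes, edges)

    @classmethod
    def from_obo(cls, path: str | Path) -> "Ontology":
        """Read an OBO file, keeping only [Term] id/name/is_a content.

        Any relation other than is_a (part_of, develops_from, ...) is
        ignored with a logged warning.
        """
        graph = obonet.read_obo(str(path), ignore_obsolete=True)
        names = {
            n: data.get("name", n) for n, data in graph.nodes(data=True)
        }
        edges = []
        ignored = 0
        for child, parent, relation in graph.edges(keys=True):
            if relation == "is_a":
                edges.append((child, parent))
            else:
                ignored += 1
        if ignored:
            logger.warning(
                "ignored %d non-is_a relation(s) while reading %s", ignored, path
            )
        return cls(graph.nodes, edges, names=names)

    @classmethod
    def load(cls, path: str | Path) -> "Ontology":
        """Dispatch on extension: .obo -> OBO reader, else edge-list TSV."""
        if str(path).endswith(".obo"):
            return cls.from_obo(path)
        return cls.from_edgelist(path)

    def to_edgelist(self, path: str | Path) -> None:
        """Write the DAG as a child<TAB>parent TSV (isolated nodes as bare rows)."""
        with_edges = {n for e in self.edges for n in e}
        lines = [f"{c}\t{p}" for c, p in sorted(self.edges)]
        lines += [n for n in self.node_ids if n not in with_edges]
        Path(path).write_text("\n".join(lines) + "\n")

    # ------------------------------------------------------------------
    # derived structures
    # ------------------------------------------------------------------
    def reachability(self) -> np.ndarray:
        """The C x C binary partial-order matrix.

        ``R[i, j] = 1`` iff class ``j`` is reachable from class ``i``:
        ``j`` is ``i`` itself (the diagonal is forced to one) or ``j`` is a
        descendant of ``i``.  Equivalently, the transitive closure of the
        inverted (parent->child) adjacency matrix.  Cached after the first
        call; do not mutate the returned array.
        """
        if self._reachability is None:
            c = len(self)
            r = np.eye(c, dtype=np.uint8)
            for i, node in enumerate(self.node_ids):
                for desc in self.descendants(node):
                    r[i, self._index[desc]] = 1
            self._reachability = r
        return self._reachability

    def classify_nodes(self) -> NodeTaxonomy:
        """Leaf/internal and connected/isolated status of every node."""
        is_leaf = np.array(
            [self._graph.in_degree(n) == 0 for n in self.node_ids], dtype=bool
        )
        is_connected = np.array(
            [self._graph.degree(n) > 0 for n in self.node_ids], dtype=bool
        )
        return NodeTaxonomy(self.node_ids, is_leaf, is_connected)

    def prune_to_labels(self, observed: Iterable[str]) -> "Ontology":
        """Restrict the ontology to an observed label set.

        The pruned graph keeps exactly the observed terms.  An edge
        ``u -> v`` is kept iff ``v`` is an ancestor of ``u`` in the full
        graph and no other observed term lies strictly between them on some
        path — i.e. the transitive reduction of the observed-ancestry
        relation.  Ancestry among observed terms is therefore preserved
        exactly, which is all the loss and the evaluator consume.
        """
        observed = set(observed)
        missing = observed - set(self.node_ids)
        if missing:
            raise KeyError(
                "observed label(s) absent from ontology: "
                + ", ".join(sorted(missing))
            )
        closure = nx.DiGraph()
        closure.add_nodes_from(observed)
        for u in observed:
            for v in self.ancestors(u) & observed:
                closure.add_edge(u, v)
        reduced = nx.transitive_reduction(closure)
        return Ontology(
            observed,
            reduced.edges(),
            names={n: self.names[n] for n in observed},
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Ontology({len(self)} nodes, {len(self.edges)} is_a edges)"
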