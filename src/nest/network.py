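"""Weighted undirected gene-interaction networks.

The central container is :class:`WeightedGeneNetwork`, a thin validated
wrapper around an undirected :class:`networkx.Graph` whose nodes are gene
identifiers and whose edges carry a confidence weight in ``(0, 1]`` — the
"connectivity matrix" that NEST multiplies against a per-gene value vector.

Networks are exchanged as STRING-like edge-list TSVs
(``geneA<TAB>geneB<TAB>weight``). STRING ships integer combined scores in
0–1000, so :func:`read_edge_list` divides by a configurable ``weight_scale``
(default 1000) to obtain confidences.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from typing import Optional

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)


class WeightedGeneNetwork:
    """Undirected simple graph with positive confidence weights.

    Invariants enforced at construction:

    * no self-loops;
    * at most one edge per unordered gene pair;
    * every edge endpoint is a node (isolated nodes are allowed);
    * all weights strictly positive finite reals.
    """

    def __init__(self, graph: nx.Graph):
        self._validate(graph)
        self._g = graph

    @staticmethod
    def _validate(graph: nx.Graph) -> None:
        if graph.is_directed() or graph.is_multigraph():
            raise ValidationError("network must be a simple undirected graph")
        for node in graph.nodes:
            if not isinstance(node, str) or not node:
                raise ValidationError(f"gene identifiers must be non-empty strings, got {node!r}")
        for a, b, data in graph.edges(data=True):
            if a == b:
                raise ValidationError(f"self-loop on {a!r} is not allowed")
            w = data.get("weight")
            if w is None or not np.isfinite(w) or w <= 0:
                raise ValidationError(f"edge {a!r}–{b!r} has non-positive weight {w!r}")

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, float]],
        nodes: Optional[Iterable[str]] = None,
    ) -> "WeightedGeneNetwork":
        """Build a network from ``(geneA, geneB, weight)`` triples.

        Duplicate listings of the same unordered pair are collapsed by
        keeping the maximum weight; extra ``nodes`` become isolated nodes.
        """
        g = nx.Graph()
        if nodes is not None:
            g.add_nodes_from(nodes)
        for a, b, w in edges:
            w = float(w)
            if g.has_edge(a, b):
                w = max(w, g[a][b]["weight"])
            g.add_edge(a, b, weight=w)
        return cls(g)

    # -- basic interrogation -------------------------------------------------

    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def nodes(self) -> list[str]:
        return list(self._g.nodes)

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def edges(self) -> list[tuple[str, str, float]]:
        """Canonicalized edge list: endpoints sorted within a pair, pairs sorted."""
        out = []
        for a, b, data in self._g.edges(data=True):
            x, y = sorted((a, b))
            out.append((x, y, float(data["weight"])))
        return sorted(out)

    def has_edge(self, a: str, b: str) -> bool:
        return self._g.has_edge(a, b)

    def weight(self, a: str, b: str) -> float:
        return float(self._g[a][b]["weight"])

    def neighbors(self, gene: str) -> list[str]:
        return list(self._g.neighbors(gene))

    def degree(self) -> dict[str, int]:
        """Unweighted degree (count of incident edges); isolated nodes map to 0."""
        return {n: int(d) for n, d in self._g.degree()}

    def degree_sequence(self) -> list[int]:
        return sorted(d for _, d in self._g.degree())

    def adjacency(self, order: Optional[list[str]] = None) -> sp.csr_matrix:
        """Symmetric sparse connectivity matrix in the given node order."""
        if order is None:
            order = self.nodes
        return nx.to_scipy_sparse_array(self._g, nodelist=order, weight="weight", format="csr")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WeightedGeneNetwork):
            return NotImplemented
        return set(self.nodes) == set(other.nodes) and self.edges() == other.edges()

    def __repr__(self) -> str:
        return f"WeightedGeneNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


def read_edge_list(
    path,
    weight_scale: float = 1000.0,
    allow_unweighted: bool = False,
    header: bool = False,
) -> WeightedGeneNetwork:
    """Read a 2–3 column whitespace/tab separated edge list.

    Weights are divided by ``weight_scale``; duplicate pair listings are
    collapsed by maximum weight; self-loops are dropped with a warning. A
    2-column file is accepted only with ``allow_unweighted`` (all weights 1).
    """
    if weight_scale <= 0:
        raise ValidationError(f"weight_scale must be positive, got {weight_scale}")
    g = nx.Graph()
    n_self_loops = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ParseError(f"{path}: line {lineno}: expected >=2 columns, got {len(fields)}")
            a, b = fields[0], fields[1]
            if len(fields) >= 3:
                try:
                    raw = float(fields[2])
                except ValueError as exc:
                    raise ParseError(
                        f"{path}: line {lineno}: non-numeric weight {fields[2]!r}"
                    ) from exc
                w = raw / weight_scale
            elif allow_unweighted:
                w = 1.0
            else:
                raise ParseError(
                    f"{path}: line {lineno}: missing weight column "
                    "(pass allow_unweighted to default weights to 1)"
                )
            if not np.isfinite(w) or w <= 0:
                raise ValidationError(
                    f"{path}: line {lineno}: non-positive weight {w} after scaling"
                )
            if a == b:
                n_self_loops += 1
                continue
            if g.has_edge(a, b):
                w = max(w, g[a][b]["weight"])
            g.add_edge(a, b, weight=w)
    if n_self_loops:
        logger.warning("%s: dropped %d self-loop edge(s)", path, n_self_loops)
    return WeightedGeneNetwork(g)


def write_edge_list(net: WeightedGeneNetwork, path, header: bool = False) -> None:
    """Write the canonicalized edge list as ``geneA<TAB>geneB<TAB>weight``.

    Isolated nodes are not representable in an edge list and are omitted.
    """
    with open(path, "w") as fh:
        if header:
            fh.write("geneA\tgeneB\tweight\n")
        for a, b, w in net.edges():
            fh.write(f"{a}\t{b}\t{w:g}\n")


def read_identifier_map(path, header: bool = False) -> dict[str, str]:
    """Read a 2-column ``source<TAB>target`` mapping (many-to-one permitted)."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 columns")
            src, dst = fields[0], fields[1]
            if not src or not dst:
                raise ParseError(f"{path}: line {lineno}: empty identifier")
            mapping[src] = dst
    return mapping


def map_identifiers(
    net: WeightedGeneNetwork,
    mapping: Mapping[str, str],
    keep_unmapped: bool = False,
) -> WeightedGeneNetwork:
    """Rename nodes through an identifier map (e.g. STRING protein → symbol).

    Edges that become parallel after renaming are collapsed by maximum
    weight; edges that become self-loops are dropped. Unmapped nodes are
    dropped (with a logged count) unless ``keep_unmapped`` keeps them under
    their original identifier.
    """
    for src, dst in mapping.items():
        if not src or not dst:
            raise ValidationError("identifier map contains an empty identifier")
    n_unmapped = sum(1 for n in net.nodes if n not in mapping)
    if n_unmapped and not keep_unmapped:
        logger.info("map_identifiers: dropping %d unmapped node(s)", n_unmapped)

    def resolve(node: str) -> Optional[str]:
        if node in mapping:
            return mapping[node]
        return node if keep_unmapped else None

    g = nx.Graph()
    for node in net.nodes:
        new = resolve(node)
        if new is not None:
            g.add_node(new)
    for a, b, w in net.edges():
        na, nb = resolve(a), resolve(b)
        if na is None or nb is None or na == nb:
            continue
        if g.has_edge(na, nb):
            w = max(w, g[na][nb]["weight"])
        g.add_edge(na, nb, weight=w)
    if g.number_of_nodes() == 0:
        raise ValidationError("identifier mapping produced an empty network")
    return WeightedGeneNetwork(g)


def degree(net: WeightedGeneNetwork) -> dict[str, int]:
    """Per-gene count of incident edges (the classic hub covariate)."""
    return net.degree()
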