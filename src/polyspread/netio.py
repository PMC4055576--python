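"""Network containers, generators and plain-text edge-list I/O.

The dynamics modules operate on simple undirected graphs. ``Network`` is a
thin immutable wrapper around a CSR adjacency structure; ``MultiplexNetwork``
stacks several layers over one node universe, so a contagion can have a
different contact structure (and transmission matrix) per layer.

Node identifiers are always 0..N-1 internally. Edge-list files may use
arbitrary integer labels; they are compacted on load and the original-id
mapping is retained on the returned object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp


class EdgeListParseError(ValueError):
    """Malformed edge-list input (reported with the offending line number)."""


@dataclass(frozen=True)
class Network:
    """Simple undirected graph with 0-based contiguous node ids.

    Attributes
    ----------
    n : int
        Number of nodes (>= 1).
    edges : tuple of (int, int)
        Canonicalized edge set: each pair sorted, pairs sorted, no
        self-loops, no duplicates.
    original_ids : tuple of int or None
        ``original_ids[i]`` is the label node ``i`` carried in the source
        file; ``None`` for generated graphs.
    """

    n: int
    edges: tuple = ()
    original_ids: tuple | None = None
    _adj: sp.csr_matrix = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("network needs at least one node")
        canon = set()
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop at node {u}")
            if not (0 <= u < self.n and 0 <= v < self.n):
                raise ValueError(f"edge ({u},{v}) outside node range 0..{self.n - 1}")
            canon.add((min(u, v), max(u, v)))
        object.__setattr__(self, "edges", tuple(sorted(canon)))
        if self.edges:
            rows = np.array([e[0] for e in self.edges] + [e[1] for e in self.edges])
            cols = np.array([e[1] for e in self.edges] + [e[0] for e in self.edges])
            data = np.ones(rows.size, dtype=np.int8)
            adj = sp.csr_matrix((data, (rows, cols)), shape=(self.n, self.n))
        else:
            adj = sp.csr_matrix((self.n, self.n), dtype=np.int8)
        object.__setattr__(self, "_adj", adj)

    # -- accessors ---------------------------------------------------------
    @property
    def adjacency(self) -> sp.csr_matrix:
        """Binary symmetric adjacency matrix A (CSR)."""
        return self._adj

    @property
    def degrees(self) -> np.ndarray:
        return np.asarray(self._adj.sum(axis=1)).ravel().astype(int)

    def neighbors(self, i: int) -> np.ndarray:
        return self._adj.indices[self._adj.indptr[i]:self._adj.indptr[i + 1]]

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def directed_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """(receiver, sender) arrays listing every ordered adjacent pair.

        The reactive process attempts one transmission per ordered pair per
        step, so the stochastic simulator iterates these arrays directly.
        """
        recv = np.repeat(np.arange(self.n), self.degrees)
        send = self._adj.indices.copy()
        return recv, send

    def is_connected(self) -> bool:
        if self.n == 1:
            return True
        ncomp = sp.csgraph.connected_components(self._adj, directed=False,
                                                return_labels=False)
        return int(ncomp) == 1

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(self.edges)
        return g


@dataclass(frozen=True)
class MultiplexNetwork:
    """Ordered layers of :class:`Network` over one shared node universe.

    A node absent from a layer's edges simply has degree 0 there.
    """

    layers: tuple

    def __post_init__(self):
        if len(self.layers) < 1:
            raise ValueError("need at least one layer")
        ns = {lay.n for lay in self.layers}
        if len(ns) != 1:
            raise ValueError(f"layers disagree on node count: {sorted(ns)}")
        object.__setattr__(self, "layers", tuple(self.layers))

    @property
    def n(self) -> int:
        return self.layers[0].n

    @property
    def n_layers(self) -> int:
        return len(self.layers)


def _warn_if_disconnected(net: Network) -> None:
    # The dynamics are well defined per component; connectivity is advisory.
    if not net.is_connected():
        warnings.warn("network is not connected; dynamics run per component",
                      stacklevel=3)


def load_edge_list(path, layer_column: bool | None = None):
    """Read a plain-text edge list.

    Format: one ``u v [layer]`` per line, whitespace- or comma-delimited,
    ``#`` starts a comment. Duplicate and reversed edges are deduplicated;
    node ids are compacted to 0..N-1 (original labels kept on the result).

    Returns a :class:`Network`, or a :class:`MultiplexNetwork` when a third
    (layer) column is present or ``layer_column=True``.
    """
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            toks = line.replace(",", " ").split()
            if len(toks) not in (2, 3):
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected 2 or 3 columns, got {len(toks)}")
            try:
                vals = [int(t) for t in toks]
            except ValueError as exc:
                raise EdgeListParseError(f"{path}:{lineno}: non-integer token "
                                         f"in {toks}") from exc
            if vals[0] == vals[1]:
                raise EdgeListParseError(f"{path}:{lineno}: self-loop at node "
                                         f"{vals[0]} rejected")
            rows.append(vals)
    if not rows:
        raise EdgeListParseError(f"{path}: no edges found")
    widths = {len(r) for r in rows}
    if widths == {2} and not layer_column:
        multiplex = False
    elif widths == {3} or layer_column:
        if widths != {3}:
            raise EdgeListParseError(f"{path}: layer column requested but absent")
        multiplex = True
    else:
        raise EdgeListParseError(f"{path}: mixed 2- and 3-column lines")

    ids = sorted({r[0] for r in rows} | {r[1] for r in rows})
    remap = {orig: i for i, orig in enumerate(ids)}
    n = len(ids)
    if not multiplex:
        net = Network(n, tuple((remap[u], remap[v]) for u, v, *_ in rows),
                      original_ids=tuple(ids))
        _warn_if_disconnected(net)
        return net

    layer_ids = sorted({r[2] for r in rows})
    layers = []
    for lid in layer_ids:
        edges = tuple((remap[u], remap[v]) for u, v, l in rows if l == lid)
        layers.append(Network(n, edges, original_ids=tuple(ids)))
    return MultiplexNetwork(tuple(layers))


def write_edge_list(network, path) -> None:
    """Write a network in the canonical form that round-trips with
    :func:`load_edge_list` (sorted pairs, one per line; layer column for
    multiplex networks)."""
    with open(path, "w") as fh:
        if isinstance(network, MultiplexNetwork):
            for lid, lay in enumerate(network.layers):
                for u, v in lay.edges:
                    fh.write(f"{u} {v} {lid}\n")
        else:
            for u, v in network.edges:
                fh.write(f"{u} {v}\n")


def make_graph(kind: str, *size) -> Network:
    """Built-in generators used throughout the experiments.

    kind ∈ {"complete", "star", "ring", "lattice2d_periodic"}; ``size`` is
    ``(n,)`` for the first three (total node count; the star has one hub and
    n-1 leaves) and ``(rows, cols)`` for the periodic lattice (torus wiring,
    every node degree 4; requires rows, cols >= 3 so the torus stays simple).
    """
    if kind == "complete":
        (n,) = size
        g = nx.complete_graph(n)
    elif kind == "star":
        (n,) = size
        if n < 1:
            raise ValueError("star needs n >= 1")
        g = nx.star_graph(n - 1)
    elif kind == "ring":
        (n,) = size
        if n < 3:
            raise ValueError("ring needs n >= 3")
        g = nx.cycle_graph(n)
    elif kind == "lattice2d_periodic":
        r, c = size
        if r < 3 or c < 3:
            raise ValueError("periodic lattice needs rows, cols >= 3 "
                             "(smaller tori create duplicate edges)")
        g = nx.grid_2d_graph(r, c, periodic=True)
        g = nx.relabel_nodes(g, {(i, j): i * c + j for i, j in g.nodes()})
    else:
        raise ValueError(f"unknown graph kind {kind!r}")
    n_nodes = g.number_of_nodes()
    return Network(n_nodes, tuple(g.edges()))


def lattice_coords(index: np.ndarray, cols: int) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of the row-major relabeling used by the lattice generator."""
    index = np.asarray(index)
    return index // cols, index % cols
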