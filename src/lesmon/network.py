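"""Interaction-network loading, cleaning and all-pairs hop distances.

The pipeline operates on an undirected, unweighted protein-protein
interaction network.  Before any distance is computed the network is cleaned:
promiscuous hub proteins (degree above a threshold, default 1000) are removed
because they connect mostly unrelated proteins and wash out local clustering
signal, and the largest connected component is extracted so that every
pairwise shortest-path distance is finite.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "read_edge_list",
    "remove_hubs",
    "largest_connected_component",
    "all_pairs_shortest_paths",
    "DistanceMatrix",
    "network_hash",
    "BIOGRID_DEFAULT_COLUMNS",
]

#: Official-symbol columns of the BioGRID tab-2/tab-3 export.
BIOGRID_DEFAULT_COLUMNS = (
    "Official Symbol Interactor A",
    "Official Symbol Interactor B",
)


def read_edge_list(path, fmt="plain", biogrid_columns=BIOGRID_DEFAULT_COLUMNS):
    """Read an undirected network from a two-column edge list.

    Parameters
    ----------
    path : str or Path
        Input file.  For ``fmt="plain"``: whitespace/tab-delimited lines with
        two identifier tokens; lines starting with ``#`` are ignored.  For
        ``fmt="biogrid"``: a tab-delimited BioGRID export with a header row;
        the two interactor-symbol columns are configurable.
    fmt : {"plain", "biogrid"}
    biogrid_columns : pair of str
        Header names of the two interactor columns (BioGRID dialect only).

    Returns
    -------
    networkx.Graph
        Directionality discarded, duplicate pairs collapsed, self-loops
        dropped.

    Raises
    ------
    ValueError
        On an empty file or a malformed line (reported with its line number).
    """
    if fmt not in ("plain", "biogrid"):
        raise ValueError(f"unknown edge-list format: {fmt!r}")
    net = nx.Graph()
    n_data_lines = 0
    with open(path, "rt", encoding="utf-8") as fh:
        if fmt == "biogrid":
            reader = csv.reader(fh, delimiter="\t")
            try:
                header = next(reader)
            except StopIteration:
                raise ValueError(f"{path}: empty file") from None
            try:
                ia = header.index(biogrid_columns[0])
                ib = header.index(biogrid_columns[1])
            except ValueError:
                raise ValueError(
                    f"{path}: header lacks columns {biogrid_columns!r}"
                ) from None
            for lineno, row in enumerate(reader, start=2):
                if not row or (len(row) == 1 and not row[0].strip()):
                    continue
                if len(row) <= max(ia, ib):
                    raise ValueError(f"{path}:{lineno}: malformed line (too few columns)")
                u, v = row[ia].strip(), row[ib].strip()
                if not u or not v:
                    raise ValueError(f"{path}:{lineno}: empty interactor symbol")
                n_data_lines += 1
                _add_edge(net, u, v)
        else:
            for lineno, line in enumerate(fh, start=1):
                stripped = line.strip()
                if not stripped or stripped.startswith("#"):
                    continue
                tokens = stripped.split()
                if len(tokens) != 2:
                    raise ValueError(
                        f"{path}:{lineno}: expected two identifier tokens, "
                        f"got {len(tokens)}"
                    )
                n_data_lines += 1
                _add_edge(net, *tokens)
    if n_data_lines == 0:
        raise ValueError(f"{path}: empty file (no data lines)")
    return net


def _add_edge(net, u, v):
    net.add_node(u)
    net.add_node(v)
    if u != v:  # drop self-loops
        net.add_edge(u, v)


def remove_hubs(net, max_degree=1000):
    """Remove every node with degree strictly greater than ``max_degree``.

    Degrees are measured on the input network; removal is simultaneous, so a
    node is judged by its original degree even if removing another hub would
    have lowered it.
    """
    if max_degree < 1:
        raise ValueError("max_degree must be >= 1")
    hubs = [n for n, d in net.degree() if d > max_degree]
    out = net.copy()
    out.remove_nodes_from(hubs)
    return out


def largest_connected_component(net):
    """Induced subgraph on the largest connected component.

    Ties in component size are broken by taking the component whose
    lexicographically smallest member is smallest, so the result is
    deterministic.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("cannot take the largest component of an empty network")
    best = max(nx.connected_components(net), key=lambda c: (len(c), _neg_min(c)))
    return net.subgraph(best).copy()


class _neg_min:
    """Orders components so that a smaller minimum identifier ranks higher."""

    def __init__(self, component):
        self.key = min(component)

    def __lt__(self, other):
        return self.key > other.key


@dataclass(frozen=True)
class DistanceMatrix:
    """All-pairs shortest-path hop distances with an explicit node ordering.

    ``matrix[i, j]`` is the hop distance between ``nodes[i]`` and
    ``nodes[j]``; stored as a dense symmetric ``int16`` array (hop distances
    in PPI-scale networks are tiny).
    """

    nodes: tuple
    matrix: np.ndarray
    _index: dict = field(repr=False, compare=False, default=None)

    def __post_init__(self):
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(self.nodes)})

    @property
    def n(self):
        return len(self.nodes)

    def index_of(self, node):
        try:
            return self._index[node]
        except KeyError:
            raise KeyError(f"node {node!r} is not in the distance matrix") from None

    def distance(self, u, v):
        return int(self.matrix[self.index_of(u), self.index_of(v)])

    def indices(self, members):
        """Matrix row indices for an iterable of node identifiers (sorted
        by identifier for determinism)."""
        return np.array([self.index_of(m) for m in sorted(members)], dtype=np.intp)

    def to_tsv(self, path):
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write("\t".join(self.nodes) + "\n")
            np.savetxt(fh, self.matrix, fmt="%d", delimiter="\t")

    @classmethod
    def from_tsv(cls, path):
        with open(path, "rt", encoding="utf-8") as fh:
            nodes = tuple(fh.readline().rstrip("\n").split("\t"))
            matrix = np.loadtxt(fh, dtype=np.int16, delimiter="\t")
        return cls(nodes=nodes, matrix=matrix)


def all_pairs_shortest_paths(net):
    """Hop-count distance matrix for a connected network.

    Uses repeated breadth-first search (via :func:`scipy.sparse.csgraph.
    shortest_path` with unit weights), which yields distances identical to
    Floyd-Warshall on unweighted graphs but runs much faster on sparse ones.

    Raises
    ------
    ValueError
        If the network is disconnected (extract the largest connected
        component first).
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    nodes = tuple(sorted(net.nodes))
    adj = nx.to_scipy_sparse_array(net, nodelist=list(nodes), weight=None, format="csr")
    dist = shortest_path(adj, method="D", directed=False, unweighted=True)
    if np.isinf(dist).any():
        raise ValueError(
            "network is disconnected; run largest_connected_component first"
        )
    return DistanceMatrix(nodes=nodes, matrix=dist.astype(np.int16))


def network_hash(net):
    """Stable hex digest of the node and edge sets (for cache keying)."""
    h = hashlib.sha256()
    for n in sorted(net.nodes):
        h.update(n.encode())
        h.update(b"\x00")
    h.update(b"\x01")
    for u, v in sorted(tuple(sorted(e)) for e in net.edges):
        h.update(f"{u}\x00{v}".encode())
        h.update(b"\x01")
    return h.hexdigest()
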