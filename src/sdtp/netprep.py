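"""Preparation of tissue-specific weighted gene networks.

A drug that treats several diseases can be associated with one weighted
protein--protein interaction network per disease-relevant tissue.  This
module reads such networks from plain edge-list files (the "top edges"
three-column dialect: gene, gene, weight), rescales their confidence
weights onto a common range, thins them to their strongest edges, and
stacks the layers over their shared genes into a dense third-order
weight tensor ``a[i, j, k]`` (gene i, gene j, layer k) that the module
miner consumes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "WeightedNetwork",
    "MultilayerTensor",
    "read_edge_list",
    "write_edge_list",
    "normalize_weights",
    "select_top_edges",
    "build_tensor",
    "degree_distribution",
]


class EdgeListParseError(ValueError):
    """Raised when an edge-list file cannot be parsed."""


def _pair(u: str, v: str) -> tuple[str, str]:
    """Canonical unordered gene pair (lexicographically sorted)."""
    return (u, v) if u <= v else (v, u)


class WeightedNetwork:
    """Undirected weighted gene network: one tissue layer.

    Nodes are gene identifiers (strings; Entrez-style numeric strings in
    the packaged fixtures).  Edge weights are strictly positive reals and
    self-loops are forbidden.  Backed by a :class:`networkx.Graph`.
    """

    def __init__(self, name: str | None = None) -> None:
        self._g = nx.Graph()
        self.name = name

    # -- construction -------------------------------------------------

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str, float]], name: str | None = None
    ) -> "WeightedNetwork":
        """Build a network, collapsing duplicate unordered pairs to the
        maximum weight and dropping self-loops with a warning."""
        net = cls(name=name)
        for u, v, w in edges:
            net._add(str(u), str(v), float(w))
        return net

    def _add(self, u: str, v: str, w: float) -> None:
        if not math.isfinite(w) or w <= 0:
            raise ValueError(f"edge ({u}, {v}) has non-positive weight {w!r}")
        if u == v:
            logger.warning("dropping self-loop on gene %s", u)
            return
        prev = self._g.get_edge_data(u, v)
        if prev is None or prev["weight"] < w:
            self._g.add_edge(u, v, weight=w)

    # -- views --------------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def edges(self) -> Iterator[tuple[str, str, float]]:
        """Iterate (u, v, weight) with u < v, in sorted pair order."""
        for u, v in sorted(_pair(a, b) for a, b in self._g.edges):
            yield u, v, self._g[u][v]["weight"]

    def weight(self, u: str, v: str, default: float = 0.0) -> float:
        data = self._g.get_edge_data(u, v)
        return default if data is None else data["weight"]

    def has_node(self, u: str) -> bool:
        return u in self._g

    def degree(self, u: str) -> int:
        return self._g.degree[u]

    def neighbors(self, u: str) -> set[str]:
        return set(self._g.neighbors(u))

    def to_networkx(self) -> nx.Graph:
        return self._g.copy()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WeightedNetwork):
            return NotImplemented
        return self.nodes == other.nodes and list(self.edges()) == list(other.edges())

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        label = self.name or "unnamed"
        return f"<WeightedNetwork {label}: {self.n_nodes} nodes, {self.n_edges} edges>"


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_edge_list(path: str | Path, name: str | None = None) -> WeightedNetwork:
    """Read a three-column weighted edge list (gene, gene, weight).

    Whitespace- or tab-delimited.  An optional single header line is
    auto-detected by a non-numeric third field.  Duplicate unordered
    pairs keep the maximum weight; self-loops are dropped with a logged
    warning.  Malformed lines raise :class:`EdgeListParseError` naming
    the line number; a file with no data lines is an error.
    """
    path = Path(path)
    net = WeightedNetwork(name=name if name is not None else path.stem)
    n_data = 0
    first_seen = False
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split()
            if not first_seen:
                first_seen = True
                if len(parts) >= 3 and not _is_number(parts[2]):
                    continue  # header line
            if len(parts) != 3:
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected 3 fields, got {len(parts)}"
                )
            u, v, wtok = parts
            try:
                w = float(wtok)
            except ValueError:
                raise EdgeListParseError(
                    f"{path}:{lineno}: unparseable weight {wtok!r}"
                ) from None
            if not math.isfinite(w) or w <= 0:
                raise EdgeListParseError(
                    f"{path}:{lineno}: weight must be a positive finite number, got {w!r}"
                )
            n_data += 1
            if u == v:
                logger.warning("%s:%d: dropping self-loop on gene %s", path, lineno, u)
                continue
            net._add(u, v, w)
    if n_data == 0:
        raise EdgeListParseError(f"{path}: no edges found")
    return net


def write_edge_list(net: WeightedNetwork, path: str | Path) -> None:
    """Write the canonical three-column form (sorted pairs, ``repr``
    weights, so read/write round-trips bit-exactly)."""
    path = Path(path)
    with path.open("w") as fh:
        for u, v, w in net.edges():
            fh.write(f"{u}\t{v}\t{w!r}\n")


def normalize_weights(
    net: WeightedNetwork, target_min: float = 0.1, target_max: float = 1.0
) -> WeightedNetwork:
    """Affinely rescale edge weights onto [target_min, target_max].

    The minimum observed weight maps exactly to ``target_min`` and the
    maximum exactly to ``target_max``; topology is unchanged.  All-equal
    weights are an error (the map is undefined), as is a degenerate
    target range.
    """
    if target_min >= target_max:
        raise ValueError(
            f"target_min ({target_min}) must be < target_max ({target_max})"
        )
    weights = [w for _, _, w in net.edges()]
    if not weights:
        raise ValueError("cannot normalize an empty network")
    lo, hi = min(weights), max(weights)
    if lo == hi:
        raise ValueError("all edge weights are equal; normalization is undefined")
    span = hi - lo
    scale = target_max - target_min
    out = WeightedNetwork(name=net.name)
    for u, v, w in net.edges():
        out._add(u, v, scale * (w - lo) / span + target_min)
    return out


def select_top_edges(net: WeightedNetwork, fraction: float) -> WeightedNetwork:
    """Keep the ``ceil(fraction * |E|)`` highest-weight edges.

    Ties at the cutoff are broken by lexicographic order of the sorted
    gene-id pair, so the result is deterministic.  Nodes left without
    any retained edge are dropped.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    edges = list(net.edges())
    if not edges:
        raise ValueError("cannot select top edges of an empty network")
    k = math.ceil(fraction * len(edges))
    ranked = sorted(edges, key=lambda e: (-e[2], (e[0], e[1])))
    return WeightedNetwork.from_edges(ranked[:k], name=net.name)


@dataclass
class MultilayerTensor:
    """Symmetric third-order weight array over shared genes x layers.

    ``weights[i, j, k]`` is the weight of the edge between genes
    ``gene_index[i]`` and ``gene_index[j]`` in layer ``layer_index[k]``;
    missing edges are 0, the diagonal is 0, and every layer slice is
    symmetric.
    """

    gene_index: list[str]
    layer_index: list[str]
    weights: np.ndarray
    _gene_pos: dict[str, int] = field(init=False, repr=False)
    _layer_pos: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        n, m = len(self.gene_index), len(self.layer_index)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (n, n, m):
            raise ValueError(
                f"weights shape {self.weights.shape} != ({n}, {n}, {m})"
            )
        self._gene_pos = {g: i for i, g in enumerate(self.gene_index)}
        self._layer_pos = {l: k for k, l in enumerate(self.layer_index)}
        if len(self._gene_pos) != n:
            raise ValueError("duplicate gene identifiers in gene_index")
        if len(self._layer_pos) != m:
            raise ValueError("duplicate layer names in layer_index")

    @property
    def n_genes(self) -> int:
        return len(self.gene_index)

    @property
    def n_layers(self) -> int:
        return len(self.layer_index)

    def gene_positions(self, genes: Iterable[str]) -> np.ndarray:
        try:
            return np.array(sorted(self._gene_pos[g] for g in genes), dtype=int)
        except KeyError as exc:
            raise ValueError(f"unknown gene {exc.args[0]!r}") from None

    def layer_positions(self, layers: Iterable[str]) -> np.ndarray:
        try:
            return np.array(sorted(self._layer_pos[l] for l in layers), dtype=int)
        except KeyError as exc:
            raise ValueError(f"unknown layer {exc.args[0]!r}") from None

    def layer_matrix(self, layer: str) -> np.ndarray:
        return self.weights[:, :, self._layer_pos[layer]]

    def layer_network(self, layer: str) -> WeightedNetwork:
        """Extract one layer back into a :class:`WeightedNetwork`
        (zero-weight entries omitted)."""
        mat = self.layer_matrix(layer)
        net = WeightedNetwork(name=layer)
        ii, jj = np.nonzero(np.triu(mat, k=1))
        for i, j in zip(ii.tolist(), jj.tolist()):
            net._add(self.gene_index[i], self.gene_index[j], float(mat[i, j]))
        return net

    def validate(self) -> None:
        """Assert symmetry and zero diagonal on every layer."""
        for k in range(self.n_layers):
            mat = self.weights[:, :, k]
            if not np.array_equal(mat, mat.T):
                raise ValueError(f"layer {self.layer_index[k]!r} is not symmetric")
            if np.any(np.diagonal(mat) != 0):
                raise ValueError(f"layer {self.layer_index[k]!r} has a nonzero diagonal")

    def copy(self) -> "MultilayerTensor":
        return MultilayerTensor(
            list(self.gene_index), list(self.layer_index), self.weights.copy()
        )

    # -- sparse directory round-trip ----------------------------------

    def to_directory(self, path: str | Path) -> None:
        """Write gene index, layer index, and one edge list per layer."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        (path / "gene_index.txt").write_text(
            "".join(f"{g}\n" for g in self.gene_index)
        )
        (path / "layer_index.txt").write_text(
            "".join(f"{l}\n" for l in self.layer_index)
        )
        for k, layer in enumerate(self.layer_index):
            mat = self.weights[:, :, k]
            ii, jj = np.nonzero(np.triu(mat, k=1))
            with (path / f"layer_{k}.tsv").open("w") as fh:
                for i, j in zip(ii.tolist(), jj.tolist()):
                    fh.write(
                        f"{self.gene_index[i]}\t{self.gene_index[j]}\t{float(mat[i, j])!r}\n"
                    )

    @classmethod
    def from_directory(cls, path: str | Path) -> "MultilayerTensor":
        path = Path(path)
        gene_index = (path / "gene_index.txt").read_text().split()
        layer_index = (path / "layer_index.txt").read_text().split()
        n, m = len(gene_index), len(layer_index)
        pos = {g: i for i, g in enumerate(gene_index)}
        weights = np.zeros((n, n, m))
        for k in range(m):
            for line in (path / f"layer_{k}.tsv").read_text().splitlines():
                u, v, w = line.split("\t")
                i, j = pos[u], pos[v]
                weights[i, j, k] = weights[j, i, k] = float(w)
        return cls(gene_index, layer_index, weights)


def build_tensor(
    nets: Sequence[WeightedNetwork], layer_names: Sequence[str] | None = None
) -> MultilayerTensor:
    """Stack networks over their common genes into a multilayer tensor.

    The gene index is the sorted intersection of the node sets; each
    layer's weights are restricted to common genes, missing edges become
    0.  At least two networks are required and the intersection must be
    non-empty.
    """
    if len(nets) < 2:
        raise ValueError("need at least 2 networks to build a multilayer tensor")
    if layer_names is None:
        layer_names = [net.name or f"layer{k}" for k, net in enumerate(nets)]
    if len(layer_names) != len(nets):
        raise ValueError("layer_names length must match the number of networks")
    common = set.intersection(*(net.nodes for net in nets))
    if not common:
        raise ValueError("networks share no genes; the common-node set is empty")
    gene_index = sorted(common)
    pos = {g: i for i, g in enumerate(gene_index)}
    n, m = len(gene_index), len(nets)
    weights = np.zeros((n, n, m))
    for k, net in enumerate(nets):
        for u, v, w in net.edges():
            if u in pos and v in pos:
                i, j = pos[u], pos[v]
                weights[i, j, k] = weights[j, i, k] = w
    return MultilayerTensor(gene_index, list(layer_names), weights)


def degree_distribution(
    net: WeightedNetwork, bin_edges: Sequence[int]
) -> np.ndarray:
    """Histogram of node degrees over the given bin edges.

    Uses :func:`numpy.histogram` semantics (last bin closed on the
    right).  The bins must cover every observed degree so that the
    counts sum to the number of nodes.
    """
    degrees = [net.degree(u) for u in net.nodes]
    counts, _ = np.histogram(degrees, bins=np.asarray(bin_edges))
    if counts.sum() != len(degrees):
        raise ValueError("bin_edges do not cover all observed degrees")
    return counts
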