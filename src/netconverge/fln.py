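"""Weighted functional linkage network (FLN): container, I/O, and transition kernel.

A functional linkage network is an undirected weighted gene graph whose edge
weights encode the likelihood that two genes participate in a common
biological process.  It is the substrate for network propagation: a random
walker steps from a gene to one of its neighbors with probability
proportional to edge weight, which is what :func:`normalize_transition`
encodes as a column-stochastic matrix.

The on-disk dialect is a tab-separated edge table with a mandatory header
``gene_a  gene_b  weight``.  Cytoscape SIF files are accepted read-only as a
secondary dialect (edges get weight 1.0).  Gene identifiers are opaque
case-sensitive strings; no symbol/ID mapping is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

EDGE_COLUMNS = ("gene_a", "gene_b", "weight")


class EdgeTableError(ValueError):
    """Raised when an edge table cannot be parsed or validated."""


class FunctionalLinkageNetwork:
    """Undirected weighted gene graph.

    Wraps a :class:`networkx.Graph`.  Invariants enforced on construction and
    mutation: no self-loops, all edge weights strictly positive, at most one
    edge per unordered gene pair (networkx guarantees the latter).  Isolated
    genes are permitted.
    """

    def __init__(self, graph: nx.Graph | None = None):
        g = graph if graph is not None else nx.Graph()
        for a, b, data in g.edges(data=True):
            if a == b:
                raise ValueError(f"self-loop on gene {a!r} not permitted")
            w = data.get("weight")
            if w is None or not np.isfinite(w) or w <= 0:
                raise ValueError(f"edge ({a!r}, {b!r}) has invalid weight {w!r}")
        self._g = g

    # -- basic accessors -------------------------------------------------

    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def genes(self) -> list[str]:
        """Node identifiers in deterministic (sorted) order."""
        return sorted(self._g.nodes)

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def __contains__(self, gene: str) -> bool:
        return gene in self._g

    def __len__(self) -> int:
        return self.n_nodes

    def weight(self, a: str, b: str) -> float:
        return float(self._g[a][b]["weight"])

    def weighted_degree(self, gene: str) -> float:
        return float(self._g.degree(gene, weight="weight"))

    # -- construction ----------------------------------------------------

    def add_gene(self, gene: str) -> None:
        self._g.add_node(gene)

    def add_edge(self, a: str, b: str, weight: float) -> None:
        """Add an edge; a duplicate pair keeps the maximum weight."""
        if a == b:
            raise ValueError(f"self-loop on gene {a!r} not permitted")
        if not np.isfinite(weight) or weight <= 0:
            raise ValueError(f"edge ({a!r}, {b!r}) has non-positive weight {weight!r}")
        if self._g.has_edge(a, b):
            weight = max(weight, self._g[a][b]["weight"])
        self._g.add_edge(a, b, weight=float(weight))

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, float]],
        extra_genes: Iterable[str] = (),
    ) -> "FunctionalLinkageNetwork":
        net = cls()
        for a, b, w in edges:
            net.add_edge(a, b, w)
        for g in extra_genes:
            net.add_gene(g)
        return net

    # -- queries ---------------------------------------------------------

    def neighbors(self, genes: Iterable[str]) -> set[str]:
        """Genes at topological distance exactly 1 from the query set.

        The union of neighbors of every query gene, with query genes
        themselves excluded.  Query genes absent from the network are
        ignored (logged).
        """
        genes = set(genes)
        unknown = genes - self.nodes
        if unknown:
            logger.info("neighbors: %d query gene(s) not in network: %s",
                        len(unknown), sorted(unknown)[:10])
        out: set[str] = set()
        for g in genes & self.nodes:
            out.update(self._g.neighbors(g))
        return out - genes

    def induce_subnetwork(
        self, genes: Iterable[str], include_first_neighbors: bool = False
    ) -> "FunctionalLinkageNetwork":
        """Subgraph induced on ``genes`` (optionally plus first neighbors)."""
        genes = set(genes) & self.nodes
        if include_first_neighbors:
            genes = genes | self.neighbors(genes)
        return FunctionalLinkageNetwork(self._g.subgraph(genes).copy())

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_edge_table(cls, path: str | Path) -> "FunctionalLinkageNetwork":
        """Load a network from a TSV edge table (or SIF if suffix ``.sif``)."""
        path = Path(path)
        if path.suffix.lower() == ".sif":
            return cls._from_sif(path)
        try:
            df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str},
                             float_precision="round_trip")
        except pd.errors.EmptyDataError as exc:
            raise EdgeTableError(f"{path}: empty file without header") from exc
        missing = [c for c in EDGE_COLUMNS if c not in df.columns]
        if missing:
            raise EdgeTableError(f"{path}: missing column(s) {missing}; header "
                                 f"must contain {EDGE_COLUMNS}")
        weights = pd.to_numeric(df["weight"], errors="coerce")
        bad = df.index[weights.isna() | df["gene_a"].isna() | df["gene_b"].isna()]
        if len(bad):
            # +2: one for the header row, one for 1-based line numbers
            raise EdgeTableError(f"{path}: malformed row at line {bad[0] + 2}")
        nonpos = df.index[weights <= 0]
        if len(nonpos):
            raise EdgeTableError(
                f"{path}: non-positive weight {weights[nonpos[0]]} at line {nonpos[0] + 2}")

        net = cls()
        self_loops = 0
        for a, b, w in zip(df["gene_a"], df["gene_b"], weights):
            if a == b:
                self_loops += 1
                net.add_gene(a)
                continue
            net.add_edge(str(a), str(b), float(w))
        if self_loops:
            logger.warning("%s: dropped %d self-loop row(s)", path, self_loops)
        logger.info("%s: loaded %d genes, %d edges", path, net.n_nodes, net.n_edges)
        return net

    @classmethod
    def _from_sif(cls, path: Path) -> "FunctionalLinkageNetwork":
        """Cytoscape SIF, read-only; unweighted edges get weight 1.0."""
        net = cls()
        for line in Path(path).read_text().splitlines():
            fields = line.split()
            if not fields:
                continue
            if len(fields) == 1:
                net.add_gene(fields[0])
                continue
            source, _relation, *targets = fields
            for t in targets:
                if t == source:
                    logger.warning("%s: dropped self-loop on %s", path, source)
                    continue
                net.add_edge(source, t, 1.0)
        return net

    def to_edge_table(self, path: str | Path) -> None:
        """Write the network as a TSV edge table (deterministic row order)."""
        rows = sorted(
            (min(a, b), max(a, b), self._g[a][b]["weight"])
            for a, b in self._g.edges
        )
        df = pd.DataFrame(rows, columns=list(EDGE_COLUMNS))
        # %.17g round-trips IEEE doubles exactly
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")


# -- gene lists -----------------------------------------------------------

def read_gene_list(path: str | Path) -> list[str]:
    """Read a gene list: one identifier per line, ``#`` comments ignored.

    Order is preserved and duplicates are removed (first occurrence wins).
    """
    genes: list[str] = []
    seen: set[str] = set()
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if line and line not in seen:
            genes.append(line)
            seen.add(line)
    return genes


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


# -- transition operator --------------------------------------------------

@dataclass
class TransitionModel:
    """Column-stochastic step kernel of a weighted network.

    ``matrix[i, j]`` is the probability that a walker at gene ``j`` (column)
    steps to gene ``i`` (row): the weight of edge (i, j) divided by j's
    weighted degree.  Columns of isolated (dangling) genes are all zero and
    flagged in ``dangling``; the walk handles them by teleporting to the
    restart distribution.
    """

    nodes: list[str]
    matrix: sp.csr_matrix
    dangling: np.ndarray  # boolean mask aligned with ``nodes``
    index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index:
            self.index = {g: i for i, g in enumerate(self.nodes)}

    @property
    def n(self) -> int:
        return len(self.nodes)


def normalize_transition(network: FunctionalLinkageNetwork) -> TransitionModel:
    """Build the weight-proportional step kernel of ``network``.

    Each non-isolated column sums to 1 within 1e-12: a walker at gene j
    chooses an incident edge with probability proportional to its weight
    ("randomly immediate neighboring node" kinetics with weights as
    propensities).
    """
    if network.n_nodes == 0:
        raise ValueError("cannot normalize an empty network")
    nodes = network.genes
    adj = nx.to_scipy_sparse_array(network.graph, nodelist=nodes, weight="weight",
                                   format="csc")
    wdeg = np.asarray(adj.sum(axis=0)).ravel()
    dangling = wdeg == 0
    if dangling.any():
        logger.info("normalize_transition: %d dangling (isolated) gene(s)",
                    int(dangling.sum()))
    inv = np.zeros_like(wdeg)
    inv[~dangling] = 1.0 / wdeg[~dangling]
    W = (adj @ sp.diags(inv)).tocsr()
    return TransitionModel(nodes=nodes, matrix=W, dangling=dangling)
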