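"""Reading, cleaning and writing interaction networks and gene-set files.

The canonical in-memory network is a :class:`networkx.Graph` of opaque
string identifiers: undirected, unweighted, no self-loops, no parallel
edges. All downstream feature and classification stages consume this
object. Gene-set membership (with optional pathway annotation) travels as
a :class:`GeneSetAnnotation`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

logger = logging.getLogger(__name__)

# tokens that mark a header line in edge files when header="auto"
_HEADER_TOKENS = {
    "source", "target", "node1", "node2", "protein1", "protein2",
    "interactor_a", "interactor_b", "from", "to", "gene1", "gene2",
    "id1", "id2",
}


@dataclass
class GeneSetAnnotation:
    """Positive-set membership restricted to a network, plus pathway labels.

    Attributes
    ----------
    positives : frozenset of str
        Listed genes that are present in the network. This intersection is
        what every downstream stage uses.
    pathways : dict of str -> frozenset of str
        Optional pathway name -> member identifiers. Members are subsets of
        ``positives``; a gene may belong to several pathways.
    unmapped : frozenset of str
        Listed genes absent from the network.
    """

    positives: frozenset
    pathways: dict = field(default_factory=dict)
    unmapped: frozenset = frozenset()

    def __post_init__(self):
        self.positives = frozenset(self.positives)
        self.unmapped = frozenset(self.unmapped)
        self.pathways = {name: frozenset(members) & self.positives
                         for name, members in self.pathways.items()}
        if self.positives & self.unmapped:
            raise ValueError("positives and unmapped must be disjoint")


class EdgeListParseError(ValueError):
    """Raised for malformed edge-list or gene-set lines."""


def _is_header(tokens) -> bool:
    return any(t.lower() in _HEADER_TOKENS for t in tokens[:2])


def load_edge_list(path, dialect: str = "tsv2col", header="auto",
                   node_list=None) -> nx.Graph:
    """Read an edge list into a cleaned simple undirected graph.

    Self-loops are dropped and duplicate edges (in either orientation)
    are collapsed; counts of both are logged. Cleaning is idempotent:
    re-reading a written cleaned network reproduces it exactly.

    Parameters
    ----------
    path : path-like
        Edge file. ``tsv2col``: two whitespace/tab-separated identifier
        columns (extra columns ignored with a warning). ``sif``: Simple
        Interaction Format — ``node relation node [node ...]``; a line
        with a single token declares an isolated node.
    dialect : {"tsv2col", "sif"}
    header : {"auto", True, False}
        Whether the first line is a header. ``"auto"`` skips it when its
        first two tokens look like column names rather than identifiers.
    node_list : path-like, optional
        Plain list of identifiers to add as nodes (allows isolates, which
        an edge list cannot express).

    Returns
    -------
    networkx.Graph
    """
    if dialect not in ("tsv2col", "sif"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    path = Path(path)
    graph = nx.Graph()
    n_self, n_dup, n_extra_cols = 0, 0, 0

    with open(path) as fh:
        lines = fh.readlines()
    data = [(i + 1, ln.strip()) for i, ln in enumerate(lines) if ln.strip()]
    if not data:
        raise EdgeListParseError(f"{path}: empty edge file")

    start = 0
    first_tokens = data[0][1].split()
    if header is True or (header == "auto" and _is_header(first_tokens)):
        start = 1
        if not data[1:]:
            raise EdgeListParseError(f"{path}: no data lines after header")

    for lineno, line in data[start:]:
        tokens = [t.strip() for t in line.split()]
        if dialect == "tsv2col":
            if len(tokens) < 2:
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected 2 identifier columns, "
                    f"got {len(tokens)}")
            if len(tokens) > 2:
                n_extra_cols += 1
            pairs = [(tokens[0], tokens[1])]
        else:  # sif
            if len(tokens) == 1:
                graph.add_node(tokens[0])
                continue
            if len(tokens) == 2:
                raise EdgeListParseError(
                    f"{path}:{lineno}: SIF line needs node, relation, "
                    "node(s)")
            pairs = [(tokens[0], t) for t in tokens[2:]]
        for a, b in pairs:
            if a == b:
                n_self += 1
                graph.add_node(a)
            elif graph.has_edge(a, b):
                n_dup += 1
            else:
                graph.add_edge(a, b)

    if node_list is not None:
        for ident in _read_id_lines(node_list):
            graph.add_node(ident)

    if n_extra_cols:
        logger.warning("%s: ignored extra columns on %d lines", path,
                       n_extra_cols)
    logger.info("%s: %d nodes, %d edges (dropped %d self-loops, "
                "%d duplicate edges)", path, graph.number_of_nodes(),
                graph.number_of_edges(), n_self, n_dup)
    return graph


def write_edge_list(graph: nx.Graph, path) -> None:
    """Write a cleaned network as a bit-stable two-column TSV.

    Endpoints are lexicographically ordered within a line and lines are
    sorted, so equal graphs always serialize to identical bytes.
    """
    rows = sorted(tuple(sorted(e)) for e in graph.edges())
    with open(path, "w") as fh:
        for a, b in rows:
            fh.write(f"{a}\t{b}\n")


def _read_id_lines(path):
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip()]


def load_gene_set(path, network: nx.Graph,
                  pathway_map=None) -> GeneSetAnnotation:
    """Read a positive gene list (one identifier per line) and restrict it
    to the network.

    Parameters
    ----------
    path : path-like
        Gene list, one identifier per line.
    network : networkx.Graph
    pathway_map : path-like, optional
        Two-column TSV ``identifier<TAB>pathway``; a gene may map to
        several pathways. Memberships are restricted to mapped positives.

    Raises
    ------
    ValueError
        If no listed gene is present in the network — there would be
        nothing to characterize.
    """
    listed = set(_read_id_lines(path))
    nodes = set(network.nodes)
    positives = listed & nodes
    unmapped = listed - nodes
    if not positives:
        raise ValueError(
            f"{path}: none of the {len(listed)} listed genes are in the "
            "network")
    pathways: dict = {}
    if pathway_map is not None:
        with open(pathway_map) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line:
                    continue
                tokens = line.split("\t") if "\t" in line else line.split()
                if len(tokens) != 2:
                    raise EdgeListParseError(
                        f"{pathway_map}:{lineno}: expected 2 columns")
                ident, pw = tokens[0].strip(), tokens[1].strip()
                pathways.setdefault(pw, set()).add(ident)
    logger.info("gene set: %d listed, %d in network, %d unmapped",
                len(listed), len(positives), len(unmapped))
    return GeneSetAnnotation(positives=positives, pathways=pathways,
                             unmapped=unmapped)


def count_negatives(network: nx.Graph, annotation: GeneSetAnnotation) -> int:
    """Number of network nodes outside the positive set.

    Everything not in the positive set is treated as a negative sample,
    so this is simply ``|nodes| - |positives ∩ nodes|``.
    """
    return network.number_of_nodes() - len(
        annotation.positives & set(network.nodes))


def write_gene_set(annotation: GeneSetAnnotation, path,
                   pathway_path=None) -> None:
    """Write positives (one per line, sorted) and optionally the pathway map."""
    with open(path, "w") as fh:
        for ident in sorted(annotation.positives | annotation.unmapped):
            fh.write(ident + "\n")
    if pathway_path is not None:
        with open(pathway_path, "w") as fh:
            for pw in sorted(annotation.pathways):
                for ident in sorted(annotation.pathways[pw]):
                    fh.write(f"{ident}\t{pw}\n")
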