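"""Per-node topological features: degree, k-core number, and the
seed-neighbor ratio (RNR).

Degree counts direct interaction partners. The core number of a node is
the largest K such that the node survives recursively removing all nodes
of degree < K; high core number marks the global network center, as
opposed to local hubs with high degree but low coreness. RNR is the
fraction of a node's direct neighbors that belong to a seed (positive)
set — the guilt-by-association signal. RNR is the only label-dependent
feature; degree and coreness never see labels.
"""

from __future__ import annotations

import logging

import networkx as nx
import pandas as pd

from .io import GeneSetAnnotation

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = ["degree", "k_core", "rnr"]
TABLE_COLUMNS = ["id", "degree", "k_core", "rnr", "label"]


def compute_degrees(network: nx.Graph) -> dict:
    """Map each node to its number of direct neighbors."""
    return dict(network.degree())


def kcore_decomposition(network: nx.Graph) -> dict:
    """Map each node to its core number.

    The core number is the largest K for which the node remains after
    iteratively deleting every node of degree < K until all remaining
    degrees are >= K. Computed by the standard O(|E|) peeling algorithm.
    """
    return nx.core_number(network)


def compute_rnr(network: nx.Graph, positives) -> dict:
    """Seed-neighbor ratio: positive direct neighbors / degree.

    A node's own label never enters its numerator or denominator — only
    neighbors count (self-loops are already excluded from cleaned
    networks). Degree-0 nodes get RNR = 0 by convention so the feature is
    total over the network.

    Raises
    ------
    ValueError
        If ``positives`` contains identifiers absent from the network;
        the caller must intersect with the node set first.
    """
    positives = set(positives)
    missing = positives - set(network.nodes)
    if missing:
        raise ValueError(
            f"{len(missing)} positive identifiers are not network nodes "
            f"(e.g. {sorted(missing)[:3]}); intersect with the node set "
            "first")
    rnr = {}
    n_isolated = 0
    for node in network.nodes:
        deg = network.degree(node)
        if deg == 0:
            rnr[node] = 0.0
            n_isolated += 1
        else:
            pos_neighbors = sum(1 for nb in network.neighbors(node)
                                if nb in positives)
            rnr[node] = pos_neighbors / deg
    if n_isolated:
        logger.info("RNR set to 0 for %d degree-0 nodes", n_isolated)
    return rnr


def build_feature_table(network: nx.Graph,
                        annotation: GeneSetAnnotation) -> pd.DataFrame:
    """Join degree, core number, RNR and the positive/negative label.

    Returns a DataFrame indexed by node identifier (sorted, so the row
    order is deterministic) with columns ``degree``, ``k_core``, ``rnr``,
    ``label`` and one row per network node.
    """
    positives = annotation.positives & set(network.nodes)
    degrees = compute_degrees(network)
    cores = kcore_decomposition(network)
    rnr = compute_rnr(network, positives)
    ids = sorted(network.nodes)
    table = pd.DataFrame(
        {
            "degree": [degrees[i] for i in ids],
            "k_core": [cores[i] for i in ids],
            "rnr": [rnr[i] for i in ids],
            "label": ["positive" if i in positives else "negative"
                      for i in ids],
        },
        index=pd.Index(ids, name="id"),
    )
    return table


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write the feature table as TSV with RNR printed to 4 decimals."""
    out = table.reset_index()[TABLE_COLUMNS].copy()
    out["rnr"] = out["rnr"].map(lambda v: f"{v:.4f}")
    out.to_csv(path, sep="\t", index=False)


def read_feature_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"id": str})
    return table.set_index("id")
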