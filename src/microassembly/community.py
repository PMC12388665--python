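"""Core-taxa (Venn) identification, bipartite sample–taxon networks and
correlation-based co-occurrence networks with topology summaries."""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ParameterError, ValidationError
from .io_tables import CountTable, TaxonomyMap, aggregate_by_rank, relative_abundance

__all__ = [
    "NetworkSummary",
    "core_taxa",
    "bipartite_network",
    "cooccurrence_network",
]


@dataclass(frozen=True)
class NetworkSummary:
    n_nodes: int
    n_edges: int
    density: float
    mean_degree: float
    degrees: dict


def _summarize(graph: nx.Graph, bipartite_sizes: tuple | None = None) -> NetworkSummary:
    n, e = graph.number_of_nodes(), graph.number_of_edges()
    if bipartite_sizes is not None:
        n1, n2 = bipartite_sizes
        density = e / (n1 * n2) if n1 and n2 else 0.0
    else:
        density = 2 * e / (n * (n - 1)) if n > 1 else 0.0
    degrees = dict(graph.degree())
    mean_degree = 2 * e / n if n else 0.0
    return NetworkSummary(n_nodes=n, n_edges=e, density=density,
                          mean_degree=mean_degree, degrees=degrees)


def core_taxa(tables_by_group: dict, tax: TaxonomyMap | None = None,
              rank: str = "phylum", presence_threshold: float = 0.0):
    """Core taxa shared by all groups and Venn region counts.

    A taxon (optionally aggregated to ``rank`` when a taxonomy is given) is
    "present" in a group when its summed relative abundance across that
    group's samples exceeds ``presence_threshold``.  The core is the
    intersection over all groups; region counts map each non-empty group
    combination to the number of taxa present in exactly those groups.
    """
    if len(tables_by_group) < 2:
        raise InsufficientDataError("need >= 2 groups for core/Venn analysis")
    presence = {}
    for group, table in tables_by_group.items():
        if table.n_samples == 0 or table.n_taxa == 0:
            raise ValidationError(f"group {group!r} has an empty table")
        if tax is not None:
            table = aggregate_by_rank(table, tax, rank)
        rel = relative_abundance(table)
        summed = rel.sum(axis=1)
        presence[group] = set(summed.index[summed > presence_threshold])
    groups = list(presence)
    core = set.intersection(*presence.values())
    universe = set.union(*presence.values())
    regions = {}
    for taxon in universe:
        membership = frozenset(g for g in groups if taxon in presence[g])
        regions[membership] = regions.get(membership, 0) + 1
    region_counts = {tuple(sorted(k)): v for k, v in regions.items()}
    return core, region_counts


def bipartite_network(abundance: pd.DataFrame, edge_threshold: float,
                      criterion=None):
    """Bipartite group–taxon graph.

    ``abundance`` is a groups x taxa matrix.  An edge (group, taxon) exists
    when ``criterion(value, edge_threshold)`` is true; the default criterion
    is value > threshold.  Density uses the bipartite normalization
    edges / (n_groups * n_taxa).  Returns (NetworkSummary, edge DataFrame).
    """
    if (abundance.to_numpy() < 0).any():
        raise ValidationError("abundance matrix must be non-negative")
    if criterion is None:
        criterion = lambda value, threshold: value > threshold
    graph = nx.Graph()
    group_nodes = [("group", g) for g in abundance.index]
    taxon_nodes = [("taxon", t) for t in abundance.columns]
    graph.add_nodes_from(group_nodes, bipartite=0)
    graph.add_nodes_from(taxon_nodes, bipartite=1)
    edges = []
    for g in abundance.index:
        for t in abundance.columns:
            v = abundance.at[g, t]
            if criterion(v, edge_threshold):
                graph.add_edge(("group", g), ("taxon", t))
                edges.append({"group": g, "taxon": t, "value": float(v)})
    summary = _summarize(graph, bipartite_sizes=(len(group_nodes), len(taxon_nodes)))
    return summary, pd.DataFrame(edges, columns=["group", "taxon", "value"])


def cooccurrence_network(table: CountTable, method: str = "spearman",
                         r_min: float = 0.6, p_max: float = 0.05,
                         min_prevalence: int = 3, bh_correct: bool = False):
    """Correlation-based co-occurrence network between taxa.

    Taxa detected in fewer than ``min_prevalence`` samples are excluded;
    correlations are computed on relative abundances across samples, and an
    undirected edge joins two taxa when |r| >= r_min and p <= p_max (t
    approximation; optional Benjamini–Hochberg correction).  Returns
    (NetworkSummary, edge DataFrame).
    """
    if table.n_samples < 5:
        raise InsufficientDataError("co-occurrence network needs >= 5 samples")
    prevalent = (table.counts > 0).sum(axis=1) >= min_prevalence
    taxa = [t for t, k in zip(table.taxon_ids, prevalent) if k]
    if not taxa:
        warnings.warn("all taxa below the prevalence filter: empty network", stacklevel=2)
        return _summarize(nx.Graph()), pd.DataFrame(columns=["taxon_a", "taxon_b", "r", "p"])
    rel = relative_abundance(table).loc[taxa]
    X = rel.to_numpy()
    n = table.n_samples
    if method == "spearman":
        X = np.apply_along_axis(stats.rankdata, 1, X)
    elif method != "pearson":
        raise ParameterError(f"unknown method {method!r}")
    R = np.corrcoef(X)
    iu = np.triu_indices(len(taxa), k=1)
    r = R[iu]
    # t approximation for the correlation p-value
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1 - r**2, 1e-300, None))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    if bh_correct:
        order = np.argsort(p)
        ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        p_adj = np.empty_like(p)
        p_adj[order] = np.minimum(adj, 1.0)
        p = p_adj
    keep = (np.abs(r) >= r_min) & (p <= p_max)
    graph = nx.Graph()
    graph.add_nodes_from(taxa)
    edges = []
    for a, b, rv, pv in zip(iu[0][keep], iu[1][keep], r[keep], p[keep]):
        graph.add_edge(taxa[a], taxa[b], r=float(rv), p=float(pv))
        edges.append({"taxon_a": taxa[a], "taxon_b": taxa[b], "r": float(rv), "p": float(pv)})
    return _summarize(graph), pd.DataFrame(edges, columns=["taxon_a", "taxon_b", "r", "p"])
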