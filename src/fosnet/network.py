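"""Significance-filtered region networks, centralities, hubs, and the
area-resampling bootstrap.

A region network keeps every atlas region as a node and draws an undirected
edge between two regions exactly when their pairwise correlation differs
significantly from zero (two-sided t test, uncorrected, p < alpha; alpha
defaults to 0.05). The correlation is retained as an edge attribute but
plays no role in path finding: shortest paths are combinatorial, on the
unweighted edge set.

Two centralities score each region's influence: degree (raw edge count) and
betweenness (the share of shortest paths between other region pairs passing
through it, Brandes' algorithm via networkx). A region is a hub when it
ranks within the top fraction (default 35%) on *both* centralities; with 20
regions that boundary is the top 7.

Rank stability is assessed with an area-resampling bootstrap: each
replicate deletes one randomly chosen region and duplicates another, then
rebuilds the correlation matrix, the network and both centralities. The
duplicated column is perfectly correlated with its source, so that edge is
always retained (p = 0 by the |r| = 1 convention) and flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .connectivity import CorrelationMatrix, CountTable, edge_significance, pearson_matrix

__all__ = [
    "CentralityRecord",
    "NetworkSummary",
    "BootstrapResult",
    "build_network",
    "degree_centrality",
    "betweenness_centrality",
    "rank_descending",
    "centrality_records",
    "identify_hubs",
    "network_summary",
    "bootstrap_centrality",
    "export_graphml",
    "export_sif",
    "centrality_frame",
]

DUPLICATE_SUFFIX = "+dup"


@dataclass(frozen=True)
class CentralityRecord:
    region: str
    degree: int
    betweenness: float
    degree_rank: int
    betweenness_rank: int
    is_hub: bool


@dataclass(frozen=True)
class NetworkSummary:
    edge_count: int
    density: float
    n_components: int


def build_network(
    corr: CorrelationMatrix,
    alpha: float = 0.05,
    mean_counts: Mapping[str, float] | None = None,
    positive_only: bool = False,
) -> nx.Graph:
    """Filter a correlation matrix into an undirected region network.

    Every region is a node (isolated regions stay in the graph); edge (i, j)
    is included iff the two-sided p of r[i, j] at sample size n is below
    ``alpha``. Undefined (zero-variance) regions contribute no edges.
    ``positive_only`` drops significant negative correlations; by default
    they are kept, since the filter is on the two-sided p.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    g = nx.Graph(alpha=alpha, n=corr.n, group=corr.group)
    for region in corr.regions:
        attrs = {"label": str(region)}
        if mean_counts is not None:
            attrs["mean_count"] = float(mean_counts[region])
        g.add_node(region, **attrs)
    regions = corr.regions
    for i, a in enumerate(regions):
        for b in regions[i + 1 :]:
            rv = corr.r.loc[a, b]
            if np.isnan(rv):
                continue
            if positive_only and rv <= 0:
                continue
            test = edge_significance(float(rv), corr.n, pair=(a, b))
            if test.p < alpha:
                g.add_edge(a, b, r=test.r, p=test.p)
    return g


def degree_centrality(net: nx.Graph) -> dict[str, int]:
    """Raw edge count per region (not normalized)."""
    return {node: int(deg) for node, deg in net.degree()}


def betweenness_centrality(
    net: nx.Graph, normalized: bool = False, weighted: bool = False
) -> dict[str, float]:
    """Brandes betweenness on the unweighted edge set by default.

    ``normalized`` divides by the number of other-node pairs (the Cytoscape
    convention); ``weighted`` uses 1 - |r| as edge length instead of hop
    count. Disconnected pairs contribute nothing; isolated regions score 0.
    """
    weight = None
    if weighted:
        weight = "length"
        for u, v, data in net.edges(data=True):
            data["length"] = 1.0 - abs(data.get("r", 0.0))
    bc = nx.betweenness_centrality(net, normalized=normalized, weight=weight)
    return {node: float(v) for node, v in bc.items()}


def rank_descending(values: Mapping[str, float]) -> dict[str, int]:
    """Competition ranks, largest value first; ties share the best rank."""
    ordered = sorted(values.values(), reverse=True)
    return {k: 1 + ordered.index(v) for k, v in values.items()}


def centrality_records(
    net: nx.Graph, top_fraction: float = 0.35
) -> list[CentralityRecord]:
    """Degree and betweenness with ranks and the dual-centrality hub call."""
    deg = degree_centrality(net)
    btw = betweenness_centrality(net)
    deg_rank = rank_descending(deg)
    btw_rank = rank_descending({k: float(v) for k, v in btw.items()})
    k = hub_cutoff(len(net), top_fraction)
    return [
        CentralityRecord(
            region=node,
            degree=deg[node],
            betweenness=btw[node],
            degree_rank=deg_rank[node],
            betweenness_rank=btw_rank[node],
            is_hub=deg_rank[node] <= k and btw_rank[node] <= k,
        )
        for node in net.nodes
    ]


def hub_cutoff(n_regions: int, top_fraction: float = 0.35) -> int:
    """Number of rank slots within the top fraction: floor(fraction * N)."""
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError(f"top_fraction must be in (0, 1], got {top_fraction}")
    return math.floor(top_fraction * n_regions)


def identify_hubs(
    centralities: Sequence[CentralityRecord], top_fraction: float = 0.35
) -> set[str]:
    """Regions ranked within the top fraction on *both* centralities.

    Ranks are recomputed from the records' values (descending, ties sharing
    the best rank), so tied regions at the boundary are all admitted.
    """
    if not centralities:
        return set()
    deg_rank = rank_descending({c.region: float(c.degree) for c in centralities})
    btw_rank = rank_descending({c.region: c.betweenness for c in centralities})
    k = hub_cutoff(len(centralities), top_fraction)
    return {
        c.region
        for c in centralities
        if deg_rank[c.region] <= k and btw_rank[c.region] <= k
    }


def network_summary(net: nx.Graph) -> NetworkSummary:
    n = net.number_of_nodes()
    e = net.number_of_edges()
    possible = n * (n - 1) / 2
    return NetworkSummary(
        edge_count=e,
        density=e / possible if possible else 0.0,
        n_components=nx.number_connected_components(net),
    )


def centrality_frame(records: Sequence[CentralityRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


# ---------------------------------------------------------------------------
# Area-resampling bootstrap
# ---------------------------------------------------------------------------


@dataclass
class BootstrapResult:
    """Replicate-level centrality tables plus a rank-stability summary.

    ``replicates`` holds one DataFrame per replicate (columns of
    ``CentralityRecord`` plus the replicate's deleted/duplicated choices);
    ``summary`` has one row per original region: median ranks, hub
    frequency, and the number of replicates in which the region survived.
    """

    n_replicates: int
    alpha: float
    top_fraction: float
    seed: int
    replicates: list[pd.DataFrame]
    summary: pd.DataFrame


def bootstrap_centrality(
    table: CountTable,
    alpha: float = 0.05,
    n_replicates: int = 380,
    seed: int = 0,
    top_fraction: float = 0.35,
    positive_only: bool = False,
) -> BootstrapResult:
    """Duplicate-one/delete-one area bootstrap of the centrality ranking.

    Each replicate deletes one region chosen uniformly at random, then
    duplicates one of the survivors (as a new column ``<label>+dup`` with
    identical values), keeping the atlas length constant; the correlation
    matrix, network, centralities and hub calls are recomputed on the
    resampled table. The summary aggregates, per original region, its rank
    distribution and hub frequency over the replicates in which it survives.
    Fully reproducible for a given seed.
    """
    regions = list(table.regions)
    if len(regions) < 3:
        raise ValueError("need at least 3 regions to bootstrap")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    replicate_frames: list[pd.DataFrame] = []
    rank_rows: dict[str, list[tuple[int, int, bool]]] = {r: [] for r in regions}
    for rep in range(n_replicates):
        deleted = regions[rng.integers(len(regions))]
        survivors = [r for r in regions if r != deleted]
        duplicated = survivors[rng.integers(len(survivors))]
        values = table.values[survivors].copy()
        values[duplicated + DUPLICATE_SUFFIX] = values[duplicated]
        resampled = CountTable(values=values, group=table.group)
        corr = pearson_matrix(resampled)
        net = build_network(
            corr, alpha=alpha,
            mean_counts=resampled.mean_counts().to_dict(),
            positive_only=positive_only,
        )
        records = centrality_records(net, top_fraction=top_fraction)
        frame = centrality_frame(records)
        frame["replicate"] = rep
        frame["deleted"] = deleted
        frame["duplicated"] = duplicated
        replicate_frames.append(frame)
        for rec in records:
            if rec.region in rank_rows:  # skip the +dup column
                rank_rows[rec.region].append(
                    (rec.degree_rank, rec.betweenness_rank, rec.is_hub)
                )
    summary_rows = []
    for region in regions:
        entries = rank_rows[region]
        if entries:
            deg_ranks = [e[0] for e in entries]
            btw_ranks = [e[1] for e in entries]
            hub_freq = sum(e[2] for e in entries) / len(entries)
            summary_rows.append(
                {
                    "region": region,
                    "n_surviving": len(entries),
                    "median_degree_rank": float(np.median(deg_ranks)),
                    "median_betweenness_rank": float(np.median(btw_ranks)),
                    "hub_frequency": hub_freq,
                }
            )
        else:
            summary_rows.append(
                {
                    "region": region,
                    "n_surviving": 0,
                    "median_degree_rank": float("nan"),
                    "median_betweenness_rank": float("nan"),
                    "hub_frequency": float("nan"),
                }
            )
    return BootstrapResult(
        n_replicates=n_replicates,
        alpha=alpha,
        top_fraction=top_fraction,
        seed=seed,
        replicates=replicate_frames,
        summary=pd.DataFrame(summary_rows),
    )


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def export_graphml(net: nx.Graph, path: str | Path, top_fraction: float = 0.35) -> None:
    """GraphML with node attributes label/mean_count/degree/betweenness/is_hub
    and edge attributes r/p, for import into Cytoscape or igraph."""
    g = net.copy()
    records = {c.region: c for c in centrality_records(g, top_fraction)}
    for node, data in g.nodes(data=True):
        rec = records[node]
        data.setdefault("label", str(node))
        data.setdefault("mean_count", 0.0)
        data["degree"] = rec.degree
        data["betweenness"] = rec.betweenness
        data["is_hub"] = bool(rec.is_hub)
    nx.write_graphml(g, path)


def export_sif(net: nx.Graph, path: str | Path, interaction: str = "corr") -> None:
    """Simple interaction format: `source interaction target` per edge,
    isolated nodes on their own lines."""
    with open(path, "w") as fh:
        isolated = [n for n in net.nodes if net.degree(n) == 0]
        for u, v in net.edges:
            fh.write(f"{u}\t{interaction}\t{v}\n")
        for n in isolated:
            fh.write(f"{n}\n")
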