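"""Phosphorylation-count binning and within-bin interaction-network statistics.

A proteome is partitioned into ordered bins by phospho-site count —
deciles, quintiles, or a zero-count bin followed by quartiles of the rest
(used when most proteins carry no site at all).  Tied counts are never
split across bins: an ideal quantile boundary landing inside a run of equal
counts moves right to the end of the run, so bin sizes are only
approximately equal.  Within each bin, the interaction subgraph at a
combined-score cut (strictly above 0.7 by default) is summarised by node
and edge counts, mean degree, connected components with at least two nodes,
and the percentage of isolated proteins.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .types import InteractionTable, ProteinRecord

logger = logging.getLogger(__name__)

SCHEMES = {"decile": 10, "quintile": 5, "zero-plus-quartile": 4}


@dataclass
class Bin:
    lo: int                      # smallest site count in the bin
    hi: int                      # largest site count in the bin
    members: list[str]           # accessions

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class BinPartition:
    scheme: str
    bins: list[Bin]

    def __post_init__(self) -> None:
        ranges = [(b.lo, b.hi) for b in self.bins]
        for (lo, hi) in ranges:
            if lo > hi:
                raise ValueError(f"inverted range [{lo}, {hi}]")
        for (_, hi_prev), (lo_next, _) in zip(ranges, ranges[1:]):
            if lo_next <= hi_prev:
                raise ValueError("bin ranges overlap or are not ascending")


def _quantile_boundaries(counts: Sequence[int], k: int) -> list[int]:
    """Boundary indices into the ascending-sorted counts for k quantile bins.

    The ideal i-th boundary sits at rank i*N/k; a boundary inside a run of
    equal counts moves right to the end of the run so ties stay together.
    """
    n = len(counts)
    cuts: list[int] = []
    for i in range(1, k):
        j = round(i * n / k)
        while 0 < j < n and counts[j - 1] == counts[j]:
            j += 1
        cuts.append(j)
    return cuts


def assign_bins(
    records: Sequence[ProteinRecord], scheme: str = "decile"
) -> BinPartition:
    """Partition records into ordered phospho-site-count bins.

    ``zero-plus-quartile`` first isolates the count-0 proteins as their own
    bin, then splits the remainder into quartiles; the plain quantile
    schemes need at least k proteins with distinct enough counts.  When all
    counts are equal a single-bin partition is returned with a warning.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {sorted(SCHEMES)}")
    if not records:
        raise ValueError("cannot bin an empty record set")
    ordered = sorted(records, key=lambda r: (r.site_count, r.accession))
    counts = [r.site_count for r in ordered]

    if counts[0] == counts[-1]:
        logger.warning("all site counts equal (%d): single-bin partition", counts[0])
        return BinPartition(
            scheme=scheme,
            bins=[Bin(counts[0], counts[-1], [r.accession for r in ordered])],
        )

    bins: list[Bin] = []
    if scheme == "zero-plus-quartile":
        zeros = [r for r in ordered if r.site_count == 0]
        rest = [r for r in ordered if r.site_count > 0]
        if zeros:
            bins.append(Bin(0, 0, [r.accession for r in zeros]))
        if len(rest) < SCHEMES[scheme]:
            raise ValueError(
                f"need >= {SCHEMES[scheme]} phosphorylated proteins for quartiles"
            )
        bins.extend(_split(rest, SCHEMES[scheme]))
    else:
        k = SCHEMES[scheme]
        if len(ordered) < k:
            raise ValueError(f"need >= {k} proteins for a {scheme} partition")
        bins.extend(_split(ordered, k))
    return BinPartition(scheme=scheme, bins=bins)


def _split(ordered: list[ProteinRecord], k: int) -> list[Bin]:
    counts = [r.site_count for r in ordered]
    cuts = _quantile_boundaries(counts, k)
    edges = [0] + cuts + [len(ordered)]
    bins = []
    for lo_idx, hi_idx in zip(edges, edges[1:]):
        if hi_idx <= lo_idx:
            continue  # a tie run swallowed this bin entirely
        chunk = ordered[lo_idx:hi_idx]
        bins.append(
            Bin(chunk[0].site_count, chunk[-1].site_count,
                [r.accession for r in chunk])
        )
    return bins


def bin_subnetwork(
    members: Iterable[str],
    interactions: InteractionTable,
    threshold: float = 0.7,
) -> nx.Graph:
    """Within-bin interaction graph: all bin members as nodes (isolated ones
    included), edges for member pairs with score strictly above threshold."""
    return interactions.graph(threshold=threshold, nodes=members)


@dataclass
class BinNetworkStats:
    nb_nodes: int
    nb_edges: int
    avg_neighbors: float         # 2E / N over all bin nodes
    nb_connected: int            # connected components with >= 2 nodes
    pct_singletons: float        # 100 * degree-0 nodes / N (NaN when N = 0)


def network_stats(graph: nx.Graph) -> BinNetworkStats:
    """Summary statistics of one bin's interaction subgraph.

    Mean degree is 2E/N over *all* nodes of the bin; components of a single
    node are not counted as connected components (they are the singletons).
    """
    n = graph.number_of_nodes()
    e = graph.number_of_edges()
    if n == 0:
        return BinNetworkStats(0, 0, 0.0, 0, math.nan)
    singletons = sum(1 for _, d in graph.degree() if d == 0)
    nb_connected = sum(
        1 for comp in nx.connected_components(graph) if len(comp) >= 2
    )
    return BinNetworkStats(
        nb_nodes=n,
        nb_edges=e,
        avg_neighbors=2.0 * e / n,
        nb_connected=nb_connected,
        pct_singletons=100.0 * singletons / n,
    )


def bin_network_table(
    partition: BinPartition,
    interactions: InteractionTable,
    threshold: float = 0.7,
) -> pd.DataFrame:
    """One row per bin with its range and network statistics."""
    rows = []
    for i, b in enumerate(partition.bins, start=1):
        s = network_stats(bin_subnetwork(b.members, interactions, threshold))
        rows.append(
            {
                "bin": i,
                "range_lo": b.lo,
                "range_hi": b.hi,
                "nb_nodes": s.nb_nodes,
                "nb_edges": s.nb_edges,
                "avg_neighbors": s.avg_neighbors,
                "nb_connected": s.nb_connected,
                "pct_singletons": s.pct_singletons,
            }
        )
    return pd.DataFrame(rows)
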