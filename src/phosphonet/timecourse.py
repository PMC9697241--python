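"""Phospho-variation counting, active-module search, and status tracking
for stimulation time courses.

A SILAC time course gives per-site log2 fold-changes versus control at each
time point.  Each protein is reduced to a *variation count*: the number of
its sites whose |log2FC| meets the two-fold threshold (log2FC <= -1 or
>= +1, inclusive).  These counts weight the nodes of the interaction
network, on which connected *active modules* — subnetworks whose weights
are collectively elevated — are searched per time point; finally each
protein's differential status is tracked across consecutive time points.

The module search is a seeded greedy expansion of a standardised mean-weight
statistic (Ideker-style active-module search): from each high-weight seed, a
module repeatedly absorbs the neighbour that maximises

    z(M) = (mean weight in M - background mean) / (background sd / sqrt(|M|))

and stops when no addition improves z.  Modules are connected, pairwise
disjoint, and ranked by z.  Any node-weighted searcher honouring the same
contract (weights in, ranked connected modules out) can be substituted.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .types import TimeCourseTable

#: per (time point, accession) variation counts
VariationCounts = dict[int, dict[str, int]]


def variation_counts(
    tc: TimeCourseTable, threshold: float = 1.0
) -> VariationCounts:
    """Count, per protein and time point, sites with |log2FC| >= threshold.

    Every accession appearing anywhere in the table gets an entry at every
    declared time point (0 when nothing qualifies or nothing was measured).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    df = tc.records
    qualifying = df[(df["log2fc"] <= -threshold) | (df["log2fc"] >= threshold)]
    grouped = qualifying.groupby(["time", "accession"]).size().to_dict()
    all_accessions = df["accession"].unique()
    return {
        t: {acc: int(grouped.get((t, acc), 0)) for acc in all_accessions}
        for t in tc.time_points
    }


@dataclass
class Module:
    """One active module at one time point."""

    time: int
    rank: int
    nodes: frozenset[str]
    score: float


def _zscore(total_w: float, size: int, mu: float, sd: float) -> float:
    return (total_w / size - mu) / (sd / math.sqrt(size))


def find_modules(
    graph: nx.Graph,
    weights: Mapping[str, float],
    z_floor: float = 2.0,
    time: int = 0,
) -> list[Module]:
    """Greedy z-statistic search for node-weighted active modules.

    Background mean and sd are computed over all graph nodes (missing
    weights count as 0).  Seeds are taken in descending weight; each module
    grows over nodes not already claimed by a higher-seeded module, so the
    returned modules are pairwise disjoint and connected.  Only modules with
    z >= ``z_floor`` are returned, ranked by z.
    """
    if any(w < 0 for w in weights.values()):
        raise ValueError("weights must be nonnegative")
    nodes = list(graph.nodes)
    if not nodes:
        return []
    w = {v: float(weights.get(v, 0.0)) for v in nodes}
    n = len(nodes)
    mu = sum(w.values()) / n
    sd = math.sqrt(sum((x - mu) ** 2 for x in w.values()) / n)
    if sd == 0:
        return []  # flat weights: nothing is elevated

    claimed: set[str] = set()
    found: list[Module] = []
    for seed in sorted(nodes, key=lambda v: (-w[v], v)):
        if w[seed] <= mu:
            break  # remaining seeds cannot start a positive module
        if seed in claimed:
            continue
        module = {seed}
        total = w[seed]
        z = _zscore(total, 1, mu, sd)
        while True:
            frontier = {
                u
                for v in module
                for u in graph.neighbors(v)
                if u not in module and u not in claimed
            }
            best_u, best_z = None, z
            for u in sorted(frontier):
                cand = _zscore(total + w[u], len(module) + 1, mu, sd)
                if cand > best_z:
                    best_u, best_z = u, cand
            if best_u is None:
                break
            module.add(best_u)
            total += w[best_u]
            z = best_z
        if z >= z_floor:
            claimed.update(module)
            found.append(Module(time=time, rank=0, nodes=frozenset(module), score=z))
    found.sort(key=lambda m: (-m.score, sorted(m.nodes)))
    for i, m in enumerate(found, start=1):
        m.rank = i
    return found


def modules_by_time(
    graph: nx.Graph,
    counts: VariationCounts,
    z_floor: float = 2.0,
) -> dict[int, list[Module]]:
    """Run the module search independently at each time point."""
    return {
        t: find_modules(graph, per_protein, z_floor=z_floor, time=t)
        for t, per_protein in counts.items()
    }


STATUSES = ("new", "persistent", "reverted", "unaffected")


def track_status(
    counts: VariationCounts,
    time_points: Sequence[int] | None = None,
    min_count: int = 1,
) -> pd.DataFrame:
    """Differential status of each protein across consecutive time points.

    A protein is differential at a time point when its variation count
    reaches ``min_count``.  Status: *new* (differential now, not at the
    previous time point), *persistent* (differential now and before),
    *reverted* (not differential now, was before), *unaffected* otherwise.
    The first time point has no predecessor, hence no persistent/reverted.
    """
    times = list(time_points) if time_points is not None else sorted(counts)
    accessions = sorted({acc for per in counts.values() for acc in per})
    rows = []
    prev_diff: dict[str, bool] = {}
    for i, t in enumerate(times):
        per = counts.get(t, {})
        for acc in accessions:
            diff = per.get(acc, 0) >= min_count
            was = prev_diff.get(acc, False) if i > 0 else False
            if diff:
                status = "persistent" if was else "new"
            else:
                status = "reverted" if was else "unaffected"
            rows.append({"time": t, "accession": acc, "status": status})
        prev_diff = {acc: per.get(acc, 0) >= min_count for acc in accessions}
    return pd.DataFrame(rows, columns=["time", "accession", "status"])
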