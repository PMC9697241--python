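"""Core in-memory containers shared by every pipeline stage.

All readers in :mod:`phosphonet.io` validate their input into these types;
downstream stages (landscape, homology, binning, enrichment, kinase overlap,
time-course modules) only ever consume validated instances.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

#: residues commonly reported as phospho-acceptors; anything else is kept
#: verbatim but flagged as "other" by consumers that care.
CANONICAL_RESIDUES = ("S", "T", "Y", "H")


@dataclass(frozen=True)
class PhosphoSite:
    """A single phosphorylation site: 1-based position and residue letter."""

    position: int
    residue: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"site position must be >= 1, got {self.position}")


@dataclass
class ProteinRecord:
    """One protein of one species.

    ``length`` (amino acids) and ``mass`` (daltons) may be unknown (``None``)
    when the protein was seen only in a phospho-site table; such records are
    excluded from density and regression stages but still usable for
    count-only stages (binning, networks).
    """

    accession: str
    species: str
    length: Optional[int] = None
    mass: Optional[float] = None
    phospho_sites: tuple[PhosphoSite, ...] = ()
    homology_group: Optional[int] = None

    def __post_init__(self) -> None:
        if self.length is not None and self.length <= 0:
            raise ValueError(
                f"{self.accession}: length must be positive, got {self.length}"
            )
        if self.mass is not None and self.mass <= 0:
            raise ValueError(
                f"{self.accession}: mass must be positive, got {self.mass}"
            )
        if self.length is not None:
            for s in self.phospho_sites:
                if s.position > self.length:
                    raise ValueError(
                        f"{self.accession}: site position {s.position} exceeds "
                        f"length {self.length}"
                    )

    @property
    def site_count(self) -> int:
        return len(self.phospho_sites)

    @property
    def is_phosphorylated(self) -> bool:
        return self.site_count >= 1


@dataclass
class InteractionTable:
    """Scored undirected protein-protein associations.

    Edges are keyed by the sorted accession pair; scores live on the unit
    interval regardless of the input dialect (0-999 integer scores are
    normalised on read).
    """

    edges: dict[tuple[str, str], float] = field(default_factory=dict)
    score_scale: str = "unit"

    @staticmethod
    def key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str, score: float) -> None:
        if a == b:
            raise ValueError(f"self-loop on {a}")
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"score {score} outside [0, 1]")
        k = self.key(a, b)
        prev = self.edges.get(k)
        # duplicate / reversed rows keep the maximum score
        self.edges[k] = score if prev is None else max(prev, score)

    def __len__(self) -> int:
        return len(self.edges)

    def graph(
        self,
        threshold: float = 0.7,
        nodes: Optional[Iterable[str]] = None,
    ) -> nx.Graph:
        """Graph of edges with score strictly above ``threshold``.

        When ``nodes`` is given, the graph contains exactly those nodes
        (isolated ones included) and only edges internal to the set.
        """
        g = nx.Graph()
        if nodes is not None:
            keep = set(nodes)
            g.add_nodes_from(keep)
            for (a, b), s in self.edges.items():
                if s > threshold and a in keep and b in keep:
                    g.add_edge(a, b, score=s)
        else:
            for (a, b), s in self.edges.items():
                if s > threshold:
                    g.add_edge(a, b, score=s)
        return g


@dataclass
class HomologyTable:
    """HID -> species -> accessions, mirroring the HomoloGene grouping."""

    groups: dict[int, dict[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[str, int] = {}
        for hid, by_species in self.groups.items():
            for accs in by_species.values():
                for acc in accs:
                    if acc in seen and seen[acc] != hid:
                        raise ValueError(
                            f"accession {acc} appears under HIDs "
                            f"{seen[acc]} and {hid}"
                        )
                    seen[acc] = hid

    def hid_of(self) -> dict[str, int]:
        """Flat accession -> HID mapping."""
        out: dict[str, int] = {}
        for hid, by_species in self.groups.items():
            for accs in by_species.values():
                for acc in accs:
                    out[acc] = hid
        return out

    def species_of_hid(self, hid: int) -> set[str]:
        return set(self.groups.get(hid, {}))

    def shared_hids(self, species_a: str, species_b: str) -> list[int]:
        return sorted(
            hid
            for hid, by_species in self.groups.items()
            if species_a in by_species and species_b in by_species
        )


@dataclass
class KinaseTargetMap:
    """Named kinase groups, each owning a set of target accessions.

    Target sets may overlap across groups; the overlap structure is the whole
    point of the Euler-region analysis.
    """

    groups: dict[str, frozenset[str]] = field(default_factory=dict)

    def total_targets(self) -> int:
        """Number of distinct targets across all groups."""
        union: set[str] = set()
        for targets in self.groups.values():
            union |= targets
        return len(union)


@dataclass
class TimeCourseTable:
    """Per-protein, per-site, per-time-point log2 fold-changes (SILAC style).

    ``records`` is a DataFrame with columns ``accession``, ``position``,
    ``time``, ``log2fc``; ``time_points`` is the declared ordered list of
    time points in minutes.
    """

    records: pd.DataFrame
    time_points: Sequence[int]

    def __post_init__(self) -> None:
        required = {"accession", "position", "time", "log2fc"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"time-course table missing columns {sorted(missing)}")
        declared = set(self.time_points)
        bad = set(self.records["time"].unique()) - declared
        if bad:
            raise ValueError(f"undeclared time points {sorted(bad)}")
        dup = self.records.duplicated(["accession", "position", "time"])
        if dup.any():
            raise ValueError(
                f"{int(dup.sum())} duplicate (accession, site, time) records"
            )


def records_frame(records: Iterable[ProteinRecord]) -> pd.DataFrame:
    """Tabular view of protein records used by the statistics stages."""
    rows = [
        {
            "accession": r.accession,
            "species": r.species,
            "length": r.length,
            "mass": r.mass,
            "site_count": r.site_count,
            "homology_group": r.homology_group,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "accession",
            "species",
            "length",
            "mass",
            "site_count",
            "homology_group",
        ],
    )
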