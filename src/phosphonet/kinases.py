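"""Euler-region cardinalities over kinase-group target sets.

Each phosphoprotein targeted by at least one kinase group belongs to exactly
one *region*: the signature of the groups that target it.  Region
cardinalities therefore partition the distinct targets.  Two filters
mirror how such diagrams are simplified in practice: dropping groups that
target no more than a given fraction of the dataset, and merging groups
whose target sets are identical (they occupy the same region geometry).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .types import KinaseTargetMap

logger = logging.getLogger(__name__)


@dataclass
class EulerRegions:
    """Signature (sorted tuple of group names) -> member accessions."""

    regions: dict[tuple[str, ...], frozenset[str]]
    total: int     # distinct targets across all groups

    def cardinalities(self) -> dict[tuple[str, ...], int]:
        return {sig: len(members) for sig, members in self.regions.items()}

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"signature": "+".join(sig), "cardinality": len(members)}
            for sig, members in sorted(self.regions.items())
        ]
        return pd.DataFrame(rows, columns=["signature", "cardinality"])


def region_counts(kmap: KinaseTargetMap) -> EulerRegions:
    """Assign every target to the signature of exactly the groups holding it."""
    if not kmap.groups:
        raise ValueError("need at least one kinase group")
    membership: dict[str, set[str]] = {}
    for name, targets in kmap.groups.items():
        for acc in targets:
            membership.setdefault(acc, set()).add(name)
    regions: dict[tuple[str, ...], set[str]] = {}
    for acc, names in membership.items():
        regions.setdefault(tuple(sorted(names)), set()).add(acc)
    return EulerRegions(
        regions={sig: frozenset(m) for sig, m in regions.items()},
        total=len(membership),
    )


def prominent_groups(
    kmap: KinaseTargetMap, fraction: float = 0.02
) -> KinaseTargetMap:
    """Keep groups targeting strictly more than ``fraction`` of the distinct
    targets across all groups (the dataset union)."""
    total = kmap.total_targets()
    if total == 0:
        raise ValueError("empty target map")
    kept = {
        name: targets
        for name, targets in kmap.groups.items()
        if len(targets) > fraction * total
    }
    if not kept:
        logger.warning("no kinase group passes the %.1f%% cut", 100 * fraction)
    return KinaseTargetMap(groups=kept)


def merge_identical(kmap: KinaseTargetMap) -> KinaseTargetMap:
    """Collapse groups with set-equal targets under a composite ``A+B`` label
    (names sorted).  Idempotent."""
    by_targets: dict[frozenset[str], list[str]] = {}
    for name, targets in kmap.groups.items():
        by_targets.setdefault(targets, []).append(name)
    merged = {
        "+".join(sorted("+".join(sorted(names)).split("+"))): targets
        for targets, names in by_targets.items()
    }
    return KinaseTargetMap(groups={k: v for k, v in merged.items()})
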