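"""Annotation over-representation per query set (bin, module, Euler region).

For each labelled query set and annotation term, a one-sided upper-tail
hypergeometric test asks whether the term's annotated proteins are
over-represented in the query relative to the universe.  P-values are
Benjamini-Hochberg adjusted *within each query label* (matching the
per-column presentation of the enrichment heatmaps), and the heatmap cell
holds log10(FDR) when FDR < 0.05 and 0 otherwise.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class AnnotationMap:
    """Term -> annotated accessions, within a declared universe."""

    terms: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for term, members in self.terms.items():
            extra = members - self.universe
            if extra:
                raise ValueError(
                    f"term {term}: {len(extra)} annotated accessions outside "
                    "the universe"
                )

    @classmethod
    def from_table(cls, df: pd.DataFrame, universe=None) -> "AnnotationMap":
        """Build from a 2-column (term, accession) table.  The universe
        defaults to every accession appearing in the table."""
        terms: dict[str, set[str]] = {}
        for row in df.itertuples(index=False):
            terms.setdefault(str(row.term), set()).add(str(row.accession))
        if universe is None:
            universe = set().union(*terms.values()) if terms else set()
        return cls(
            terms={t: frozenset(m) for t, m in terms.items()},
            universe=frozenset(universe),
        )


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X hypergeometric: ``n`` draws from a universe of ``N``
    containing ``K`` marked elements."""
    if not (0 <= k <= min(K, n) <= N):
        raise ValueError(f"invalid hypergeometric bounds k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_fdr(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


@dataclass
class EnrichmentResult:
    term: str
    label: str
    k: int          # query ∩ term
    K: int          # term size
    n: int          # query size
    N: int          # universe size
    p: float
    fdr: float

    @property
    def log10_fdr(self) -> float:
        """log10 of the adjusted p when significant (FDR < 0.05), else 0."""
        return math.log10(self.fdr) if self.fdr < 0.05 else 0.0


def enrich(
    queries: Mapping[str, set[str] | frozenset[str]],
    annotations: AnnotationMap,
    clip_to_universe: bool = False,
) -> list[EnrichmentResult]:
    """Test every (query label, term) combination.

    Query sets must be subsets of the annotation universe unless
    ``clip_to_universe`` asks for silent intersection.  FDR adjustment runs
    within each label across its terms.
    """
    N = len(annotations.universe)
    results: list[EnrichmentResult] = []
    for label, members in queries.items():
        query = frozenset(members)
        outside = query - annotations.universe
        if outside:
            if clip_to_universe:
                query -= outside
            else:
                raise ValueError(
                    f"query {label!r}: {len(outside)} accessions outside the "
                    "universe (pass clip_to_universe=True to intersect)"
                )
        if not query:
            continue
        batch = []
        for term, annotated in sorted(annotations.terms.items()):
            k = len(query & annotated)
            batch.append(
                EnrichmentResult(
                    term=term, label=label, k=k, K=len(annotated),
                    n=len(query), N=N,
                    p=hypergeom_p(k, len(annotated), len(query), N),
                    fdr=math.nan,
                )
            )
        for res, adj in zip(batch, bh_fdr([r.p for r in batch])):
            res.fdr = adj
        results.extend(batch)
    return results


def results_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": r.term, "label": r.label, "k": r.k, "K": r.K,
                "n": r.n, "N": r.N, "p": r.p, "fdr": r.fdr,
                "log10_fdr": r.log10_fdr,
            }
            for r in results
        ]
    )


def heatmap_matrix(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Term x label matrix of log10(FDR); non-significant cells hold 0."""
    if not results:
        return pd.DataFrame()
    df = results_frame(results)
    return df.pivot_table(
        index="term", columns="label", values="log10_fdr", fill_value=0.0
    )
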