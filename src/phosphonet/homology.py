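"""Cross-species homolog correlation and mass-site regressions.

For each pair of species, proteins sharing a HomoloGene group (HID) are
paired by their phosphorylation metric (site count by default, density as an
option) and rank-correlated with Spearman's rho.  Correlation strength is
labelled with the conventional bands: strong above 0.6, moderate in
(0.4, 0.6], weak in [0.2, 0.4].
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from statistics import mean
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .landscape import density
from .types import HomologyTable, ProteinRecord

Metric = Literal["sites", "density"]

MASS_CAP = 500_000.0   # daltons; outlier filter for the regressions
SITE_CAP = 500


def _metric_value(record: ProteinRecord, metric: Metric) -> float:
    if metric == "sites":
        return float(record.site_count)
    if metric == "density":
        return density(record)
    raise ValueError(f"unknown metric {metric!r}")


def pair_homolog_values(
    homology: HomologyTable,
    records_a: Sequence[ProteinRecord],
    records_b: Sequence[ProteinRecord],
    metric: Metric = "sites",
) -> list[tuple[float, float]]:
    """One (x, y) pair per HID shared by both species.

    Within a species and HID, multiple proteins (paralogs) are aggregated by
    the arithmetic mean of the metric.
    """
    if not records_a or not records_b:
        return []
    species_a = records_a[0].species
    species_b = records_b[0].species
    value_a = {r.accession: _metric_value(r, metric) for r in records_a}
    value_b = {r.accession: _metric_value(r, metric) for r in records_b}
    pairs: list[tuple[float, float]] = []
    for hid in homology.shared_hids(species_a, species_b):
        accs_a = [a for a in homology.groups[hid][species_a] if a in value_a]
        accs_b = [b for b in homology.groups[hid][species_b] if b in value_b]
        if accs_a and accs_b:
            pairs.append(
                (mean(value_a[a] for a in accs_a), mean(value_b[b] for b in accs_b))
            )
    return pairs


def spearman_rho(pairs: Sequence[tuple[float, float]]) -> float:
    """Spearman rank correlation: Pearson correlation of average ranks.

    Refuses fewer than 10 pairs (the estimate would be meaningless) and
    returns NaN when either margin has zero variance (undefined).
    """
    if len(pairs) < 10:
        raise ValueError(f"need >= 10 pairs, got {len(pairs)}")
    x, y = zip(*pairs)
    if len(set(x)) == 1 or len(set(y)) == 1:
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def classify_strength(rho: float) -> str:
    """Strength band for a correlation value.

    strong: rho > 0.6; moderate: 0.4 < rho <= 0.6; weak: 0.2 <= rho <= 0.4;
    below-weak otherwise.  Boundary values fall to the lower band.
    """
    if np.isnan(rho):
        raise ValueError("rho is undefined")
    if rho > 0.6:
        return "strong"
    if rho > 0.4:
        return "moderate"
    if rho >= 0.2:
        return "weak"
    return "below-weak"


def correlation_matrix(
    homology: HomologyTable,
    records_by_species: dict[str, Sequence[ProteinRecord]],
    metric: Metric = "sites",
    min_pairs: int = 10,
) -> pd.DataFrame:
    """Symmetric species x species table of (rho, n_pairs, strength).

    Diagonal rho is 1 by construction.  Pairs with fewer than ``min_pairs``
    shared HIDs get NaN.
    """
    species = sorted(records_by_species)
    rows = []
    for a, b in itertools.combinations_with_replacement(species, 2):
        if a == b:
            rho, n = 1.0, len(records_by_species[a])
        else:
            pairs = pair_homolog_values(
                homology, list(records_by_species[a]),
                list(records_by_species[b]), metric,
            )
            n = len(pairs)
            rho = spearman_rho(pairs) if n >= min_pairs else float("nan")
        label = classify_strength(rho) if not np.isnan(rho) else "undefined"
        rows.append({"species_a": a, "species_b": b, "rho": rho,
                     "n_pairs": n, "strength": label})
        if a != b:
            rows.append({"species_a": b, "species_b": a, "rho": rho,
                         "n_pairs": n, "strength": label})
    return pd.DataFrame(rows)


@dataclass
class RegressionFit:
    """OLS of site count on mass for one species / homology subset."""

    species: str
    subset: str                  # all | homologous | non_homologous
    slope: float                 # sites per dalton
    intercept: float             # sites
    n: int
    mass_cap: float
    site_cap: int


def mass_site_regression(
    records: Sequence[ProteinRecord],
    subset: str = "all",
    homology: Optional[HomologyTable] = None,
    mass_cap: float = MASS_CAP,
    site_cap: int = SITE_CAP,
) -> RegressionFit:
    """Least-squares line of phospho-site count against protein mass.

    Only phosphorylated proteins (>= 1 site) with known mass enter; records
    with mass >= ``mass_cap`` or site count >= ``site_cap`` are excluded
    (strict filters) to limit outlier leverage.  ``subset`` restricts to
    homologous / non-homologous proteins when a homology table is given.
    """
    from .landscape import _homologous_mask

    if subset not in ("all", "homologous", "non_homologous"):
        raise ValueError(f"unknown subset {subset!r}")
    recs = list(records)
    hom = _homologous_mask(recs, homology)
    keep: list[ProteinRecord] = []
    for r, h in zip(recs, hom):
        if r.mass is None or r.site_count < 1:
            continue
        if not (r.mass < mass_cap and r.site_count < site_cap):
            continue
        if subset == "homologous" and not h:
            continue
        if subset == "non_homologous" and h:
            continue
        keep.append(r)
    if len(keep) < 2:
        raise ValueError(
            f"only {len(keep)} records survive the filters; need >= 2"
        )
    x = np.array([r.mass for r in keep])
    y = np.array([r.site_count for r in keep], dtype=float)
    if np.allclose(y, y[0]):
        slope, intercept = 0.0, float(y[0])
    elif np.allclose(x, x[0]):
        raise ValueError("mass has zero variance; slope undefined")
    else:
        fit = stats.linregress(x, y)
        slope, intercept = float(fit.slope), float(fit.intercept)
    return RegressionFit(
        species=keep[0].species,
        subset=subset,
        slope=slope,
        intercept=intercept,
        n=len(keep),
        mass_cap=mass_cap,
        site_cap=site_cap,
    )
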