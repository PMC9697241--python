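"""Per-species phosphorylation landscape summaries and the site-density
frequency distribution.

A protein is *phosphorylated* iff it carries at least one site, and
*homologous* iff its homology group (HID) contains at least one protein of
another species.  Mean density is the mean of per-protein densities
(sites per 1000 aa), not the ratio of means.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import HomologyTable, ProteinRecord, records_frame

CATEGORIES = (
    "all",
    "non_phosphorylated",
    "non_phosphorylated_homologous",
    "non_phosphorylated_non_homologous",
    "phosphorylated",
    "phosphorylated_homologous",
    "phosphorylated_non_homologous",
)


def density(record: ProteinRecord) -> float:
    """Phospho-site density: sites per 1000 amino acids."""
    if record.length is None or record.length <= 0:
        raise ValueError(f"{record.accession}: length unknown or non-positive")
    return 1000.0 * record.site_count / record.length


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal rounding with ties away from zero (table formatting rule)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: int, total: int, ndigits: int = 2) -> float:
    """Percentage of ``total``, half-up rounded to ``ndigits`` decimals."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_up(100.0 * count / total, ndigits)


def _homologous_mask(
    records: Sequence[ProteinRecord], homology: Optional[HomologyTable]
) -> np.ndarray:
    """True where the record's HID holds >=1 protein of another species."""
    if homology is None:
        return np.array(
            [r.homology_group is not None for r in records], dtype=bool
        )
    hid_of = homology.hid_of()
    out = np.zeros(len(records), dtype=bool)
    for i, r in enumerate(records):
        hid = r.homology_group
        if hid is None:
            hid = hid_of.get(r.accession)
        if hid is None:
            continue
        out[i] = bool(homology.species_of_hid(hid) - {r.species})
    return out


def summarize(
    records: Sequence[ProteinRecord],
    homology: Optional[HomologyTable] = None,
) -> pd.DataFrame:
    """Landscape summary: one row per category.

    Columns: count, pct (of all proteins, 2-dp half-up), mean_length,
    mean_mass, mean_sites, mean_density.  Length/mass/density means use only
    records with known length (and mass where relevant); site means use all
    records in the category.  Empty categories keep their zero count with
    NaN means.
    """
    if not records:
        raise ValueError("summarize requires at least one record")
    df = records_frame(records)
    df["homologous"] = _homologous_mask(records, homology)
    df["phos"] = df["site_count"] >= 1
    with np.errstate(invalid="ignore"):
        df["density"] = 1000.0 * df["site_count"] / df["length"]

    total = len(df)
    masks = {
        "all": np.ones(total, dtype=bool),
        "non_phosphorylated": ~df["phos"].to_numpy(),
        "non_phosphorylated_homologous": (~df["phos"] & df["homologous"]).to_numpy(),
        "non_phosphorylated_non_homologous": (~df["phos"] & ~df["homologous"]).to_numpy(),
        "phosphorylated": df["phos"].to_numpy(),
        "phosphorylated_homologous": (df["phos"] & df["homologous"]).to_numpy(),
        "phosphorylated_non_homologous": (df["phos"] & ~df["homologous"]).to_numpy(),
    }
    rows = []
    for cat in CATEGORIES:
        sub = df[masks[cat]]
        n = len(sub)
        rows.append(
            {
                "category": cat,
                "count": n,
                "pct": percentage(n, total) if n else 0.0,
                "mean_length": sub["length"].mean() if n else math.nan,
                "mean_mass": sub["mass"].mean() if n else math.nan,
                "mean_sites": sub["site_count"].mean() if n else math.nan,
                "mean_density": sub["density"].mean() if n else math.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class DensityDistribution:
    """Integer-binned site-density frequencies plus the log-log OLS fit."""

    bins: np.ndarray            # integer density values
    frequency: np.ndarray       # count / total per bin, sums to 1
    slope: Optional[float]      # None when undefined (see below)
    intercept: Optional[float]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"density_bin": self.bins, "frequency": self.frequency})


def _round_half_away(values: np.ndarray) -> np.ndarray:
    return np.sign(values) * np.floor(np.abs(values) + 0.5)


def density_distribution(records: Sequence[ProteinRecord]) -> DensityDistribution:
    """Frequency of integer-rounded densities and its log-log regression.

    The OLS of log10(frequency) on log10(bin) runs over bins >= 1 with
    nonzero frequency (the zero bin has no defined log).  With fewer than
    two such bins the slope is undefined and returned as None.
    """
    with_length = [r for r in records if r.length is not None]
    if len(with_length) < 2:
        raise ValueError("density_distribution requires >= 2 records with length")
    dens = np.array([density(r) for r in with_length])
    binned = _round_half_away(dens).astype(int)
    values, counts = np.unique(binned, return_counts=True)
    freq = counts / counts.sum()
    mask = values >= 1
    slope = intercept = None
    if mask.sum() >= 2:
        fit = stats.linregress(np.log10(values[mask]), np.log10(freq[mask]))
        slope, intercept = float(fit.slope), float(fit.intercept)
    return DensityDistribution(
        bins=values, frequency=freq, slope=slope, intercept=intercept
    )
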