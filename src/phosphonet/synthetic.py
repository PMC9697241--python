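"""Seeded synthetic datasets with the statistical structure each stage assumes.

Real phospho-proteome resources (site catalogues, reference proteomes,
homology groupings, scored interaction networks, SILAC time courses) cannot
be bundled, so every downstream stage is exercised on generated data that
reproduces the features the analyses rely on:

* heavy-tailed per-protein site counts whose density-frequency relationship
  is near-linear on a log-log plot (zero-inflated truncated power law);
* cross-species homolog pairs whose site counts carry a *planted* Spearman
  correlation (Gaussian copula on ranks, calibrated for tie attenuation);
* interaction networks whose expected node degree is coupled to the
  phospho-site count at a planted strength (Chung-Lu style weights);
* kinase-group target sets with exactly planted Euler-region cardinalities;
* time courses with a planted differentially-phosphorylated module on the
  interaction graph, returned with its ground-truth node set.

Every generator is bit-deterministic under a fixed seed: the global seed is
expanded into independent per-generator streams, so adding one generator
never perturbs another's output.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .types import (
    HomologyTable,
    InteractionTable,
    KinaseTargetMap,
    PhosphoSite,
    ProteinRecord,
    TimeCourseTable,
)

KINASE_GROUPS = (
    "AGC", "CAMK", "CK1", "CMGC", "STE", "TK", "TKL", "Other", "Atypical",
)

#: fraction of phospho-acceptor residues: S, T, Y dominate; H is rare.
RESIDUE_WEIGHTS = {"S": 0.86, "T": 0.12, "Y": 0.018, "H": 0.002}


class ConfigError(ValueError):
    """An inconsistent synthetic configuration."""


@dataclass
class SiteCountLaw:
    """Zero-inflated discrete power law for per-protein site counts.

    P(0) = ``zero_fraction``; conditional on >0, P(k) proportional to
    k**-``exponent`` for k = 1..``cap``.  The power-law tail is what makes
    the density-frequency relationship near-linear on a log-log plot; the
    exponent is a knob, not a claim about any particular proteome.
    """

    zero_fraction: float = 0.06
    exponent: float = 1.5
    cap: int = 100    # may not exceed the minimum protein length

    def __post_init__(self) -> None:
        if not 0.0 <= self.zero_fraction <= 1.0:
            raise ConfigError("zero_fraction must lie in [0, 1]")
        if self.exponent <= 1.0:
            raise ConfigError("tail exponent must exceed 1")
        if self.cap < 1:
            raise ConfigError("cap must be >= 1")

    def pmf(self) -> np.ndarray:
        """Probability mass over counts 0..cap."""
        k = np.arange(1, self.cap + 1, dtype=float)
        tail = k ** (-self.exponent)
        tail *= (1.0 - self.zero_fraction) / tail.sum()
        return np.concatenate(([self.zero_fraction], tail))

    def ppf(self, u: np.ndarray) -> np.ndarray:
        """Quantile function: uniform draws -> integer counts."""
        cdf = np.cumsum(self.pmf())
        cdf[-1] = 1.0  # guard against floating rounding
        return np.searchsorted(cdf, u, side="left")


@dataclass
class LengthLaw:
    """Log-normal protein length (aa), floored at ``min_length``."""

    meanlog: float = 6.1   # median ~ 446 aa
    sdlog: float = 0.65
    min_length: int = 100

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ConfigError("min_length must be >= 1")


@dataclass
class ModulePlant:
    """How the time-course generator plants an active module.

    ``schedule`` maps each time point (minutes) to the number of sites per
    planted protein whose |log2FC| exceeds 1 at that time; background
    proteins' sites exceed independently at ``background_rate``.
    """

    size: int = 10
    n_sites: int = 5
    background_rate: float = 0.01
    schedule: Mapping[int, int] = field(
        default_factory=lambda: {1: 2, 5: 3, 10: 4, 15: 5, 20: 3, 30: 1}
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.background_rate <= 1.0:
            raise ConfigError("background_rate must lie in [0, 1]")
        if any(v > self.n_sites for v in self.schedule.values()):
            raise ConfigError("schedule exceeds sites per protein")


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic pipeline."""

    seed: int = 0
    n_proteins: int = 2000
    site_count_law: SiteCountLaw = field(default_factory=SiteCountLaw)
    length_law: LengthLaw = field(default_factory=LengthLaw)
    planted_rho: float = 0.6
    degree_coupling: float = 1.0
    edge_density: float = 0.005
    kinase_groups: Sequence[str] = KINASE_GROUPS
    kinase_region_counts: Mapping[tuple[str, ...], int] = field(
        default_factory=lambda: {
            ("TK",): 1500,
            ("AGC",): 100,
            ("CMGC",): 80,
            ("AGC", "CMGC", "TK"): 150,
            ("AGC", "CAMK", "CK1", "CMGC", "STE"): 120,
            ("AGC", "CAMK", "CK1", "CMGC", "STE", "TK"): 224,
        }
    )
    module_plant: ModulePlant = field(default_factory=ModulePlant)
    time_points: Sequence[int] = (1, 5, 10, 15, 20, 30)

    def __post_init__(self) -> None:
        if not -1.0 <= self.planted_rho <= 1.0:
            raise ConfigError("planted_rho must lie in [-1, 1]")
        if self.degree_coupling < 0:
            raise ConfigError("degree_coupling must be >= 0")
        if not 0.0 <= self.edge_density <= 1.0:
            raise ConfigError("edge_density must lie in [0, 1]")
        for signature in self.kinase_region_counts:
            unknown = set(signature) - set(self.kinase_groups)
            if unknown:
                raise ConfigError(f"unknown kinase group(s) {sorted(unknown)}")
            if not signature:
                raise ConfigError("empty region signature")


_STREAMS = {
    "proteome": 1,
    "homology": 2,
    "interactions": 3,
    "kinases": 4,
    "timecourse": 5,
    "calibration": 6,
}


def _rng(seed: int, stream: str, *labels: str) -> np.random.Generator:
    """Independent generator stream derived from the global seed."""
    key = (_STREAMS[stream],) + tuple(
        zlib.crc32(lbl.encode()) for lbl in labels
    )
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


# ---------------------------------------------------------------------------
# proteome

def _draw_sites(
    rng: np.random.Generator, count: int, length: int
) -> tuple[PhosphoSite, ...]:
    if count == 0:
        return ()
    positions = np.sort(rng.choice(length, size=count, replace=False)) + 1
    residues = rng.choice(
        list(RESIDUE_WEIGHTS), size=count, p=list(RESIDUE_WEIGHTS.values())
    )
    return tuple(PhosphoSite(int(p), str(r)) for p, r in zip(positions, residues))


def simulate_proteome(cfg: SyntheticConfig, species: str) -> list[ProteinRecord]:
    """Generate one species' proteome: lengths, masses and phospho-sites.

    Site positions are uniform without replacement over the protein length,
    which requires the site-count cap not to exceed the minimum length.
    Mass is tied to length at ~110 Da per residue with mild scatter.
    """
    law = cfg.site_count_law
    if law.cap > cfg.length_law.min_length:
        raise ConfigError(
            f"site-count cap {law.cap} exceeds minimum length "
            f"{cfg.length_law.min_length}"
        )
    rng = _rng(cfg.seed, "proteome", species)
    n = cfg.n_proteins
    lengths = np.maximum(
        np.round(
            rng.lognormal(cfg.length_law.meanlog, cfg.length_law.sdlog, size=n)
        ).astype(int),
        cfg.length_law.min_length,
    )
    masses = lengths * rng.normal(110.0, 4.0, size=n)
    counts = law.ppf(rng.uniform(size=n))
    records = []
    for i in range(n):
        records.append(
            ProteinRecord(
                accession=f"{species}_{i:06d}",
                species=species,
                length=int(lengths[i]),
                mass=float(max(masses[i], 1.0)),
                phospho_sites=_draw_sites(rng, int(counts[i]), int(lengths[i])),
            )
        )
    return records


# ---------------------------------------------------------------------------
# homolog pairs with planted Spearman

def _tied_spearman_of_latent(
    law: SiteCountLaw, latent_rho_s: float, rng: np.random.Generator,
    m: int = 20000,
) -> float:
    """Empirical tied-rank Spearman produced by a latent copula level."""
    r = 2.0 * np.sin(np.pi * latent_rho_s / 6.0)  # Spearman -> Pearson, Gaussian
    z = rng.multivariate_normal([0, 0], [[1, r], [r, 1]], size=m)
    u = stats.norm.cdf(z)
    x, y = law.ppf(u[:, 0]), law.ppf(u[:, 1])
    return float(stats.spearmanr(x, y).statistic)


def _calibrate_latent(cfg: SyntheticConfig, target: float) -> float:
    """Find the latent copula Spearman whose tied empirical Spearman hits
    ``target``; discrete margins attenuate rank correlation, so the latent
    level sits above the target.  Monotone bisection on a fixed stream."""
    law = cfg.site_count_law
    lo, hi = abs(target), 1.0
    sign = 1.0 if target >= 0 else -1.0
    for _ in range(12):
        mid = 0.5 * (lo + hi)
        rng = _rng(cfg.seed, "calibration", f"{mid:.6f}")
        got = _tied_spearman_of_latent(law, sign * mid, rng)
        if abs(got) < abs(target):
            lo = mid
        else:
            hi = mid
    return sign * 0.5 * (lo + hi)


def simulate_homology(
    cfg: SyntheticConfig, species_a: str, species_b: str, n_pairs: int
) -> tuple[HomologyTable, list[ProteinRecord], list[ProteinRecord]]:
    """Generate homolog pairs whose site counts carry the planted Spearman.

    Rank coupling uses a Gaussian copula; because the discrete site-count
    margins tie heavily at small counts, the latent correlation is
    calibrated so the *empirical* (tie-corrected) Spearman converges to
    ``cfg.planted_rho``.  |rho| = 1 bypasses the copula (comonotone /
    antitone ranks, hence exact +/-1).
    """
    if n_pairs < 10:
        raise ConfigError("n_pairs < 10: correlation would be meaningless")
    law = cfg.site_count_law
    rng = _rng(cfg.seed, "homology", species_a, species_b)
    u1 = rng.uniform(size=n_pairs)
    rho = cfg.planted_rho
    if rho >= 1.0:
        u2 = u1
    elif rho <= -1.0:
        u2 = 1.0 - u1
    elif rho == 0.0:
        u2 = rng.uniform(size=n_pairs)
    else:
        latent = _calibrate_latent(cfg, rho)
        r = 2.0 * np.sin(np.pi * latent / 6.0)
        z2 = r * stats.norm.ppf(u1) + np.sqrt(1 - r * r) * rng.standard_normal(
            n_pairs
        )
        u2 = stats.norm.cdf(z2)
    counts_a, counts_b = law.ppf(u1), law.ppf(u2)

    def _records(species: str, counts: np.ndarray) -> list[ProteinRecord]:
        lengths = np.maximum(
            np.round(
                rng.lognormal(
                    cfg.length_law.meanlog, cfg.length_law.sdlog, size=n_pairs
                )
            ).astype(int),
            max(cfg.length_law.min_length, int(counts.max())),
        )
        return [
            ProteinRecord(
                accession=f"{species}_h{i:06d}",
                species=species,
                length=int(lengths[i]),
                mass=float(lengths[i]) * 110.0,
                phospho_sites=_draw_sites(rng, int(counts[i]), int(lengths[i])),
                homology_group=i + 1,
            )
            for i in range(n_pairs)
        ]

    recs_a = _records(species_a, counts_a)
    recs_b = _records(species_b, counts_b)
    table = HomologyTable(
        groups={
            i + 1: {
                species_a: [recs_a[i].accession],
                species_b: [recs_b[i].accession],
            }
            for i in range(n_pairs)
        }
    )
    return table, recs_a, recs_b


# ---------------------------------------------------------------------------
# interaction network with degree-phosphorylation coupling

def simulate_interactions(
    cfg: SyntheticConfig, proteins: Sequence[ProteinRecord]
) -> InteractionTable:
    """Random graph whose expected degree grows with phospho-site count.

    Chung-Lu style: node weight w_i = exp(coupling * x_i) with x_i the
    standardised log(1 + site count); edge probability is
    density * w_i * w_j / mean(w)^2, clipped to 1.  Coupling 0 collapses to
    an Erdos-Renyi graph independent of site counts.
    """
    rng = _rng(cfg.seed, "interactions")
    n = len(proteins)
    counts = np.array([p.site_count for p in proteins], dtype=float)
    x = np.log1p(counts)
    sd = x.std()
    x = (x - x.mean()) / sd if sd > 0 else np.zeros(n)
    w = np.exp(cfg.degree_coupling * x)
    w /= w.mean()
    ii, jj = np.triu_indices(n, k=1)
    p = np.clip(cfg.edge_density * w[ii] * w[jj], 0.0, 1.0)
    hit = rng.uniform(size=p.size) < p
    # edge scores: most above the 0.7 STRING-style confidence cut
    scores = np.round(rng.uniform(0.701, 0.999, size=int(hit.sum())), 3)
    table = InteractionTable(score_scale="unit")
    accs = [prot.accession for prot in proteins]
    for (i, j), s in zip(zip(ii[hit], jj[hit]), scores):
        table.add(accs[i], accs[j], float(s))
    return table


# ---------------------------------------------------------------------------
# kinase target sets with planted Euler regions

def simulate_kinase_targets(cfg: SyntheticConfig) -> KinaseTargetMap:
    """Construct kinase-group target sets whose Euler-region cardinalities
    equal ``cfg.kinase_region_counts`` exactly (set construction, no noise)."""
    groups: dict[str, set[str]] = {}
    idx = 0
    for signature in sorted(cfg.kinase_region_counts, key=lambda s: (len(s), s)):
        count = cfg.kinase_region_counts[signature]
        if count < 0:
            raise ConfigError("region cardinality must be >= 0")
        for _ in range(count):
            acc = f"T{idx:06d}"
            idx += 1
            for name in signature:
                groups.setdefault(name, set()).add(acc)
    return KinaseTargetMap(
        groups={name: frozenset(t) for name, t in groups.items()}
    )


# ---------------------------------------------------------------------------
# time course with a planted active module

def _pick_module(
    rng: np.random.Generator, graph, size: int
) -> frozenset[str]:
    """Random connected node set of the requested size (BFS ball)."""
    import networkx as nx

    components = [c for c in nx.connected_components(graph) if len(c) >= size]
    if not components:
        raise ConfigError(
            f"no connected component of size >= {size} to plant a module in"
        )
    comp = components[int(rng.integers(len(components)))]
    nodes = sorted(comp)
    start = nodes[int(rng.integers(len(nodes)))]
    module: list[str] = []
    seen = {start}
    frontier = [start]
    while frontier and len(module) < size:
        node = frontier.pop(0)
        module.append(node)
        neighbors = sorted(set(graph.neighbors(node)) - seen)
        rng.shuffle(neighbors)
        seen.update(neighbors)
        frontier.extend(neighbors)
    return frozenset(module[:size])


def simulate_timecourse(
    cfg: SyntheticConfig, interactions: InteractionTable
) -> tuple[TimeCourseTable, frozenset[str]]:
    """SILAC-style time course with one planted differentially-phosphorylated
    module on the interaction graph (combined score > 0.7).

    Planted proteins receive, at each time point, the scheduled number of
    sites with |log2FC| >= 1 (magnitudes 1 + |N(0.8, 0.4)|, random sign);
    every other site stays below the threshold except for rare background
    exceedances at ``background_rate``.  Returns the table and the
    ground-truth module node set for recovery benchmarks.
    """
    plant = cfg.module_plant
    graph = interactions.graph(threshold=0.7)
    if plant.size > graph.number_of_nodes():
        raise ConfigError("module size exceeds graph order")
    rng = _rng(cfg.seed, "timecourse")
    module = _pick_module(rng, graph, plant.size)
    accessions = sorted(graph.nodes)
    times = list(cfg.time_points)
    rows_acc: list[str] = []
    rows_pos: list[int] = []
    rows_time: list[int] = []
    rows_fc: list[float] = []
    for acc in accessions:
        in_module = acc in module
        positions = np.arange(1, plant.n_sites + 1)
        for t in times:
            n_exceed = plant.schedule.get(t, 0) if in_module else int(
                rng.binomial(plant.n_sites, plant.background_rate)
            )
            exceed_idx = set(
                rng.choice(plant.n_sites, size=n_exceed, replace=False).tolist()
            )
            for k, pos in enumerate(positions):
                if k in exceed_idx:
                    mag = 1.0 + abs(rng.normal(0.8, 0.4))
                    fc = mag * (1.0 if rng.uniform() < 0.5 else -1.0)
                else:
                    fc = float(np.clip(rng.normal(0.0, 0.3), -0.99, 0.99))
                rows_acc.append(acc)
                rows_pos.append(int(pos))
                rows_time.append(t)
                rows_fc.append(float(fc))
    import pandas as pd

    table = TimeCourseTable(
        records=pd.DataFrame(
            {
                "accession": rows_acc,
                "position": rows_pos,
                "time": rows_time,
                "log2fc": rows_fc,
            }
        ),
        time_points=times,
    )
    return table, module
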