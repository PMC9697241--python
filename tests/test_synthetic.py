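"""Synthetic generators: planted structure, error handling, determinism."""
import numpy as np
import pytest
from scipy import stats

from phosphonet import (
    ConfigError,
    LengthLaw,
    ModulePlant,
    SiteCountLaw,
    SyntheticConfig,
    pair_homolog_values,
    region_counts,
    simulate_homology,
    simulate_interactions,
    simulate_kinase_targets,
    simulate_proteome,
    simulate_timecourse,
    spearman_rho,
    variation_counts,
)


class TestProteome:
    def test_zero_fraction_one_means_no_sites(self):
        cfg = SyntheticConfig(
            seed=7, n_proteins=200,
            site_count_law=SiteCountLaw(zero_fraction=1.0),
        )
        assert all(r.site_count == 0 for r in simulate_proteome(cfg, "s"))

    def test_zero_fraction_recovered_at_large_n(self):
        # binomial se at n=10000, p=0.5 is 0.005; +/-2 se band
        cfg = SyntheticConfig(
            seed=11, n_proteins=10_000,
            site_count_law=SiteCountLaw(zero_fraction=0.5),
        )
        recs = simulate_proteome(cfg, "s")
        frac = sum(r.site_count == 0 for r in recs) / len(recs)
        assert 0.49 <= frac <= 0.51

    def test_cap_above_min_length_rejected(self):
        cfg = SyntheticConfig(
            site_count_law=SiteCountLaw(cap=200),
            length_law=LengthLaw(min_length=100),
        )
        with pytest.raises(ConfigError, match="cap"):
            simulate_proteome(cfg, "s")

    def test_sites_fit_protein_and_are_distinct(self):
        cfg = SyntheticConfig(seed=3, n_proteins=300)
        for r in simulate_proteome(cfg, "s"):
            positions = [s.position for s in r.phospho_sites]
            assert len(set(positions)) == len(positions)
            assert all(1 <= p <= r.length for p in positions)


class TestHomology:
    def test_rho_one_is_exactly_comonotone(self):
        cfg = SyntheticConfig(seed=5, planted_rho=1.0)
        hom, ra, rb = simulate_homology(cfg, "a", "b", 200)
        rho = spearman_rho(pair_homolog_values(hom, ra, rb))
        assert rho == 1.0

    def test_rho_zero_within_null_band(self):
        cfg = SyntheticConfig(seed=5, planted_rho=0.0)
        hom, ra, rb = simulate_homology(cfg, "a", "b", 2000)
        rho = spearman_rho(pair_homolog_values(hom, ra, rb))
        assert abs(rho) < 0.05  # null sd ~ 1/sqrt(2000) ~ 0.022

    def test_planted_rho_recovered(self):
        cfg = SyntheticConfig(seed=5, planted_rho=0.6)
        hom, ra, rb = simulate_homology(cfg, "a", "b", 2000)
        rho = spearman_rho(pair_homolog_values(hom, ra, rb))
        assert 0.55 <= rho <= 0.65

    def test_too_few_pairs_refused(self):
        with pytest.raises(ConfigError, match="n_pairs"):
            simulate_homology(SyntheticConfig(), "a", "b", 5)


class TestInteractions:
    def _spearman_sites_degree(self, cfg, n):
        cfg.n_proteins = n
        recs = simulate_proteome(cfg, "s")
        table = simulate_interactions(cfg, recs)
        g = table.graph(0.0)
        deg = dict(g.degree())
        sites = [r.site_count for r in recs]
        degrees = [deg.get(r.accession, 0) for r in recs]
        return stats.spearmanr(sites, degrees).statistic

    def test_zero_coupling_is_uncoupled(self):
        cfg = SyntheticConfig(seed=9, degree_coupling=0.0)
        rho = self._spearman_sites_degree(cfg, 1000)
        assert abs(rho) < 3 / np.sqrt(1000)  # ~3 null sd

    def test_strong_coupling_links_degree_to_sites(self):
        cfg = SyntheticConfig(seed=9, degree_coupling=5.0)
        assert self._spearman_sites_degree(cfg, 1000) > 0.5

    def test_zero_density_gives_empty_graph(self):
        cfg = SyntheticConfig(seed=9, edge_density=0.0, n_proteins=100)
        recs = simulate_proteome(cfg, "s")
        assert len(simulate_interactions(cfg, recs)) == 0


class TestKinaseTargets:
    def test_planted_regions_recovered_exactly(self):
        planted = {("AGC",): 5, ("TK",): 3, ("AGC", "TK"): 2}
        cfg = SyntheticConfig(kinase_region_counts=planted)
        kmap = simulate_kinase_targets(cfg)
        assert len(kmap.groups["AGC"]) == 7
        assert len(kmap.groups["TK"]) == 5
        assert region_counts(kmap).cardinalities() == planted

    def test_single_region(self):
        cfg = SyntheticConfig(kinase_region_counts={("CK1",): 4})
        kmap = simulate_kinase_targets(cfg)
        assert kmap.groups == {"CK1": kmap.groups["CK1"]}
        assert len(kmap.groups["CK1"]) == 4

    def test_all_zero_regions_give_empty_map(self):
        cfg = SyntheticConfig(kinase_region_counts={("AGC",): 0})
        assert simulate_kinase_targets(cfg).groups == {}

    def test_unknown_group_name_rejected(self):
        with pytest.raises(ConfigError, match="unknown kinase group"):
            SyntheticConfig(kinase_region_counts={("NOPE",): 3})


class TestTimecourse:
    def _cfg(self, seed=13, **plant):
        return SyntheticConfig(
            seed=seed, n_proteins=300,
            module_plant=ModulePlant(**plant),
        )

    def test_zero_background_rate_isolates_planted(self):
        cfg = self._cfg(background_rate=0.0)
        recs = simulate_proteome(cfg, "s")
        tc, module = simulate_timecourse(cfg, simulate_interactions(cfg, recs))
        counts = variation_counts(tc)
        nonzero = {
            acc for per in counts.values() for acc, c in per.items() if c > 0
        }
        assert nonzero == set(module)

    def test_schedule_peak_shows_in_counts(self):
        cfg = self._cfg(schedule={1: 1, 5: 2, 10: 3, 15: 5, 20: 2, 30: 1})
        recs = simulate_proteome(cfg, "s")
        tc, module = simulate_timecourse(cfg, simulate_interactions(cfg, recs))
        counts = variation_counts(tc)
        means = {
            t: np.mean([per[acc] for acc in module])
            for t, per in counts.items()
        }
        assert max(means, key=means.get) == 15

    def test_module_size_exceeding_graph_rejected(self):
        cfg = self._cfg(size=10_000)
        recs = simulate_proteome(cfg, "s")
        with pytest.raises(ConfigError):
            simulate_timecourse(cfg, simulate_interactions(cfg, recs))


class TestDeterminism:
    """Bit-identical output under a fixed seed, for every generator."""

    def test_all_generators_deterministic(self):
        cfg = SyntheticConfig(seed=21, n_proteins=200)

        def run():
            recs = simulate_proteome(cfg, "s")
            hom = simulate_homology(cfg, "a", "b", 50)
            inter = simulate_interactions(cfg, recs)
            kin = simulate_kinase_targets(cfg)
            tc, module = simulate_timecourse(cfg, inter)
            return recs, hom, inter, kin, tc, module

        r1, h1, i1, k1, t1, m1 = run()
        r2, h2, i2, k2, t2, m2 = run()
        assert r1 == r2
        assert h1[0].groups == h2[0].groups and h1[1] == h2[1] and h1[2] == h2[2]
        assert i1.edges == i2.edges
        assert k1.groups == k2.groups
        assert t1.records.equals(t2.records) and m1 == m2

    def test_different_seeds_differ(self):
        a = simulate_proteome(SyntheticConfig(seed=1, n_proteins=100), "s")
        b = simulate_proteome(SyntheticConfig(seed=2, n_proteins=100), "s")
        assert a != b
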