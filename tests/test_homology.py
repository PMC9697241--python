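"""Homolog pairing, Spearman correlation, strength bands, regressions."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phosphonet import (
    HomologyTable,
    classify_strength,
    correlation_matrix,
    mass_site_regression,
    pair_homolog_values,
    spearman_rho,
)
from tests.conftest import make_record


def average_rank_pearson(pairs):
    """Independent oracle: Pearson correlation of average (midrank) ranks."""

    def midranks(values):
        values = np.asarray(values, dtype=float)
        order = np.argsort(values, kind="stable")
        ranks = np.empty(len(values))
        i = 0
        sorted_vals = values[order]
        while i < len(values):
            j = i
            while j < len(values) and sorted_vals[j] == sorted_vals[i]:
                j += 1
            ranks[order[i:j]] = (i + j + 1) / 2.0  # average of 1-based ranks
            i = j
        return ranks

    x, y = zip(*pairs)
    rx, ry = midranks(x), midranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])


class TestPairing:
    def _setup(self):
        hom = HomologyTable(groups={
            1: {"A": ["P1"], "B": ["Q1"]},
            2: {"A": ["P2", "P3"], "B": ["Q2"]},
        })
        recs_a = [
            make_record("P1", species="A", n_sites=4),
            make_record("P2", species="A", n_sites=2),
            make_record("P3", species="A", n_sites=4),
        ]
        recs_b = [
            make_record("Q1", species="B", n_sites=6),
            make_record("Q2", species="B", n_sites=5),
        ]
        return hom, recs_a, recs_b

    def test_one_pair_per_shared_hid(self):
        hom, ra, rb = self._setup()
        assert pair_homolog_values(hom, ra, rb) == [(4.0, 6.0), (3.0, 5.0)]

    def test_paralogs_aggregated_by_mean(self):
        hom, ra, rb = self._setup()
        pairs = dict(pair_homolog_values(hom, ra, rb))
        assert pairs[3.0] == 5.0  # (2 + 4) / 2 on the A side

    def test_no_shared_hid_gives_empty(self):
        hom = HomologyTable(groups={1: {"A": ["P1"]}})
        assert pair_homolog_values(
            hom, [make_record("P1", species="A")], [make_record("Q", species="B")]
        ) == []


class TestSpearman:
    def test_comonotone_and_antitone(self):
        up = [(i, i * 2) for i in range(10)]
        down = [(i, -i) for i in range(10)]
        assert spearman_rho(up) == pytest.approx(1.0)
        assert spearman_rho(down) == pytest.approx(-1.0)

    def test_matches_average_rank_pearson_on_swapped_pairs(self):
        pairs = [(1, 2), (2, 1), (3, 4), (4, 3), (5, 6),
                 (6, 5), (7, 8), (8, 7), (9, 10), (10, 9)]
        assert spearman_rho(pairs) == pytest.approx(average_rank_pearson(pairs))

    def test_matches_oracle_on_random_tied_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(10, 40))
            pairs = list(zip(rng.integers(0, 5, n), rng.integers(0, 5, n)))
            if len({x for x, _ in pairs}) == 1 or len({y for _, y in pairs}) == 1:
                continue
            assert spearman_rho(pairs) == pytest.approx(
                average_rank_pearson(pairs), abs=1e-12
            )

    def test_too_few_pairs_refused(self):
        with pytest.raises(ValueError):
            spearman_rho([(1, 2)] * 9)

    def test_zero_variance_is_undefined(self):
        assert np.isnan(spearman_rho([(1.0, y) for y in range(10)]))

    @given(
        st.lists(
            st.tuples(st.integers(0, 50), st.integers(0, 50)),
            min_size=10, max_size=40,
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_invariant_under_monotone_transform(self, pairs):
        xs = {x for x, _ in pairs}
        ys = {y for _, y in pairs}
        if len(xs) == 1 or len(ys) == 1:
            return
        transformed = [(np.exp(x / 10), y**3 + 2 * y) for x, y in pairs]
        assert spearman_rho(pairs) == pytest.approx(
            spearman_rho(transformed), abs=1e-12
        )


class TestStrengthBands:
    @pytest.mark.parametrize(
        "rho,label",
        [
            (0.65, "strong"),
            (0.61, "strong"),
            (0.6, "moderate"),   # boundary falls to the lower band
            (0.5, "moderate"),
            (0.4, "weak"),
            (0.2, "weak"),
            (0.1, "below-weak"),
            (-0.3, "below-weak"),
        ],
    )
    def test_bands(self, rho, label):
        assert classify_strength(rho) == label

    def test_undefined_rho_rejected(self):
        with pytest.raises(ValueError):
            classify_strength(float("nan"))


class TestCorrelationMatrix:
    def test_symmetric_with_unit_diagonal(self):
        hom = HomologyTable(groups={
            i: {"A": [f"P{i}"], "B": [f"Q{i}"]} for i in range(1, 21)
        })
        ra = [make_record(f"P{i}", species="A", n_sites=i) for i in range(1, 21)]
        rb = [make_record(f"Q{i}", species="B", n_sites=i) for i in range(1, 21)]
        df = correlation_matrix(hom, {"A": ra, "B": rb}).set_index(
            ["species_a", "species_b"]
        )
        assert df.loc[("A", "A"), "rho"] == 1.0
        assert df.loc[("A", "B"), "rho"] == df.loc[("B", "A"), "rho"] == pytest.approx(1.0)
        assert df.loc[("A", "B"), "strength"] == "strong"


class TestMassSiteRegression:
    def test_mass_cap_is_strict(self):
        recs = [
            make_record("P1", mass=600_000.0, n_sites=5),
            make_record("P2", mass=10_000.0, n_sites=1),
            make_record("P3", mass=20_000.0, n_sites=3),
        ]
        fit = mass_site_regression(recs)
        assert fit.n == 2  # the 600 kDa protein is excluded

    def test_two_point_closed_form(self):
        recs = [
            make_record("P1", mass=10_000.0, n_sites=1),
            make_record("P2", mass=20_000.0, n_sites=3),
        ]
        fit = mass_site_regression(recs)
        assert fit.slope == pytest.approx(2e-4)
        assert fit.intercept == pytest.approx(-1.0)

    def test_constant_y_gives_zero_slope(self):
        recs = [make_record(f"P{i}", mass=1e4 * (i + 1), n_sites=2)
                for i in range(4)]
        fit = mass_site_regression(recs)
        assert fit.slope == 0.0 and fit.intercept == 2.0

    def test_residuals_sum_to_zero(self):
        rng = np.random.default_rng(1)
        recs = [
            make_record(f"P{i}", mass=float(m), n_sites=int(s))
            for i, (m, s) in enumerate(
                zip(rng.uniform(1e4, 4e5, 50), rng.integers(1, 400, 50))
            )
        ]
        fit = mass_site_regression(recs)
        resid = [
            r.site_count - (fit.intercept + fit.slope * r.mass) for r in recs
        ]
        assert sum(resid) == pytest.approx(0.0, abs=1e-6)

    def test_unphosphorylated_proteins_excluded(self):
        recs = [
            make_record("P0", mass=5e4, n_sites=0),
            make_record("P1", mass=1e4, n_sites=1),
            make_record("P2", mass=2e4, n_sites=3),
        ]
        assert mass_site_regression(recs).n == 2

    def test_too_few_survivors_rejected(self):
        with pytest.raises(ValueError):
            mass_site_regression([make_record("P1", mass=1e4, n_sites=1)])
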