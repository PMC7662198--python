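"""Diversity and turnover metrics against hand arithmetic and brute-force
oracles (explicit set algebra for the Jaccard exchange ratio; dense
union-indexed vectors for the Wishart dissimilarity)."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ecoturn.errors import UndefinedMetricError, ValidationError
from ecoturn.metrics import (
    all_pairs_metrics,
    coefficient_of_variation,
    consecutive_metrics,
    delta_richness,
    effective_number_of_species,
    richness,
    ser_a,
    ser_r,
)
from ecoturn.types import CommunityTimeSeries

from conftest import make_assemblage


# -- independent oracles ------------------------------------------------------

def brute_ser_r(a, b):
    sa = {t for t, v in a.abundances.items() if v > 0}
    sb = {t for t, v in b.abundances.items() if v > 0}
    changed = len(sa - sb) + len(sb - sa)
    return changed / len(sa | sb)


def brute_ser_a(a, b):
    union = sorted(
        {t for t, v in a.abundances.items() if v > 0}
        | {t for t, v in b.abundances.items() if v > 0}
    )
    x = np.array([a.abundances.get(t, 0.0) for t in union])
    y = np.array([b.abundances.get(t, 0.0) for t in union])
    x, y = x / x.sum(), y / y.sum()
    return 1.0 - (x @ y) / (x @ x + y @ y - x @ y)


# -- standing diversity -------------------------------------------------------

class TestRichnessAndEns:
    def test_richness_counts_positive_taxa(self):
        assert richness(make_assemblage({"spA": 3.0, "spB": 1.0})) == 2
        assert richness(make_assemblage({"spA": 3.0, "spB": 0.0})) == 1

    def test_richness_undefined_on_empty(self):
        with pytest.raises(UndefinedMetricError):
            richness(make_assemblage({"spA": 0.0}))

    @pytest.mark.parametrize("s", [1, 2, 20, 100])
    def test_even_community_has_ens_equal_richness(self, s):
        a = make_assemblage({f"t{i}": 1.0 for i in range(s)})
        assert effective_number_of_species(a) == pytest.approx(s, abs=1e-12)

    def test_skewed_two_taxon_community(self):
        # p = (0.9, 0.1): ENS = 1 / (0.81 + 0.01)
        a = make_assemblage({"spA": 0.9, "spB": 0.1})
        assert effective_number_of_species(a) == pytest.approx(1 / 0.82, abs=1e-12)

    def test_ens_against_skbio_enspie(self):
        from skbio.diversity.alpha import enspie

        rng = np.random.default_rng(11)
        for _ in range(50):
            counts = rng.integers(0, 40, size=12)
            if counts.sum() == 0:
                continue
            a = make_assemblage({f"t{i}": float(c) for i, c in enumerate(counts)})
            assert effective_number_of_species(a) == pytest.approx(
                enspie(counts), abs=1e-10
            )

    @given(st.lists(st.floats(0.01, 1000), min_size=1, max_size=40))
    def test_ens_bounded_by_richness(self, values):
        a = make_assemblage({f"t{i}": v for i, v in enumerate(values)})
        ens = effective_number_of_species(a)
        assert 1.0 - 1e-9 <= ens <= richness(a) + 1e-9


# -- pairwise turnover --------------------------------------------------------

class TestPairwiseExamples:
    def test_delta_richness_is_net_immigration(self):
        a = make_assemblage({"x": 1.0, "y": 1.0}, year=2000)
        b = make_assemblage({"y": 1.0, "z": 1.0, "w": 1.0}, year=2001)
        assert delta_richness(a, b) == 1  # 2 immigrations - 1 extinction
        assert delta_richness(b, a) == -1

    def test_cross_series_pair_rejected(self):
        a = make_assemblage({"x": 1.0}, series_id="s1")
        b = make_assemblage({"x": 1.0}, series_id="s2", year=2001)
        with pytest.raises(ValidationError):
            delta_richness(a, b)

    def test_ser_r_shared_two_of_four(self):
        a = make_assemblage({"a": 1, "b": 1, "c": 1}, year=2000)
        b = make_assemblage({"b": 1, "c": 1, "d": 1}, year=2001)
        assert ser_r(a, b) == pytest.approx(0.5, abs=1e-15)

    def test_ser_r_boundaries_by_set_logic(self):
        a = make_assemblage({"a": 1.0, "b": 2.0}, year=2000)
        same = make_assemblage({"a": 9.0, "b": 0.5}, year=2001)
        disjoint = make_assemblage({"c": 1.0}, year=2001)
        assert ser_r(a, same) == 0.0
        assert ser_r(a, disjoint) == 1.0

    def test_ser_a_dominance_swap(self):
        # x=(0.8,0.2) vs y=(0.2,0.8): 1 - 0.32/1.04, while ser_r = 0
        a = make_assemblage({"a": 0.8, "b": 0.2}, year=2000)
        b = make_assemblage({"a": 0.2, "b": 0.8}, year=2001)
        assert ser_a(a, b) == pytest.approx(1 - 0.32 / 1.04, abs=1e-12)
        assert ser_r(a, b) == 0.0

    def test_ser_a_boundaries(self):
        a = make_assemblage({"a": 2.0, "b": 1.0}, year=2000)
        scaled = make_assemblage({"a": 4.0, "b": 2.0}, year=2001)
        disjoint = make_assemblage({"c": 1.0}, year=2001)
        assert ser_a(a, scaled) == 0.0  # identical proportions
        assert ser_a(a, disjoint) == 1.0

    def test_ser_a_total_abundance_invariance(self):
        a = make_assemblage({"a": 5.0, "b": 1.0, "c": 0.4}, year=2000)
        b = make_assemblage({"b": 2.0, "c": 3.0, "d": 1.0}, year=2001)
        b10 = make_assemblage({t: 10 * v for t, v in b.abundances.items()}, year=2001)
        assert ser_a(a, b10) == pytest.approx(ser_a(a, b), abs=1e-14)

    def test_raw_abundance_mode_sees_biomass_change(self):
        a = make_assemblage({"a": 1.0, "b": 1.0}, year=2000)
        b = make_assemblage({"a": 10.0, "b": 10.0}, year=2001)
        assert ser_a(a, b, proportions=True) == 0.0
        assert ser_a(a, b, proportions=False) > 0.5

    def test_explicit_zeros_do_not_alter_metrics(self):
        a = make_assemblage({"a": 1.0, "b": 1.0, "ghost": 0.0}, year=2000)
        b = make_assemblage({"a": 1.0, "b": 1.0, "ghost": 0.0}, year=2001)
        assert ser_r(a, b) == 0.0
        assert ser_a(a, b) == 0.0

    def test_dominance_decoupling_construction(self):
        # two-taxon dominance swap with proportions (1-eps, eps):
        # delta_s = 0, ser_r = 0, ser_a -> 1 as eps -> 0
        eps = 1e-4
        a = make_assemblage({"a": 1 - eps, "b": eps}, year=2000)
        b = make_assemblage({"a": eps, "b": 1 - eps}, year=2001)
        assert delta_richness(a, b) == 0
        assert ser_r(a, b) == 0.0
        assert ser_a(a, b) > 0.999


class TestOracleEquivalence:
    def test_ser_r_and_ser_a_match_brute_force(self, random_assemblage_pairs):
        for a, b in random_assemblage_pairs(1000, seed=5):
            assert abs(ser_r(a, b) - brute_ser_r(a, b)) <= 1e-12
            assert abs(ser_a(a, b) - brute_ser_a(a, b)) <= 1e-12

    def test_ser_r_matches_scipy_jaccard(self, random_assemblage_pairs):
        from scipy.spatial.distance import jaccard

        for a, b in random_assemblage_pairs(100, seed=6):
            union = sorted(a.presence_set() | b.presence_set())
            xa = [t in a.presence_set() for t in union]
            xb = [t in b.presence_set() for t in union]
            assert ser_r(a, b) == pytest.approx(jaccard(xa, xb), abs=1e-12)

    def test_symmetry_and_bounds(self, random_assemblage_pairs):
        for a, b in random_assemblage_pairs(200, seed=7):
            r_ab, r_ba = ser_r(a, b), ser_r(b, a)
            a_ab, a_ba = ser_a(a, b), ser_a(b, a)
            assert r_ab == r_ba and a_ab == pytest.approx(a_ba, abs=1e-14)
            assert 0.0 <= r_ab <= 1.0 and 0.0 <= a_ab <= 1.0
            assert delta_richness(a, b) == -delta_richness(b, a)

    @pytest.mark.parametrize("s,k", [(10, 0), (10, 3), (50, 5), (7, 7)])
    def test_fixed_replacement_closed_form(self, s, k):
        shared = {f"shared{i}": 1.0 for i in range(s - k)}
        a = make_assemblage({**shared, **{f"olda{i}": 1.0 for i in range(k)}},
                            year=2000)
        b = make_assemblage({**shared, **{f"newb{i}": 1.0 for i in range(k)}},
                            year=2001)
        assert ser_r(a, b) == pytest.approx(2 * k / (s + k), abs=1e-15)


# -- series-level application -------------------------------------------------

def _series(years_abunds, series_id="s1"):
    assemblages = [
        make_assemblage(ab, series_id=series_id, year=y) for y, ab in years_abunds
    ]
    return CommunityTimeSeries(series_id=series_id, assemblages=assemblages)


class TestSeriesMetrics:
    def test_consecutive_uses_calendar_adjacency(self):
        s = _series([(2001, {"a": 1}), (2002, {"a": 1}), (2003, {"a": 1})])
        pairs = consecutive_metrics(s)
        assert [(p.year_from, p.year_to) for p in pairs] == [(2001, 2002), (2002, 2003)]
        assert all(p.lag == 1 for p in pairs)

    def test_gap_years_are_not_bridged(self):
        s = _series([(2001, {"a": 1}), (2003, {"a": 1})])
        with pytest.warns(UserWarning, match="no valid adjacent-year pairs"):
            assert consecutive_metrics(s) == []

    def test_empty_year_breaks_adjacency(self):
        s = _series([(2001, {"a": 1}), (2002, {"a": 0.0}), (2003, {"a": 1})])
        with pytest.warns(UserWarning):
            assert consecutive_metrics(s) == []

    def test_unbroken_series_yields_n_minus_1_pairs(self):
        s = _series([(2000 + i, {"a": 1.0, "b": float(i + 1)}) for i in range(10)])
        assert len(consecutive_metrics(s)) == 9

    def test_all_pairs_count_and_lags(self):
        s = _series([(2001, {"a": 1}), (2003, {"a": 1}), (2004, {"b": 1}),
                     (2006, {"a": 1})])
        pairs = all_pairs_metrics(s)
        assert len(pairs) == 6
        assert sorted(p.lag for p in pairs) == [1, 2, 2, 3, 3, 5]

    def test_identical_assemblages_have_zero_turnover(self):
        s = _series([(2000 + i, {"a": 2.0, "b": 1.0}) for i in range(4)])
        for p in all_pairs_metrics(s):
            assert p.ser_r == 0.0 and p.ser_a == 0.0 and p.delta_s == 0


class TestCoefficientOfVariation:
    def test_constant_values_have_zero_cv(self):
        assert coefficient_of_variation([2, 2, 2]) == 0.0

    def test_two_point_hand_value(self):
        # sd = sqrt(2), mean = 2
        assert coefficient_of_variation([1, 3]) == pytest.approx(
            100 * np.sqrt(2) / 2, abs=1e-9
        )

    def test_scale_invariance(self):
        vals = [1.0, 4.0, 2.5, 3.0]
        assert coefficient_of_variation([10 * v for v in vals]) == pytest.approx(
            coefficient_of_variation(vals), abs=1e-9
        )

    @pytest.mark.parametrize("bad", [[1.0], [1.0, -1.0]])
    def test_undefined_cases(self, bad):
        with pytest.raises(UndefinedMetricError):
            coefficient_of_variation(bad)
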