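"""Monthly matrix construction, grouping, seasonal averaging, biomass."""

import numpy as np
import pandas as pd
import pytest

from commsync.community_data import (
    AbundanceMatrix,
    BodyMassTable,
    GroupScheme,
    build_monthly_matrix,
    group_sum,
    seasonal_mean,
    select_frequent,
    split_period,
    to_biomass,
)


class TestBuildMonthlyMatrix:
    def test_max_and_zero_fill(self):
        records = [(1981, 1, "A", 3), (1981, 1, "A", 7), (1981, 2, "A", 0)]
        m = build_monthly_matrix(records, ["A", "B"], ((1981, 1), (1981, 2)))
        assert m.units == ["A", "B"]
        np.testing.assert_array_equal(m.values, [[7.0, 0.0], [0.0, 0.0]])

    def test_empty_records_zero_fill(self):
        m = build_monthly_matrix([], ["A"], ((1981, 1), (1981, 3)))
        np.testing.assert_array_equal(m.values, np.zeros((3, 1)))

    def test_matches_brute_force_cell_max(self, rng):
        """Random records equal an exhaustive per-cell max scan."""
        records = [
            (1990 + int(rng.integers(0, 2)), int(rng.integers(1, 13)),
             rng.choice(list("ABCDE")), int(rng.integers(0, 50)))
            for _ in range(300)
        ]
        m = build_monthly_matrix(records, list("ABCDE"), ((1990, 1), (1991, 12)))
        for t, per in enumerate(m.times):
            for j, sp in enumerate(m.units):
                cell = [
                    c for (y, mo, s, c) in records
                    if y == per.year and mo == per.month and s == sp
                ]
                assert m.values[t, j] == (max(cell) if cell else 0.0)

    def test_rejects_bad_records(self):
        with pytest.raises(ValueError, match="negative"):
            build_monthly_matrix([(1981, 1, "A", -1)], ["A"], ((1981, 1), (1981, 1)))
        with pytest.raises(ValueError, match="month"):
            build_monthly_matrix([(1981, 13, "A", 1)], ["A"], ((1981, 1), (1981, 1)))

    def test_long_format_round_trip(self, random_matrix, tmp_path):
        long = random_matrix.to_long()
        rebuilt = build_monthly_matrix(long)
        pd.testing.assert_frame_equal(rebuilt.data, random_matrix.data)
        # delimited matrix round trip too
        random_matrix.write(tmp_path / "m.tsv")
        again = AbundanceMatrix.read(tmp_path / "m.tsv")
        pd.testing.assert_frame_equal(again.data, random_matrix.data)


class TestSelectFrequent:
    def test_ranks_by_occupancy(self):
        vals = np.zeros((10, 3))
        vals[:10, 0] = 1.0  # 10 nonzero months
        vals[:5, 1] = 1.0  # 5
        m = AbundanceMatrix.from_values(vals, ["A", "B", "C"])
        assert select_frequent(m, 2).units == ["A", "B"]

    def test_tie_breaks_by_total_abundance(self):
        vals = np.ones((6, 2))
        vals[:, 1] *= 3.0  # same occupancy, larger total
        m = AbundanceMatrix.from_values(vals, ["A", "B"])
        assert select_frequent(m, 1).units == ["B"]

    def test_matches_sort_oracle(self, rng):
        vals = rng.poisson(2.0, size=(36, 20)).astype(float)
        m = AbundanceMatrix.from_values(vals, [f"s{i:02d}" for i in range(20)])
        got = set(select_frequent(m, 10).units)
        occ = (vals > 0).sum(0)
        tot = vals.sum(0)
        oracle = sorted(
            range(20), key=lambda j: (-occ[j], -tot[j], f"s{j:02d}")
        )[:10]
        assert got == {f"s{j:02d}" for j in oracle}

    def test_k_out_of_range(self, random_matrix):
        with pytest.raises(ValueError):
            select_frequent(random_matrix, 99)


class TestGroupSum:
    def test_sums_members(self):
        m = AbundanceMatrix.from_values(np.array([[1.0, 2.0]]), ["A", "B"])
        g = group_sum(m, GroupScheme("one", {"A": "G", "B": "G"}))
        assert g.units == ["G"]
        assert g.values[0, 0] == 3.0

    def test_singleton_groups_restrict(self, random_matrix):
        scheme = GroupScheme("solo", {"A": "gA", "C": "gC"})
        g = group_sum(random_matrix, scheme)
        np.testing.assert_array_equal(g.data["gA"], random_matrix.data["A"])
        np.testing.assert_array_equal(g.data["gC"], random_matrix.data["C"])

    def test_matches_column_sum_oracle(self, random_matrix):
        scheme = GroupScheme("two", {"A": "g1", "B": "g1", "C": "g2", "D": "g2"})
        g = group_sum(random_matrix, scheme)
        np.testing.assert_allclose(
            g.values,
            np.column_stack([
                random_matrix.values[:, :2].sum(1),
                random_matrix.values[:, 2:4].sum(1),
            ]),
        )

    def test_no_mapped_units_is_error(self, random_matrix):
        with pytest.raises(ValueError, match="maps no unit"):
            group_sum(random_matrix, GroupScheme("none", {"Z": "g"}))

    def test_total_abundance_conserved(self, random_matrix):
        """Summing all species into one group conserves the monthly total."""
        scheme = GroupScheme("all", {u: "all" for u in random_matrix.units})
        g = group_sum(random_matrix, scheme)
        np.testing.assert_allclose(g.values[:, 0], random_matrix.values.sum(1))


class TestSeasonalMean:
    def test_warm_season_mean(self):
        m = build_monthly_matrix([], ["A"], ((1990, 1), (1990, 12)))
        vals = m.data.copy()
        vals.loc["1990-05":"1990-08", "A"] = [1.0, 2.0, 3.0, 6.0]
        s = seasonal_mean(AbundanceMatrix(vals), "warm")
        assert s.years.tolist() == [1990]
        assert s.values[0, 0] == 3.0

    def test_cold_season_straddles_year_boundary(self):
        m = build_monthly_matrix([], ["A"], ((1990, 1), (1991, 12)))
        vals = m.data.copy()
        vals.loc["1990-11", "A"] = 4.0
        vals.loc["1990-12", "A"] = 4.0
        # Jan/Feb 1991 stay 0
        s = seasonal_mean(AbundanceMatrix(vals), "cold")
        assert 1990 in s.years
        assert s.data.loc[1990, "A"] == 2.0

    def test_matches_calendar_slicing_oracle(self, rng):
        vals = rng.poisson(5.0, size=(35 * 12, 3)).astype(float)
        m = AbundanceMatrix.from_values(vals, ["A", "B", "C"], start="1981-01")
        for season, months in (("warm", [5, 6, 7, 8]), ("cold", [11, 12, 13, 14])):
            s = seasonal_mean(m, season)
            for year in s.years:
                rows = []
                for mo in months:
                    y, mm = (year, mo) if mo <= 12 else (year + 1, mo - 12)
                    per = pd.Period(year=y, month=mm, freq="M")
                    rows.append(m.data.loc[per].to_numpy())
                np.testing.assert_allclose(
                    s.data.loc[year].to_numpy(), np.mean(rows, axis=0)
                )

    def test_incomplete_edge_seasons_dropped(self):
        # Dec 1990 .. Jan 1992: cold 1990 misses Nov, cold 1991 complete
        m = build_monthly_matrix([], ["A"], ((1990, 12), (1992, 2)))
        s = seasonal_mean(m, "cold")
        assert s.years.tolist() == [1991]

    def test_constant_matrix_gives_constant_means(self):
        m = AbundanceMatrix.from_values(np.full((48, 2), 7.0), ["A", "B"])
        for season in ("warm", "cold"):
            assert np.all(seasonal_mean(m, season).values == 7.0)

    def test_group_then_average_equals_average_then_sum(self, random_matrix):
        """Linearity: guild sums commute with seasonal averaging."""
        scheme = GroupScheme("two", {"A": "g1", "B": "g1", "C": "g2", "D": "g2"})
        a = seasonal_mean(group_sum(random_matrix, scheme), "warm")
        b = seasonal_mean(random_matrix, "warm")
        np.testing.assert_allclose(
            a.data["g1"], b.data[["A", "B"]].sum(1)
        )
        np.testing.assert_allclose(
            a.data["g2"], b.data[["C", "D"]].sum(1)
        )

    def test_no_complete_season_is_error(self):
        m = build_monthly_matrix([], ["A"], ((1990, 1), (1990, 3)))
        with pytest.raises(ValueError):
            seasonal_mean(m, "warm")


class TestSplitPeriod:
    def test_cut_year_goes_to_post(self, rng):
        vals = rng.random((5, 2)) + 1
        from commsync.community_data import SeasonalSeries

        s = SeasonalSeries.from_values(vals, season="warm", start_year=2004)
        pre, post = split_period(s, 2006)
        assert pre.years.tolist() == [2004, 2005]
        assert post.years.tolist() == [2006, 2007, 2008]
        assert pre.period == "pre2006" and post.period == "post2006"

    @pytest.mark.parametrize("cut,empty", [(2000, "pre"), (2020, "post")])
    def test_empty_side_flagged(self, rng, cut, empty):
        from commsync.community_data import SeasonalSeries

        s = SeasonalSeries.from_values(rng.random((5, 2)), season="warm", start_year=2004)
        with pytest.warns(UserWarning, match="empty period"):
            pre, post = split_period(s, cut)
        assert (pre if empty == "pre" else post).n_years == 0


class TestToBiomass:
    def test_multiplies_by_mass(self):
        m = AbundanceMatrix.from_values(np.array([[10.0]]), ["A"])
        b = to_biomass(m, BodyMassTable({"A": 60.0}))
        assert b.values[0, 0] == 600.0

    def test_unit_masses_identity(self, random_matrix):
        b = to_biomass(random_matrix, {u: 1.0 for u in random_matrix.units})
        np.testing.assert_array_equal(b.values, random_matrix.values)

    def test_matches_elementwise_oracle(self, random_matrix, rng):
        masses = {u: float(rng.uniform(10, 500)) for u in random_matrix.units}
        b = to_biomass(random_matrix, masses)
        np.testing.assert_allclose(
            b.values,
            random_matrix.values * np.array([masses[u] for u in random_matrix.units]),
        )

    def test_missing_mass_names_species(self, random_matrix):
        with pytest.raises(KeyError, match="E"):
            to_biomass(random_matrix, {u: 1.0 for u in "ABCD"})

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            BodyMassTable({"A": 0.0})
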