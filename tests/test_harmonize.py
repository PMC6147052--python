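"""Flux-report harmonization: classification, basis conversions, pooling
and gap-filling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peatflux import refdata
from peatflux.constants import Constants
from peatflux.harmonize import (
    ClassificationError,
    aggregate_emission_factors,
    annual_to_seasonal,
    classify_peatland,
    daily_to_seasonal,
    fill_missing_factors,
    harmonize_records,
    regional_summary,
    seasonal_to_daily_ch4,
    seasonal_to_daily_nee,
    winter_rate_reference,
)


class TestClassifyPeatland:
    @pytest.mark.parametrize(
        "ph,source,notes,expected",
        [
            (6.2, "geogenous", "brown mosses", "rich_fen"),
            (4.5, "geogenous", "Sphagnum lawn", "poor_fen"),
            (None, "ombrotrophic", "oligotrophic Sphagnum", "bog"),
            (None, "geogenous", "brown moss carpet", "rich_fen"),
            (None, "geogenous", "Sphagnum-dominated", "poor_fen"),
            (None, "unknown", "Sphagnum hummocks", "bog"),
            (7.0, "unknown", "sedges", "unknown"),
        ],
    )
    def test_evidence_combinations(self, ph, source, notes, expected):
        assert classify_peatland(ph, source, notes) == expected

    def test_ph_boundary_splits_fen_types(self):
        assert classify_peatland(5.5, "geogenous", "") == "rich_fen"
        assert classify_peatland(5.499, "geogenous", "") == "poor_fen"

    def test_no_evidence_raises(self):
        with pytest.raises(ClassificationError):
            classify_peatland(None, "unknown", "")


class TestBasisConversions:
    @pytest.mark.parametrize(
        "seasonal,gs,expected",
        [(-300.0, 150, -10.0), (0.0, 150, 0.0), (100.0, 100, 5.0)],
    )
    def test_seasonal_to_daily_nee(self, seasonal, gs, expected):
        assert seasonal_to_daily_nee(seasonal, gs) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "seasonal,gs,expected",
        [(6.6, 165, 40.0), (0.0, 200, 0.0), (3.3, 150, 22.0)],
    )
    def test_seasonal_to_daily_ch4(self, seasonal, gs, expected):
        assert seasonal_to_daily_ch4(seasonal, gs) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "daily,gs,gas,expected",
        [(-10.0, 150, "NEE", -300.0), (40.0, 165, "CH4", 6.6)],
    )
    def test_daily_to_seasonal(self, daily, gs, gas, expected):
        assert daily_to_seasonal(daily, gs, gas) == pytest.approx(expected)

    def test_nonpositive_season_rejected(self):
        for fn in (lambda: seasonal_to_daily_nee(1.0, 0),
                   lambda: seasonal_to_daily_ch4(1.0, -5),
                   lambda: daily_to_seasonal(1.0, 0, "NEE")):
            with pytest.raises(ValueError):
                fn()

    @given(
        seasonal=st.floats(-500, 500, allow_nan=False),
        gs=st.integers(50, 300),
    )
    @settings(max_examples=200, derandomize=True)
    def test_round_trip_inversion(self, seasonal, gs):
        """seasonal -> daily -> seasonal is the identity to < 1e-9 relative."""
        back_nee = daily_to_seasonal(seasonal_to_daily_nee(seasonal, gs), gs, "NEE")
        back_ch4 = daily_to_seasonal(seasonal_to_daily_ch4(seasonal, gs), gs, "CH4")
        assert back_nee == pytest.approx(seasonal, rel=1e-9, abs=1e-12)
        assert back_ch4 == pytest.approx(seasonal, rel=1e-9, abs=1e-12)


class TestAnnualToSeasonal:
    @pytest.mark.parametrize(
        "annual,gs,rate,gas,expected",
        [
            (-100.0, 165, 0.9, "NEE", -280.0),
            (10.0, 165, 7.0, "CH4", 8.6),
        ],
    )
    def test_winter_stripping(self, annual, gs, rate, gas, expected):
        assert annual_to_seasonal(annual, gs, rate, gas) == pytest.approx(expected)

    @given(annual=st.floats(-500, 500, allow_nan=False), gs=st.integers(60, 300))
    @settings(max_examples=100, derandomize=True)
    def test_zero_winter_rate_is_identity(self, annual, gs):
        assert annual_to_seasonal(annual, gs, 0.0, "NEE") == annual


class TestWinterRateReference:
    def test_literature_co2_mean(self):
        assert round(winter_rate_reference(refdata.WINTER_CO2_STUDIES), 1) == 0.9

    def test_literature_ch4_mean(self):
        # brute-force mean of the nine reported values, 61.5/9 = 6.83
        assert round(winter_rate_reference(refdata.WINTER_CH4_STUDIES), 1) == 6.8

    def test_singleton_and_empty(self):
        assert winter_rate_reference([1.5]) == 1.5
        with pytest.raises(ValueError):
            winter_rate_reference([])

    def test_by_study_grouping_pools_microforms(self):
        by_study = winter_rate_reference(refdata.WINTER_CH4_STUDIES, "by_study")
        assert round(by_study, 2) == 6.64


def _harm_frame(rows):
    df = pd.DataFrame(
        rows,
        columns=["study_id", "ecozone", "peatland_class", "microform",
                 "daily_nee", "daily_ch4"],
    )
    return df


class TestAggregateEmissionFactors:
    def test_two_entries_mean_and_se(self):
        tab = aggregate_emission_factors(_harm_frame([
            ("s1", "Boreal Plains", "bog", "hummock", -4.0, np.nan),
            ("s2", "Boreal Plains", "bog", "hollow", -6.0, np.nan),
        ]))
        row = tab.iloc[0]
        assert row["mean"] == pytest.approx(-5.0)
        assert row["se"] == pytest.approx(1.0)
        assert row["n"] == 2

    def test_single_entry_has_no_se(self):
        tab = aggregate_emission_factors(_harm_frame([
            ("s1", "Taiga Plains", "bog", "site", -1.3, np.nan),
        ]))
        assert tab.iloc[0]["mean"] == pytest.approx(-1.3)
        assert np.isnan(tab.iloc[0]["se"])

    def test_years_averaged_before_pooling(self):
        # one site measured twice is one entry, not two
        tab = aggregate_emission_factors(_harm_frame([
            ("s1", "Boreal Shield", "bog", "site", -3.0, np.nan),
            ("s1", "Boreal Shield", "bog", "site", -5.0, np.nan),
            ("s2", "Boreal Shield", "bog", "site", -4.0, np.nan),
        ]))
        assert tab.iloc[0]["n"] == 2
        assert tab.iloc[0]["mean"] == pytest.approx(-4.0)

    def test_matches_brute_force_oracle(self, rng):
        rows = []
        for i in range(18):
            rows.append((f"s{i}", "Hudson Plains", "rich_fen", "site",
                         float(rng.normal(-2, 3)), float(rng.lognormal(2, 0.5))))
        df = _harm_frame(rows)
        tab = aggregate_emission_factors(df)
        for gas, col in (("NEE", "daily_nee"), ("CH4", "daily_ch4")):
            vals = df[col].to_numpy()
            row = tab[tab["gas"] == gas].iloc[0]
            assert row["mean"] == pytest.approx(vals.mean())
            assert row["se"] == pytest.approx(vals.std(ddof=1) / np.sqrt(len(vals)))


class TestFillMissingFactors:
    def test_borrows_from_similar_ecozone(self):
        table = refdata.EMISSION_FACTORS_COMBINED.copy()
        table["borrowed_from"] = None
        # blank the Atlantic Maritime fen NEE cell and refill it
        idx = table[(table["ecozone"] == "Atlantic Maritime")
                    & (table["peatland_class"] == "fen")
                    & (table["gas"] == "NEE")].index[0]
        table.loc[idx, ["mean", "se"]] = np.nan
        filled = fill_missing_factors(table)
        row = filled.loc[idx]
        assert row["mean"] == pytest.approx(-1.3)
        assert row["se"] == pytest.approx(2.8)
        assert row["borrowed"] and row["borrowed_from"] == "Mixedwood Plains"

    def test_complete_cell_untouched(self):
        table = refdata.EMISSION_FACTORS_COMBINED.copy()
        table["borrowed"] = False
        table["borrowed_from"] = None
        filled = fill_missing_factors(table)
        assert not filled["borrowed"].any()

    def test_n1_cell_keeps_mean_borrows_se(self):
        table = pd.DataFrame(
            [
                ("Taiga Plains", "bog", "NEE", 1, -1.3, np.nan, False, None),
                ("Boreal Plains", "bog", "NEE", 11, -8.6, 2.7, False, None),
            ],
            columns=["ecozone", "peatland_class", "gas", "n", "mean", "se",
                     "borrowed", "borrowed_from"],
        )
        filled = fill_missing_factors(table)
        row = filled.iloc[0]
        assert row["mean"] == pytest.approx(-1.3)
        assert row["se"] == pytest.approx(2.7)
        assert row["borrowed_from"] == "Boreal Plains"

    def test_unmapped_missing_cell_raises(self):
        table = pd.DataFrame(
            [("Prairie", "bog", "NEE", 0, np.nan, np.nan, False, None)],
            columns=["ecozone", "peatland_class", "gas", "n", "mean", "se",
                     "borrowed", "borrowed_from"],
        )
        with pytest.raises(ValueError, match="Prairie"):
            fill_missing_factors(table)

    def test_borrowed_count_equals_initial_gaps(self):
        table = refdata.EMISSION_FACTORS_SEPARATED.copy()
        gaps = table["borrowed"].sum()
        table.loc[table["borrowed"], ["mean", "se"]] = table.loc[
            table["borrowed"]].apply(
            lambda r: pd.Series([np.nan if r["n"] == 0 else r["mean"], np.nan]),
            axis=1,
        ).to_numpy()
        table["borrowed"] = False
        table["borrowed_from"] = None
        filled = fill_missing_factors(table)
        assert filled["borrowed"].sum() == gaps
        assert not filled["mean"].isna().any()
        assert not filled["se"].isna().any()


class TestRegionalSummary:
    def test_default_region_membership(self, flux_records):
        records, _ = flux_records
        harm = harmonize_records(records)
        out = regional_summary(harm)
        assert set(out["region"]) <= {"temperate", "boreal", "subarctic"}

    def test_unmapped_ecozone_raises(self):
        df = _harm_frame([("s", "Prairie", "bog", "site", -1.0, np.nan)])
        with pytest.raises(ValueError, match="Prairie"):
            regional_summary(df)

    def test_region_mean_rank_order_recovered(self, rng):
        rows = []
        true = {"temperate": -1.0, "boreal": -8.0, "subarctic": -4.0}
        zones = {"temperate": "Mixedwood Plains", "boreal": "Boreal Plains",
                 "subarctic": "Hudson Plains"}
        for region, mu in true.items():
            for i in range(40):
                rows.append((f"{region}{i}", zones[region], "bog", "site",
                             float(rng.normal(mu, 1.0)), np.nan))
        out = regional_summary(_harm_frame(rows))
        means = out.set_index("region")["mean"]
        assert means["boreal"] < means["subarctic"] < means["temperate"]


class TestHarmonizeRecords:
    def test_mixed_bases_all_converted(self, flux_records):
        records, _ = flux_records
        harm = harmonize_records(records)
        assert {"daily_nee", "daily_ch4", "conversion_path"} <= set(harm.columns)
        daily = harm["basis"] == "daily"
        assert (harm.loc[daily, "conversion_path"] == "none").all()
        assert (harm.loc[~daily, "conversion_path"] != "none").all()

    def test_seasonal_record_conversion_value(self):
        df = pd.DataFrame([{"basis": "seasonal", "nee_value": -300.0,
                            "ch4_value": np.nan, "gs_days": 150}])
        harm = harmonize_records(df)
        assert harm["daily_nee"].iloc[0] == pytest.approx(-10.0)

    def test_annual_record_strips_winter_then_scales(self):
        c = Constants(winter_co2=0.9)
        df = pd.DataFrame([{"basis": "annual", "nee_value": -100.0,
                            "ch4_value": np.nan, "gs_days": 165}])
        harm = harmonize_records(df, constants=c)
        assert harm["daily_nee"].iloc[0] == pytest.approx(-280.0 / 165 * 5)

    def test_unknown_basis_rejected(self):
        df = pd.DataFrame([{"basis": "weekly", "nee_value": 1.0, "gs_days": 165}])
        with pytest.raises(ValueError, match="weekly"):
            harmonize_records(df)


class TestParameterRecovery:
    def test_cell_means_recovered_within_two_se(self):
        """Harmonization recovers generator cell means within 2 SE for >= 90%
        of cells across seeds."""
        from peatflux import synth

        hits = total = 0
        for seed in range(25):
            cfg = synth.SynthConfig(seed=seed, records_per_cell=8)
            records, truth = synth.gen_flux_records(cfg)
            harm = harmonize_records(records)
            tab = aggregate_emission_factors(harm)
            merged = tab.merge(truth, on=["ecozone", "peatland_class", "gas"])
            for _, r in merged.iterrows():
                if r["true_sd"] == 0:
                    continue
                se_theory = r["true_sd"] / np.sqrt(r["n_entries"])
                total += 1
                hits += abs(r["mean"] - r["true_mean"]) <= 2.0 * se_theory
        assert hits / total >= 0.9
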