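import numpy as np
import pandas as pd
import pytest

from andrias.interviews import normalize_sighting_date
from andrias.permutation import permutation_f_test
from andrias.synthetic import (
    ConfigurationError,
    LandscapeConfig,
    SurveyConfig,
    generate_historical_records,
    generate_interviews,
    generate_landscape,
)


class TestLandscape:
    def test_same_seed_reproduces_every_grid(self):
        cfg = LandscapeConfig(grid_rows=30, grid_cols=30, n_counties=8,
                              n_provinces=3, seed=123)
        a = generate_landscape(cfg)
        b = generate_landscape(cfg)
        np.testing.assert_array_equal(a.elevation.values, b.elevation.values)
        np.testing.assert_array_equal(a.landcover.values, b.landcover.values)
        np.testing.assert_array_equal(a.county_labels.values, b.county_labels.values)
        for ga, gb in zip(a.monthly_temperature, b.monthly_temperature):
            np.testing.assert_array_equal(ga.values, gb.values)
        pd.testing.assert_frame_equal(a.county_province_map, b.county_province_map)

    def test_elevation_respects_configured_range(self):
        cfg = LandscapeConfig(grid_rows=20, grid_cols=20, n_counties=5,
                              n_provinces=2, elevation_range=(0, 3000), seed=4)
        land = generate_landscape(cfg)
        assert land.elevation.values.min() >= 0.0
        assert land.elevation.values.max() <= 3000.0

    def test_county_labels_partition_all_cells(self):
        cfg = LandscapeConfig(grid_rows=100, grid_cols=100, n_counties=16,
                              n_provinces=4, seed=9)
        land = generate_landscape(cfg)
        labels, counts = np.unique(land.county_labels.values, return_counts=True)
        assert set(labels) == set(range(1, 17))
        assert (counts >= 1).all()
        assert counts.sum() == 100 * 100

    def test_every_county_has_exactly_one_province(self):
        cfg = LandscapeConfig(grid_rows=40, grid_cols=40, n_counties=20,
                              n_provinces=7, seed=2)
        land = generate_landscape(cfg)
        cp = land.county_province_map
        assert len(cp) == 20
        assert cp["county_id"].is_unique
        assert set(cp["province"]) == set(range(1, 8))

    def test_all_layers_share_georeference(self):
        cfg = LandscapeConfig(grid_rows=20, grid_cols=24, n_counties=6,
                              n_provinces=2, seed=1)
        land = generate_landscape(cfg)
        ref = land.elevation
        for layer in [land.landcover, land.county_labels,
                      *land.monthly_temperature, *land.monthly_precipitation]:
            assert ref.same_grid(layer)

    @pytest.mark.parametrize(
        "kw",
        [
            {"grid_rows": 3},
            {"n_provinces": 50, "n_counties": 10},
            {"grid_rows": 4, "grid_cols": 4, "n_counties": 100},
            {"elevation_range": (100, 100)},
            {"landcover_classes": ((1, "forest", 0.0),)},
        ],
    )
    def test_degenerate_configs_rejected(self, kw):
        base = dict(grid_rows=20, grid_cols=20, n_counties=10, n_provinces=3)
        with pytest.raises(ConfigurationError):
            LandscapeConfig(**{**base, **kw})


class TestHistoricalRecords:
    def test_zero_link_gives_half_probability(self):
        counties = pd.DataFrame({"percent_suitable": [0.0, 0.0, 0.0]})
        _, truth = generate_historical_records(counties, 0.0, 0.0, seed=0)
        assert truth["presence_probabilities"] == [0.5, 0.5, 0.5]

    def test_missing_percent_column_rejected(self):
        with pytest.raises(ValueError, match="percent_suitable"):
            generate_historical_records(pd.DataFrame({"x": [1]}), 0, 0, seed=0)

    def test_null_slope_calibrates_permutation_rejections(self):
        # with no true link, the permutation test should reject at ~alpha
        rng = np.random.default_rng(0)
        n_rej = 0
        n_rep = 200
        for rep in range(n_rep):
            counties = pd.DataFrame({"percent_suitable": rng.uniform(0, 100, 40)})
            recs, _ = generate_historical_records(counties, 0.0, 0.0, seed=rep)
            if recs["presence"].nunique() < 2:
                n_rep -= 1
                continue
            res = permutation_f_test(
                recs["percent_suitable"].to_numpy(), recs["presence"].to_numpy(),
                n_iterations=400, seed=rep,
            )
            n_rej += res.p_value <= 0.05
        rate = n_rej / n_rep
        # 95% binomial interval around 0.05 for ~200 replicates
        assert 0.02 <= rate <= 0.09

    def test_large_slope_separates_groups(self):
        rng = np.random.default_rng(1)
        n_higher = 0
        for rep in range(100):
            counties = pd.DataFrame({"percent_suitable": rng.uniform(0, 100, 50)})
            recs, _ = generate_historical_records(counties, -5.0, 0.1, seed=rep)
            grp = recs.groupby("presence")["percent_suitable"].mean()
            if len(grp) == 2 and grp[1] > grp[0]:
                n_higher += 1
        assert n_higher >= 95


class TestInterviews:
    def test_record_count_is_counties_times_respondents(self, survey_design):
        big = pd.concat([survey_design] * 4, ignore_index=True)
        big["county_id"] = np.arange(1, len(big) + 1)
        cfg = SurveyConfig(respondents_per_county=30, seed=0)
        records, _ = generate_interviews(big, cfg)
        assert len(records) == 30 * 96

    def test_empty_county_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            generate_interviews(pd.DataFrame(), SurveyConfig())

    def test_pooled_proportion_matches_baseline_without_noise(self, survey_design):
        cfg = SurveyConfig(
            respondents_per_county=30, baseline_report_prob=0.45,
            effect_prob=0.0, province_intercept_sd=0.0, county_olre_sd=0.0,
            seed=21,
        )
        records, _ = generate_interviews(survey_design, cfg)
        n = len(records)
        prop = records["reported_sighting"].mean()
        se = np.sqrt(0.45 * 0.55 / n)
        assert abs(prop - 0.45) <= 3 * se

    def test_proportion_converges_at_large_n(self, survey_design):
        cfg = SurveyConfig(
            respondents_per_county=1000, baseline_report_prob=0.30,
            effect_prob=0.0, province_intercept_sd=0.0, county_olre_sd=0.0,
            seed=8,
        )
        records, _ = generate_interviews(survey_design, cfg)
        assert records["reported_sighting"].mean() == pytest.approx(0.30, abs=0.01)

    def test_every_raw_report_normalises_to_stored_truth(self, interview_dataset):
        records, _ = interview_dataset
        dated = records[records["raw_format"].notna()]
        assert len(dated) > 100
        assert set(dated["raw_format"]) == {
            "calendar_year", "years_ago", "decade", "age_at_sighting",
        }
        for row in dated.itertuples(index=False):
            got = normalize_sighting_date(
                row.raw_format, row.raw_value, row.interview_year,
                respondent_age=row.age,
            )
            assert got == row.true_years_ago, row

    def test_effect_prob_shifts_historical_arm(self, survey_design):
        cfg = SurveyConfig(
            respondents_per_county=500, baseline_report_prob=0.45,
            effect_prob=0.10, province_intercept_sd=0.0, county_olre_sd=0.0,
            seed=3,
        )
        records, truth = generate_interviews(survey_design, cfg)
        by_arm = records.groupby("selection_method")["reported_sighting"].mean()
        assert by_arm[0] == pytest.approx(0.45, abs=0.02)
        assert by_arm[1] == pytest.approx(0.55, abs=0.02)
        assert truth["beta1"] > 0

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            SurveyConfig(baseline_report_prob=1.2)
        with pytest.raises(ConfigurationError):
            SurveyConfig(baseline_report_prob=0.95, effect_prob=0.10)
        with pytest.raises(ConfigurationError):
            SurveyConfig(province_intercept_sd=-0.1)
        with pytest.raises(ConfigurationError):
            SurveyConfig(date_format_mix={"years_ago": 0.5})
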