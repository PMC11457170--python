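"""Salinity ingest, aggregation, and the 18 psu restoration-outcome rule."""

import datetime as dt
import random

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from marshcarbon import (
    EmptyWindowError,
    OutcomeCategory,
    SalinityObservation,
    SchemaError,
    ValidationError,
    classify_site,
    count_qualifying_years,
    load_observations,
    qualifying_years,
    summarize_salinity,
)
from marshcarbon.synthetic import (
    SiteScenario,
    eastern_point_scenario,
    generate_site,
    observations_to_frame,
)

RDATE = dt.date(2003, 11, 1)


def _obs(date, salinity, depth="shallow", transect="T1", site="s1"):
    return SalinityObservation(site_id=site, date=date, transect_id=transect,
                               depth_class=depth, salinity=salinity)


class TestLoadObservations:
    def test_roundtrip_through_csv(self, tmp_path):
        obs, _, _ = generate_site(eastern_point_scenario(seed=3, n_per_year=6))
        path = tmp_path / "obs.csv"
        observations_to_frame(obs).to_csv(path, index=False)
        assert load_observations(path) == obs

    def test_shuffled_columns_with_mapping(self, tmp_path):
        path = tmp_path / "obs.csv"
        path.write_text(
            "sal,when,marsh,line,layer\n"
            "12.5,2001-05-02,s1,T2,medium\n"
            "0.0,2001-06-02,s1,T1,deep\n"
            "30.1,2004-01-15,s1,T3,shallow\n"
        )
        mapping = {"site_id": "marsh", "date": "when", "transect_id": "line",
                   "depth_class": "layer", "salinity_psu": "sal"}
        expected = [
            _obs(dt.date(2001, 5, 2), 12.5, "medium", "T2"),
            _obs(dt.date(2001, 6, 2), 0.0, "deep", "T1"),
            _obs(dt.date(2004, 1, 15), 30.1, "shallow", "T3"),
        ]
        assert load_observations(path, schema=mapping) == expected

    def test_negative_salinity_names_row(self, tmp_path):
        path = tmp_path / "obs.csv"
        path.write_text(
            "site_id,date,transect_id,depth_class,salinity_psu\n"
            "s1,2001-05-02,T1,shallow,12.0\n"
            "s1,2001-06-02,T1,shallow,-2\n"
        )
        with pytest.raises(ValidationError, match="row 2"):
            load_observations(path)

    def test_unparseable_salinity_and_date_reported(self, tmp_path):
        path = tmp_path / "obs.csv"
        path.write_text(
            "site_id,date,transect_id,depth_class,salinity_psu\n"
            "s1,not-a-date,T1,shallow,12.0\n"
            "s1,2001-06-02,T1,shallow,abc\n"
        )
        with pytest.raises(ValidationError, match="2 bad row"):
            load_observations(path)

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "obs.csv"
        path.write_text("site_id,date,salinity_psu\ns1,2001-05-02,12.0\n")
        with pytest.raises(SchemaError, match="transect_id"):
            load_observations(path)


class TestSummarize:
    def test_pooled_mean_matches_direct_arithmetic(self):
        rng = np.random.default_rng(11)
        values = rng.uniform(0, 35, size=40)
        obs = [_obs(dt.date(2001, 1 + i % 12, 1 + i % 28), v)
               for i, v in enumerate(values)]
        (summary,) = summarize_salinity(obs, RDATE, "pre")
        assert summary.mean == pytest.approx(values.mean())
        assert summary.standard_error == pytest.approx(
            values.std(ddof=1) / np.sqrt(values.size)
        )
        assert summary.n == 40

    def test_single_observation_has_zero_se(self):
        (summary,) = summarize_salinity([_obs(dt.date(2001, 1, 1), 18.0)], RDATE, "pre")
        assert (summary.mean, summary.standard_error, summary.n) == (18.0, 0.0, 1)

    def test_empty_window_raises(self):
        with pytest.raises(EmptyWindowError):
            summarize_salinity([_obs(dt.date(2001, 1, 1), 18.0)], RDATE, "post")

    def test_window_split_on_restoration_date(self):
        obs = [_obs(RDATE - dt.timedelta(days=1), 10.0),
               _obs(RDATE, 20.0)]  # on the restoration date counts as post
        assert summarize_salinity(obs, RDATE, "pre")[0].mean == 10.0
        assert summarize_salinity(obs, RDATE, "post")[0].mean == 20.0

    def test_depth_stratification_isolates_shallow_shift(self):
        base = {"shallow": 12.0, "medium": 15.0, "deep": 15.0}
        obs = [_obs(dt.date(2001, m, 1), base[d] + (5.0 if d == "shallow" else 0.0), d)
               for m in range(1, 13) for d in ("shallow", "medium", "deep")]
        by_depth = {s.stratum: s.mean for s in
                    summarize_salinity(obs, RDATE, "pre", stratify_by="depth")}
        assert by_depth == {"shallow": 17.0, "medium": 15.0, "deep": 15.0}

    def test_generator_mean_recovered_within_two_se(self):
        obs, _, _ = generate_site(eastern_point_scenario(seed=5))
        (pre,) = summarize_salinity(obs, RDATE, "pre")
        assert abs(pre.mean - 10.2) <= 2 * pre.standard_error + 1e-12


class TestClassify:
    @pytest.mark.parametrize(
        ("pre", "post", "expected"),
        [
            (10.2, 19.0, OutcomeCategory.SUCCESS),  # Eastern Point
            (17.4, 19.7, OutcomeCategory.SUCCESS),  # Mill Pond
            (12.6, 9.8, OutcomeCategory.FAILED_BELOW_THRESHOLD),  # Cedar Point
            (27.4, 25.7, OutcomeCategory.NOT_IMPAIRED),  # Town Farm Road
            (18.3, 23.7, OutcomeCategory.NOT_IMPAIRED),  # Conomo Point: pre at 18.3
            (17.9, 18.0, OutcomeCategory.FAILED_BELOW_THRESHOLD),  # strict "surpassed"
            (18.0, 25.0, OutcomeCategory.NOT_IMPAIRED),  # pre boundary: not impaired
        ],
    )
    def test_threshold_rule(self, pre, post, expected):
        assert classify_site(pre, post).category == expected

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValidationError):
            classify_site(float("nan"), 19.0)

    def test_invariant_to_order_and_duplication(self):
        obs, _, _ = generate_site(eastern_point_scenario(seed=7, n_per_year=12))
        shuffled = obs[:]
        random.Random(0).shuffle(shuffled)

        def outcome(observations):
            pre = summarize_salinity(observations, RDATE, "pre")[0].mean
            post = summarize_salinity(observations, RDATE, "post")[0].mean
            return classify_site(pre, post).category

        assert outcome(obs) == outcome(shuffled) == outcome(obs + obs)


class TestQualifyingYears:
    def test_lag_years_excluded(self):
        scenario = eastern_point_scenario(seed=2, lag_years=2, observation_sd=0.5)
        obs, _, truth = generate_site(scenario)
        per_year = qualifying_years(obs, scenario.restoration_date)
        # post span 2003-2015 = 13 calendar years, first 2 lagging below 18
        assert len(per_year) == 13
        assert [q for _, _, q in per_year[:2]] == [False, False]
        assert count_qualifying_years(obs, scenario.restoration_date) == \
            truth.intended_qualifying_years == 11

    def test_all_post_years_below_threshold(self):
        scenario = SiteScenario(true_pre_mean=12.0, true_post_mean=14.0,
                                observation_sd=0.0, seed=0)
        obs, _, _ = generate_site(scenario)
        assert count_qualifying_years(obs, scenario.restoration_date) == 0

    @given(threshold=st.floats(min_value=0, max_value=40))
    def test_count_non_increasing_in_threshold(self, threshold):
        obs, _, _ = generate_site(eastern_point_scenario(seed=9, n_per_year=12))
        lo = count_qualifying_years(obs, RDATE, threshold)
        hi = count_qualifying_years(obs, RDATE, threshold + 1.0)
        assert hi <= lo
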