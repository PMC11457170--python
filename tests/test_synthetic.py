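"""Seeded synthetic-data generation and ground-truth recovery."""

import datetime as dt

import numpy as np
import pytest

from marshcarbon import (
    ConsistencyError,
    OutcomeCategory,
    classify_site,
    site_abatement,
    table1_fixture,
)
from marshcarbon.emissions import SCENARIO_GEOMETRIC
from marshcarbon.synthetic import (
    SiteScenario,
    eastern_point_scenario,
    generate_inventory,
    generate_site,
    observations_to_frame,
)


class TestDeterminism:
    def test_same_seed_same_dataset(self, tmp_path):
        scenario = eastern_point_scenario(seed=42, n_per_year=12)
        obs1, rec1, _ = generate_site(scenario)
        obs2, rec2, _ = generate_site(scenario)
        assert obs1 == obs2 and rec1 == rec2
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        observations_to_frame(obs1).to_csv(p1, index=False)
        observations_to_frame(obs2).to_csv(p2, index=False)
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seed_different_noise(self):
        obs1, _, _ = generate_site(eastern_point_scenario(seed=1, n_per_year=6))
        obs2, _, _ = generate_site(eastern_point_scenario(seed=2, n_per_year=6))
        assert obs1 != obs2


class TestGroundTruth:
    def test_noiseless_limit_recovers_true_means_exactly(self):
        scenario = SiteScenario(true_pre_mean=10.2, true_post_mean=19.0,
                                observation_sd=0.0, n_per_year=1, seed=0)
        _, record, _ = generate_site(scenario)
        assert record.pre_mean == 10.2
        assert record.post_mean == 19.0

    def test_success_scenario_classified_success(self):
        _, record, truth = generate_site(eastern_point_scenario(seed=8))
        outcome = classify_site(record.pre_mean, record.post_mean)
        assert outcome.category == truth.intended_outcome == OutcomeCategory.SUCCESS

    def test_not_impaired_scenario(self):
        scenario = SiteScenario(true_pre_mean=27.4, true_post_mean=25.7,
                                observation_sd=1.0, seed=8)
        _, record, truth = generate_site(scenario)
        assert truth.intended_outcome == OutcomeCategory.NOT_IMPAIRED
        assert classify_site(record.pre_mean, record.post_mean).category == \
            OutcomeCategory.NOT_IMPAIRED

    def test_lag_phase_reduces_qualifying_years(self):
        scenario = eastern_point_scenario(seed=3, lag_years=2, observation_sd=0.5)
        _, record, truth = generate_site(scenario)
        assert truth.intended_qualifying_years == len(scenario.post_years) - 2
        assert record.post_restoration_years == truth.intended_qualifying_years

    def test_inconsistent_lag_scenario_rejected(self):
        with pytest.raises(ConsistencyError):
            generate_site(SiteScenario(true_pre_mean=10.0, true_post_mean=16.0,
                                       lag_years=2, seed=0))

    def test_classification_recovery_rate(self):
        """Outcome recovery >= 95% when true means sit > 3 SE from threshold."""
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            scenario = SiteScenario(
                true_pre_mean=10.2, true_post_mean=19.0, observation_sd=2.0,
                monitoring_start=2000, monitoring_end=2009,
                restoration_date=dt.date(2003, 11, 1), n_per_year=12, seed=seed,
            )
            _, record, truth = generate_site(scenario)
            got = classify_site(record.pre_mean, record.post_mean).category
            hits += got == truth.intended_outcome
        assert hits / n_rep >= 0.95

    def test_estimated_means_unbiased(self):
        means = []
        for seed in range(100):
            _, record, _ = generate_site(eastern_point_scenario(seed=seed, n_per_year=12))
            means.append(record.post_mean)
        # Monte-Carlo error of the mean of 100 replicate estimates
        mc_se = np.std(means, ddof=1) / 10.0
        assert abs(np.mean(means) - 19.0) < 4 * mc_se + 1e-9

    def test_end_to_end_abatement_independent_of_noise(self):
        _, record, _ = generate_site(eastern_point_scenario(seed=13))
        result = site_abatement(record, SCENARIO_GEOMETRIC)
        assert result.annual_t == (19.4 - 0.46) * record.area_m2 / 1e6


class TestTable1Fixture:
    def test_six_sites_with_printed_areas(self):
        sites = {s.site_id: s for s in table1_fixture()}
        assert len(sites) == 6
        areas = {"conomo_point": 54_197, "eastern_point": 10_955, "cedar_point": 12_869,
                 "town_farm": 97_128, "seaview_street": 12_141, "mill_pond": 161_880}
        for site_id, area in areas.items():
            assert sites[site_id].area_m2 == area

    def test_successful_hectares_total(self):
        sites = {s.site_id: s for s in table1_fixture()}
        total = sites["eastern_point"].area_ha + sites["mill_pond"].area_ha
        assert round(total, 1) == 17.3

    def test_qualifying_year_counts(self):
        sites = {s.site_id: s for s in table1_fixture()}
        assert sites["eastern_point"].post_restoration_years == 12
        assert sites["mill_pond"].post_restoration_years == 11


class TestInventoryGenerator:
    def test_filtered_total_matches_truth(self):
        frame, truth = generate_inventory(100, seed=5)
        mask = frame["effect_score"] > 0.5
        assert int(mask.sum()) == truth.filtered_count
        assert float(frame.loc[mask, "area_ha"].sum()) == truth.filtered_area_ha

    def test_threshold_extremes(self):
        frame, all_kept = generate_inventory(30, effect_threshold=0.0, seed=6)
        assert all_kept.filtered_count == 30
        _, none_kept = generate_inventory(30, effect_threshold=1.0, seed=6)
        assert none_kept.filtered_count == 0
        assert none_kept.filtered_area_ha == 0.0

    def test_deterministic_under_seed(self):
        f1, _ = generate_inventory(40, seed=9)
        f2, _ = generate_inventory(40, seed=9)
        assert f1.equals(f2)
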