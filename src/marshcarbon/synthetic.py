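"""Seeded generators for salinity monitoring data and marsh inventories.

Every pipeline stage is testable without external downloads: the generator
emits observation tables in the same schema the ingest code reads, with
known ground truth (intended outcome, intended qualifying years, filtered
inventory totals) attached.

The noise model is independent normal observation error around a
depth/season-shifted yearly mean, truncated at 0 psu: monitoring summaries
report only means with standard errors, and this is the minimal structure
supporting SE-based recovery tests. The seasonal term is a yearly sinusoid
with amplitude defaulting to 0 so basic tests are season-free. Seeds are
explicit everywhere; there is no hidden global random state.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .constants import SALINITY_THRESHOLD_PSU
from .errors import ConsistencyError, ValidationError
from .salinity import OBSERVATION_COLUMNS, count_qualifying_years, summarize_salinity
from .types import (
    DepthClass,
    OutcomeCategory,
    SalinityObservation,
    SiteRecord,
)

_DEPTH_CYCLE = (DepthClass.SHALLOW, DepthClass.MEDIUM, DepthClass.DEEP)


@dataclass(frozen=True)
class SiteScenario:
    """Ground-truth parameters for one simulated monitoring site."""

    true_pre_mean: float  # psu
    true_post_mean: float  # psu
    observation_sd: float = 2.0  # psu, independent per-observation noise
    depth_offsets: dict[DepthClass, float] = field(default_factory=dict)
    seasonal_amplitude: float = 0.0  # psu
    monitoring_start: int = 2000
    monitoring_end: int = 2015
    restoration_date: dt.date = dt.date(2003, 11, 1)
    lag_years: int = 0  # leading post years forced below threshold
    lag_mean: float = 15.0  # psu, yearly mean during the lag phase
    n_per_year: int = 48
    transects: int = 3
    area_m2: float = 10_955.0
    site_id: str = "synthetic_site"
    seed: int = 0
    threshold: float = SALINITY_THRESHOLD_PSU

    def __post_init__(self) -> None:
        if self.n_per_year < 1:
            raise ValidationError("n_per_year must be >= 1")
        if self.transects < 1:
            raise ValidationError("transects must be >= 1")
        if self.observation_sd < 0:
            raise ValidationError("observation_sd must be >= 0")
        if not self.monitoring_start <= self.restoration_date.year <= self.monitoring_end:
            raise ValidationError("restoration date must fall inside the monitoring window")
        post_span = self.monitoring_end - self.restoration_date.year + 1
        if not 0 <= self.lag_years <= post_span:
            raise ValidationError(
                f"lag_years={self.lag_years} outside the post-monitoring span {post_span}"
            )

    @property
    def post_years(self) -> list[int]:
        return list(range(self.restoration_date.year, self.monitoring_end + 1))

    @property
    def lag_year_set(self) -> set[int]:
        return set(self.post_years[: self.lag_years])


@dataclass(frozen=True)
class GroundTruth:
    """What the generator intended; compared against pipeline output in tests."""

    intended_outcome: OutcomeCategory
    intended_qualifying_years: int
    scenario: SiteScenario


def _intended_outcome(s: SiteScenario) -> OutcomeCategory:
    if s.true_pre_mean >= s.threshold:
        return OutcomeCategory.NOT_IMPAIRED
    if s.true_post_mean > s.threshold:
        return OutcomeCategory.SUCCESS
    return OutcomeCategory.FAILED_BELOW_THRESHOLD


def generate_site(
    scenario: SiteScenario,
) -> tuple[list[SalinityObservation], SiteRecord, GroundTruth]:
    """Simulate one site's monitoring record.

    Observations are drawn as (yearly true mean + depth offset + seasonal
    sinusoid + N(0, sd)), truncated at 0 psu. The first ``lag_years``
    post-restoration calendar years use ``lag_mean`` instead of the true post
    mean, emulating the lag phase seen after some restorations. Identical
    scenario + seed gives an identical dataset.
    """
    if scenario.lag_years > 0:
        if scenario.lag_mean > scenario.threshold:
            raise ConsistencyError(
                f"lag_mean={scenario.lag_mean} must sit below the threshold "
                f"{scenario.threshold} psu"
            )
        if scenario.true_post_mean <= scenario.threshold:
            raise ConsistencyError(
                "lag_years only makes sense for scenarios whose eventual post mean "
                f"exceeds the threshold (got true_post_mean={scenario.true_post_mean})"
            )

    rng = np.random.default_rng(scenario.seed)
    observations: list[SalinityObservation] = []
    for year in range(scenario.monitoring_start, scenario.monitoring_end + 1):
        for k in range(scenario.n_per_year):
            month = k % 12 + 1
            day = min(3 + 7 * (k // 12), 28)
            date = dt.date(year, month, day)
            if date < scenario.restoration_date:
                base = scenario.true_pre_mean
            elif year in scenario.lag_year_set:
                base = scenario.lag_mean
            else:
                base = scenario.true_post_mean
            depth = _DEPTH_CYCLE[k % 3]
            value = (
                base
                + scenario.depth_offsets.get(depth, 0.0)
                + scenario.seasonal_amplitude
                * np.sin(2 * np.pi * date.timetuple().tm_yday / 365.25)
                + (rng.normal(0.0, scenario.observation_sd)
                   if scenario.observation_sd > 0 else 0.0)
            )
            observations.append(
                SalinityObservation(
                    site_id=scenario.site_id,
                    date=date,
                    transect_id=f"T{k % scenario.transects + 1}",
                    depth_class=depth,
                    salinity=max(value, 0.0),
                )
            )

    pre = summarize_salinity(observations, scenario.restoration_date, "pre")[0]
    post = summarize_salinity(observations, scenario.restoration_date, "post")[0]
    record = SiteRecord(
        site_id=scenario.site_id,
        name=scenario.site_id,
        area_m2=scenario.area_m2,
        restoration_date=scenario.restoration_date,
        monitoring_start=scenario.monitoring_start,
        monitoring_end=scenario.monitoring_end,
        post_restoration_years=count_qualifying_years(
            observations, scenario.restoration_date, scenario.threshold
        ),
        pre_mean=pre.mean,
        pre_se=pre.standard_error,
        post_mean=post.mean,
        post_se=post.standard_error,
    )
    outcome = _intended_outcome(scenario)
    qualifying = (
        len(scenario.post_years) - scenario.lag_years
        if scenario.true_post_mean > scenario.threshold
        else 0
    )
    truth = GroundTruth(
        intended_outcome=outcome,
        intended_qualifying_years=qualifying,
        scenario=scenario,
    )
    return observations, record, truth


def observations_to_frame(observations: list[SalinityObservation]) -> pd.DataFrame:
    """Observation list as a DataFrame in the canonical CSV schema."""
    return pd.DataFrame(
        {
            "site_id": [o.site_id for o in observations],
            "date": [o.date.isoformat() for o in observations],
            "transect_id": [o.transect_id for o in observations],
            "depth_class": [o.depth_class.value for o in observations],
            "salinity_psu": [o.salinity for o in observations],
        },
        columns=list(OBSERVATION_COLUMNS),
    )


def table1_fixture() -> list[SiteRecord]:
    """The six Massachusetts restoration sites with their printed summaries."""
    with resources.files("marshcarbon.data").joinpath("table1_sites.csv").open() as fh:
        frame = pd.read_csv(fh)
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            SiteRecord(
                site_id=row.site_id,
                name=row.name,
                area_m2=float(row.area_m2),
                restoration_date=dt.date.fromisoformat(row.restoration_date),
                monitoring_start=int(row.monitoring_start),
                monitoring_end=int(row.monitoring_end),
                post_restoration_years=int(row.post_restoration_years),
                pre_mean=float(row.pre_mean_psu),
                pre_se=float(row.pre_se_psu),
                post_mean=float(row.post_mean_psu),
                post_se=float(row.post_se_psu),
            )
        )
    return records


@dataclass(frozen=True)
class InventoryTruth:
    """Generator-side totals for marshes above the effect threshold."""

    threshold: float
    filtered_count: int
    filtered_area_ha: float


def generate_inventory(
    n_marshes: int,
    median_area_ha: float = 1.4,
    sigma_log: float = 0.8,
    effect_alpha: float = 2.0,
    effect_beta: float = 2.0,
    effect_threshold: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, InventoryTruth]:
    """Simulate a per-marsh restriction inventory (id, area, effect score).

    Areas are lognormal (small-marsh skew typical of restriction inventories);
    effect scores are Beta distributed on [0, 1]. The returned truth holds the
    exact filtered count/area at ``effect_threshold`` (strictly-greater rule).
    """
    if n_marshes < 0:
        raise ValidationError("n_marshes must be >= 0")
    rng = np.random.default_rng(seed)
    areas = np.exp(rng.normal(np.log(median_area_ha), sigma_log, size=n_marshes))
    effects = rng.beta(effect_alpha, effect_beta, size=n_marshes)
    frame = pd.DataFrame(
        {
            "marsh_id": [f"marsh_{i:04d}" for i in range(n_marshes)],
            "area_ha": areas,
            "effect_score": effects,
        }
    )
    mask = frame["effect_score"] > effect_threshold
    truth = InventoryTruth(
        threshold=effect_threshold,
        filtered_count=int(mask.sum()),
        filtered_area_ha=float(frame.loc[mask, "area_ha"].sum()),
    )
    return frame, truth


def eastern_point_scenario(seed: int = 0, **overrides) -> SiteScenario:
    """A SUCCESS scenario shaped like the Eastern Point site (10.2 -> 19.0 psu)."""
    params = dict(
        true_pre_mean=10.2,
        true_post_mean=19.0,
        monitoring_start=2000,
        monitoring_end=2015,
        restoration_date=dt.date(2003, 11, 1),
        area_m2=10_955.0,
        site_id="eastern_point_like",
        seed=seed,
    )
    params.update(overrides)
    return SiteScenario(**params)
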