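"""Report tables and the end-to-end replication pipeline.

Accounting throughout the package carries full precision; this module owns
the *rendering* conventions of the published report tables, which matter for
matching them digit-for-digit:

- annual avoided emissions display at 2 d.p.;
- displayed annual VCUs are the *displayed* (2 d.p.) emissions times the GWP,
  rounded to 1 d.p. (so 0.21 x 27.2 -> 5.7);
- totals rows sum the displayed (rounded) cells;
- dollar figures are whole-dollar, half-up; market revenue prices whole
  credits;
- cumulative credits/benefits use unrounded annual values, rounded once at
  the end.
"""

from __future__ import annotations

from collections.abc import Sequence

import pandas as pd

from ._util import round_half_up
from .constants import (
    DEFAULT_CREDIT_PRICE,
    DEFAULT_END_YEAR,
    DEFAULT_START_YEAR,
)
from .crediting import DEFAULT_GWP, crediting_window, cumulative_vcus, revenue, vcu_annual
from .emissions import (
    SCENARIO_GEOMETRIC,
    SCENARIO_TRUE_MEAN,
    cumulative_avoided,
    per_hectare_rate,
    site_abatement,
)
from .salinity import classify_site
from .scaling import MASSACHUSETTS_INVENTORY, statewide_estimate
from .social_cost import cumulative_benefit, default_schedule
from .synthetic import table1_fixture
from .types import (
    EmissionScenario,
    MarshInventory,
    OutcomeCategory,
    SCMSchedule,
    SiteRecord,
)

#: The two published emission-factor scenarios, keyed by display label.
DEFAULT_SCENARIOS: dict[str, EmissionScenario] = {
    "EF 19.4": SCENARIO_GEOMETRIC,
    "EF 41.6": SCENARIO_TRUE_MEAN,
}


def successful_sites(sites: Sequence[SiteRecord] | None = None) -> list[SiteRecord]:
    """Sites classified SUCCESS from their pooled means, in input order."""
    if sites is None:
        sites = table1_fixture()
    return [
        s
        for s in sites
        if classify_site(s.pre_mean, s.post_mean).category == OutcomeCategory.SUCCESS
    ]


def table3_frame(
    sites: Sequence[SiteRecord] | None = None,
    scenarios: dict[str, EmissionScenario] | None = None,
    gwp: float = DEFAULT_GWP.value,
) -> pd.DataFrame:
    """Annual avoided emissions and VCUs per successful site, printed style.

    Rows ``E_t_per_yr`` and ``VCU_per_yr``; columns are (scenario, site_id)
    plus a (scenario, "total") column that sums the displayed cells.
    """
    winners = successful_sites(sites)
    scenarios = scenarios or DEFAULT_SCENARIOS
    data: dict[tuple[str, str], dict[str, float]] = {}
    for label, scenario in scenarios.items():
        e_cells, v_cells = [], []
        for site in winners:
            annual = site_abatement(site, scenario).annual_t
            e_disp = round_half_up(annual, 2)
            v_disp = round_half_up(e_disp * gwp, 1)
            e_cells.append(e_disp)
            v_cells.append(v_disp)
            data[(label, site.site_id)] = {"E_t_per_yr": e_disp, "VCU_per_yr": v_disp}
        data[(label, "total")] = {
            "E_t_per_yr": round_half_up(sum(e_cells), 2),
            "VCU_per_yr": round_half_up(sum(v_cells), 1),
        }
    frame = pd.DataFrame(data)
    frame.columns = pd.MultiIndex.from_tuples(frame.columns, names=["scenario", "site"])
    return frame.loc[["E_t_per_yr", "VCU_per_yr"]]


def table4_frame(
    sites: Sequence[SiteRecord] | None = None,
    scenarios: dict[str, EmissionScenario] | None = None,
    schedule: SCMSchedule | None = None,
    inventory: MarshInventory = MASSACHUSETTS_INVENTORY,
    display_start: int = DEFAULT_START_YEAR,
    display_end: int = 2030,
    window_end: int = DEFAULT_END_YEAR,
) -> pd.DataFrame:
    """Per-year social benefit of avoided methane, printed style.

    One row per display year plus a ``{start}-{end} Total`` row; columns are
    the $/t schedule value, then (site, scenario) whole-dollar benefits, then
    statewide (inventory-area) columns. The combined-total convention sums
    per-site whole-dollar totals.
    """
    winners = successful_sites(sites)
    scenarios = scenarios or DEFAULT_SCENARIOS
    schedule = schedule or default_schedule()

    streams: dict[tuple[str, str], float] = {}  # (entity, scenario) -> t CH4/yr
    for label, scenario in scenarios.items():
        for site in winners:
            streams[(site.site_id, label)] = site_abatement(site, scenario).annual_t
        rate = per_hectare_rate(
            sum(site_abatement(s, scenario).annual_t for s in winners),
            sum(s.area_ha for s in winners),
        )
        streams[("statewide", label)] = rate * inventory.total_area_ha

    rows = {}
    for year in range(display_start, display_end + 1):
        value = schedule.value(year)
        row = {("scm_usd_per_t", ""): value}
        for key, avoided in streams.items():
            row[key] = round_half_up(avoided * value)
        rows[str(year)] = row
    total_label = f"{display_start}-{window_end} Total"
    total_row = {("scm_usd_per_t", ""): float("nan")}
    for key, avoided in streams.items():
        benefit = cumulative_benefit(avoided, schedule, display_start, window_end)
        total_row[key] = round_half_up(benefit.cumulative)
    rows[total_label] = total_row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.columns = pd.MultiIndex.from_tuples(frame.columns, names=["entity", "scenario"])
    return frame


def replicate_study(
    sites: Sequence[SiteRecord] | None = None,
    scenarios: dict[str, EmissionScenario] | None = None,
    schedule: SCMSchedule | None = None,
    inventory: MarshInventory = MASSACHUSETTS_INVENTORY,
    gwp: float = DEFAULT_GWP.value,
    price: float = DEFAULT_CREDIT_PRICE,
) -> dict:
    """Run the whole pipeline on the packaged site table; return headline numbers.

    The returned dict holds, per emission-factor scenario: per-site and total
    annual avoided emissions and VCUs (printed rendering), the per-hectare
    rate, cumulative abatement/VCUs/revenue over each site's qualifying
    years, the 2021-2050 crediting window, per-site and combined social
    benefit, and the statewide upper bound.
    """
    if sites is None:
        sites = table1_fixture()
    winners = successful_sites(sites)
    scenarios = scenarios or DEFAULT_SCENARIOS
    schedule = schedule or default_schedule()
    start, end = DEFAULT_START_YEAR, DEFAULT_END_YEAR

    out: dict = {
        "n_sites": len(sites),
        "n_successful": len(winners),
        "successful_site_ids": [s.site_id for s in winners],
        "successful_area_ha": sum(s.area_ha for s in winners),
        "scenarios": {},
    }
    for label, scenario in scenarios.items():
        per_site = {}
        for site in winners:
            ab = site_abatement(site, scenario)
            e_disp = round_half_up(ab.annual_t, 2)
            social = cumulative_benefit(ab.annual_t, schedule, start, end, label=label)
            per_site[site.site_id] = {
                "annual_t": ab.annual_t,
                "annual_t_printed": e_disp,
                "vcu_per_year_printed": round_half_up(e_disp * gwp, 1),
                "qualifying_years": ab.years,
                "social_2021_2050_usd": round_half_up(social.cumulative),
            }
        annual_total = sum(site_abatement(s, scenario).annual_t for s in winners)
        rate = per_hectare_rate(annual_total, out["successful_area_ha"])
        cum_t = sum(
            cumulative_avoided(site_abatement(s, scenario).annual_t, s.post_restoration_years)
            for s in winners
        )
        cum_vcu = cumulative_vcus(
            (vcu_annual(site_abatement(s, scenario).annual_t, gwp), s.post_restoration_years)
            for s in winners
        )
        window = crediting_window(vcu_annual(annual_total, gwp), start, end, price)
        state = statewide_estimate(
            rate, inventory, schedule, gwp=gwp, price=price,
            start=start, end=end, scenario_label=label,
        )
        out["scenarios"][label] = {
            "per_site": per_site,
            "annual_total_t_printed": round_half_up(
                sum(v["annual_t_printed"] for v in per_site.values()), 2
            ),
            "vcu_total_per_year_printed": round_half_up(
                sum(v["vcu_per_year_printed"] for v in per_site.values()), 1
            ),
            "per_hectare_t": rate,
            "cumulative_t": cum_t,
            "cumulative_vcus": cum_vcu,
            "revenue_usd": revenue(cum_vcu, price),
            "credits_2021_2050": round_half_up(window.cumulative_vcus),
            "credit_revenue_2021_2050_usd": window.revenue,
            "social_2021_2050_combined_usd": sum(
                v["social_2021_2050_usd"] for v in per_site.values()
            ),
            "statewide": {
                "abatement_t_per_year": state.abatement_t_per_year,
                "revenue_per_year_usd": state.revenue_per_year,
                "social_2021_usd": round_half_up(
                    state.abatement_t_per_year * schedule.value(start)
                ),
                "social_2021_2050_usd": round_half_up(state.cumulative_social_benefit),
            },
        }
    return out
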