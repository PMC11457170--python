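"""Regional scaling of per-hectare abatement to a tidal-restriction inventory.

A statewide inventory of tidally restricted marshes (count, area, restriction
effect score in [0, 1]) defines an upper bound: if every restriction with an
effect above the threshold were remediated successfully, the per-hectare
abatement rate applies across the whole filtered area. A success-rate
adjustment scales the bound by the observed fraction of restorations that
actually raised salinity above the threshold.
"""

from __future__ import annotations

import pandas as pd

from ._util import require_finite, require_non_negative
from .constants import (
    DEFAULT_CREDIT_PRICE,
    DEFAULT_END_YEAR,
    DEFAULT_START_YEAR,
    M2_PER_ACRE,
    M2_PER_HA,
)
from .crediting import DEFAULT_GWP, revenue, vcu_annual
from .errors import SchemaError, ValidationError
from .social_cost import cumulative_benefit
from .types import GWPEntry, MarshInventory, SCMSchedule, StatewideEstimate

#: The published Massachusetts inventory: marshes with a tidal-restriction
#: effect score above 0.5, totalling 2,304 acres (932.4 ha at 4,047 m2/acre).
MASSACHUSETTS_INVENTORY = MarshInventory(
    n_marshes=475,
    total_area_ha=2304 * M2_PER_ACRE / M2_PER_HA,
    effect_threshold=0.5,
    source_label="MA tidal-restriction inventory (acreage-derived area)",
)


def inventory_from_acres(
    n_marshes: int,
    acres: float,
    effect_threshold: float = 0.5,
    source_label: str = "",
) -> MarshInventory:
    """Build an inventory from an acreage total (1 acre = 4,047 m2)."""
    require_non_negative("acres", acres)
    return MarshInventory(
        n_marshes=n_marshes,
        total_area_ha=acres * M2_PER_ACRE / M2_PER_HA,
        effect_threshold=effect_threshold,
        source_label=source_label,
    )


def load_inventory(path, effect_threshold: float = 0.5, source_label: str = "") -> MarshInventory:
    """Filter a per-marsh CSV (marsh_id, area_ha, effect_score) at a threshold.

    Marshes with ``effect_score`` strictly greater than the threshold are
    retained and their areas summed.
    """
    frame = pd.read_csv(path)
    required = {"marsh_id", "area_ha", "effect_score"}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"inventory file missing column(s) {sorted(missing)}")
    kept = frame[frame["effect_score"] > effect_threshold]
    if kept.empty:
        raise ValidationError(
            f"no marshes exceed effect threshold {effect_threshold} in {path}"
        )
    return MarshInventory(
        n_marshes=int(len(kept)),
        total_area_ha=float(kept["area_ha"].sum()),
        effect_threshold=effect_threshold,
        source_label=source_label or str(path),
    )


def statewide_abatement(per_ha_rate: float, inventory: MarshInventory) -> float:
    """Upper-bound abatement, t CH4/yr, across the inventory's area."""
    require_non_negative("per_ha_rate", per_ha_rate)
    return per_ha_rate * inventory.total_area_ha


def statewide_social_benefit(
    abatement_t: float,
    schedule: SCMSchedule,
    start: int = DEFAULT_START_YEAR,
    end: int = DEFAULT_END_YEAR,
    label: str = "statewide",
):
    """Per-year and cumulative avoided social cost of the statewide abatement."""
    return cumulative_benefit(abatement_t, schedule, start=start, end=end, label=label)


def statewide_estimate(
    per_ha_rate: float,
    inventory: MarshInventory,
    schedule: SCMSchedule,
    gwp: GWPEntry | float = DEFAULT_GWP,
    price: float = DEFAULT_CREDIT_PRICE,
    start: int = DEFAULT_START_YEAR,
    end: int = DEFAULT_END_YEAR,
    scenario_label: str = "",
) -> StatewideEstimate:
    """Bundle abatement, crediting revenue and social benefit for a region."""
    abatement = statewide_abatement(per_ha_rate, inventory)
    vcus = vcu_annual(abatement, gwp)
    benefit = statewide_social_benefit(abatement, schedule, start=start, end=end)
    return StatewideEstimate(
        abatement_t_per_year=abatement,
        vcus_per_year=vcus,
        revenue_per_year=revenue(vcus, price),
        cumulative_social_benefit=benefit.cumulative,
        scenario_label=scenario_label,
        discount_rate=schedule.discount_rate,
    )


def success_adjusted(estimate: StatewideEstimate, success_rate: float) -> StatewideEstimate:
    """Scale an upper-bound estimate by a restoration success fraction."""
    require_finite("success_rate", success_rate)
    if not 0.0 <= success_rate <= 1.0:
        raise ValidationError(f"success_rate must be in [0, 1], got {success_rate}")
    return StatewideEstimate(
        abatement_t_per_year=estimate.abatement_t_per_year * success_rate,
        vcus_per_year=estimate.vcus_per_year * success_rate,
        revenue_per_year=estimate.revenue_per_year * success_rate,
        cumulative_social_benefit=estimate.cumulative_social_benefit * success_rate,
        scenario_label=estimate.scenario_label,
        discount_rate=estimate.discount_rate,
        success_rate=estimate.success_rate * success_rate,
    )
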