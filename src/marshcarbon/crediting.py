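"""Verified Carbon Unit (VCU) crediting of avoided methane.

Annual credits for a site are

    VCU/yr = (E0 - E1) * A * GWP_CH4 + (C0 - C1) * A-aggregated terms

i.e. avoided methane (t CH4/yr) times the methane GWP, plus any additional
CO2e terms (soil carbon, N2O, ...) supplied as aggregate t CO2e/yr. One VCU
is one metric ton of CO2e avoided. Accumulation across sites and years uses
unrounded annual values; revenue prices whole credits (registry practice)
and is not discounted.
"""

from __future__ import annotations

import csv
from collections.abc import Iterable
from importlib import resources

from ._util import require_finite, require_non_negative, round_half_up
from .constants import DEFAULT_CREDIT_PRICE
from .errors import ConfigError, ValidationError
from .types import AdditionalCO2e, CreditResult, Gas, GWPEntry


def load_gwp_table(path=None) -> dict[tuple[str, str, int], GWPEntry]:
    """GWP entries keyed by (gas, report, horizon); packaged IPCC table."""
    if path is None:
        text = resources.files("marshcarbon.data").joinpath("gwp.csv").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    table = {}
    for row in csv.DictReader(text.splitlines()):
        entry = GWPEntry(
            gas=Gas(row["gas"]),
            report=row["report"],
            horizon=int(row["horizon_years"]),
            value=float(row["value"]),
            uncertainty=float(row["uncertainty"]) if row["uncertainty"] else None,
        )
        table[(entry.gas.value, entry.report, entry.horizon)] = entry
    return table


_GWP_TABLE = load_gwp_table()


def gwp_ch4(report: str = "AR6", horizon: int = 100) -> GWPEntry:
    """Methane (non-fossil) GWP from the packaged IPCC table. Default: AR6 100-yr (27.2)."""
    try:
        return _GWP_TABLE[(Gas.CH4_NONFOSSIL.value, report, horizon)]
    except KeyError:
        raise ConfigError(f"no CH4 GWP entry for report={report!r}, horizon={horizon}") from None


#: Default GWP applied to avoided methane (AR6, 100-year, 27.2).
DEFAULT_GWP = gwp_ch4()


def vcu_annual(
    avoided_t: float,
    gwp: GWPEntry | float = DEFAULT_GWP,
    additional: AdditionalCO2e = AdditionalCO2e(),
) -> float:
    """Annual VCUs: avoided methane x GWP_CH4 plus net additional CO2e."""
    require_finite("avoided_t", avoided_t)
    if isinstance(gwp, GWPEntry):
        if gwp.gas != Gas.CH4_NONFOSSIL:
            raise ConfigError(
                f"GWP entry for {gwp.gas.value} cannot be applied to methane emissions"
            )
        gwp_value = gwp.value
    else:
        gwp_value = require_finite("gwp", float(gwp))
    return avoided_t * gwp_value + (additional.c0 - additional.c1)


def cumulative_vcus(vcus_per_year_by_site: Iterable[tuple[float, int]]) -> float:
    """Sum of unrounded per-site annual VCUs times per-site qualifying years."""
    total = 0.0
    for vcu_per_year, years in vcus_per_year_by_site:
        require_finite("vcus_per_year", vcu_per_year)
        if years < 0:
            raise ValidationError(f"years must be >= 0, got {years}")
        total += vcu_per_year * years
    return total


def revenue(
    vcus: float,
    price: float = DEFAULT_CREDIT_PRICE,
    integral_credits: bool = True,
) -> float:
    """Market revenue in dollars; credits sell as whole units by default."""
    require_finite("vcus", vcus)
    require_non_negative("price", price)
    credits = round_half_up(vcus) if integral_credits else vcus
    return credits * price


def crediting_window(
    vcus_per_year_total: float,
    start_year: int,
    end_year: int,
    price: float = DEFAULT_CREDIT_PRICE,
) -> CreditResult:
    """Credits and undiscounted revenue over an inclusive year window."""
    require_finite("vcus_per_year_total", vcus_per_year_total)
    if end_year < start_year:
        raise ValidationError(f"end_year {end_year} precedes start_year {start_year}")
    credits = vcus_per_year_total * (end_year - start_year + 1)
    return CreditResult(
        vcus_per_year=vcus_per_year_total,
        cumulative_vcus=credits,
        revenue=revenue(credits, price),
        price=price,
    )
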