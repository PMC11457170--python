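"""Social-cost-of-methane valuation of avoided emissions.

The cumulative avoided social cost over a window is

    SCM = sum_{i=start..end} (E0 - E1) * A * Y_{i,a%}

where Y_{i,a%} is the social cost of methane ($ per metric ton, 2021 dollars)
for emission year i at discount rate a. The schedule is input data taken from
the 2021 US Interagency Working Group estimates; this module applies it, it
does not re-derive damage functions. The same mechanism values a CO2 stream
against a social-cost-of-carbon schedule file.

The avoided-emission rate is held constant across the window: restorations
predate the valuation schedule, so benefits are valued forward over
2021-2050 by convention.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from ._util import require_finite, require_non_negative
from .constants import DEFAULT_DISCOUNT_RATE, DEFAULT_END_YEAR, DEFAULT_START_YEAR
from .errors import CoverageError, SchemaError
from .types import SCMSchedule, SocialBenefitResult

_SCHEDULE_COLUMNS = {"year", "discount_rate_pct", "usd_per_t"}


def load_scm_schedule(path=None) -> dict[float, SCMSchedule]:
    """Load year->$/t schedules keyed by discount rate (percent).

    The packaged file carries reconstructed 2021-2050 schedules at 2.5%, 3%
    and 5%; the 3% schedule's 2021-2030 decade matches the published values
    (1500, 1600, 1600, 1700, 1700, 1800, 1800, 1900, 1900, 2000) and its
    2021-2050 sum equals the published cumulative value of 68,200 $/t.
    """
    if path is None:
        with resources.files("marshcarbon.data").joinpath("scm_schedule.csv").open() as fh:
            frame = pd.read_csv(fh)
    else:
        frame = pd.read_csv(path)
    missing = _SCHEDULE_COLUMNS - set(frame.columns)
    if missing:
        raise SchemaError(f"SCM schedule file missing column(s) {sorted(missing)}")
    schedules = {}
    for rate, group in frame.groupby("discount_rate_pct"):
        entries = {int(y): float(v) for y, v in zip(group["year"], group["usd_per_t"])}
        schedules[float(rate)] = SCMSchedule(
            discount_rate=float(rate), entries=entries, label=f"{rate}%"
        )
    return schedules


def default_schedule(discount_rate: float = DEFAULT_DISCOUNT_RATE) -> SCMSchedule:
    return load_scm_schedule()[float(discount_rate)]


def annual_benefit(avoided_t: float, scm_value: float) -> float:
    """Dollar benefit of one year's avoided methane at one year's SCM value."""
    require_finite("avoided_t", avoided_t)
    require_non_negative("scm_value", scm_value)
    return avoided_t * scm_value


def cumulative_benefit(
    avoided_t: float,
    schedule: SCMSchedule,
    start: int = DEFAULT_START_YEAR,
    end: int = DEFAULT_END_YEAR,
    label: str = "",
) -> SocialBenefitResult:
    """Avoided social cost per year and summed over [start, end].

    Raises :class:`CoverageError` naming missing years if the schedule does
    not span the window.
    """
    require_finite("avoided_t", avoided_t)
    missing = [y for y in range(start, end + 1) if y not in schedule.entries]
    if missing:
        raise CoverageError(
            f"SCM schedule ({schedule.label or schedule.discount_rate}) does not "
            f"cover {start}-{end}; missing years {missing}"
        )
    per_year = {y: annual_benefit(avoided_t, schedule.entries[y]) for y in range(start, end + 1)}
    return SocialBenefitResult(
        per_year=per_year,
        cumulative=sum(per_year.values()),
        discount_rate=schedule.discount_rate,
        emission_scenario_label=label,
    )
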