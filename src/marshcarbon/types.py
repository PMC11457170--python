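"""Domain value types shared across the pipeline.

These are frozen dataclasses with eager validation: an instance that exists is
an instance whose invariants hold. Monetary amounts are 2021 US dollars;
masses are metric tons (10^6 g) unless a field name says otherwise.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass, field

from ._util import require_finite, require_non_negative, require_positive
from .constants import M2_PER_HA, SALINITY_THRESHOLD_PSU
from .errors import ValidationError


class DepthClass(str, enum.Enum):
    """Soil depth band of a salinity measurement.

    Field protocols measure at three discrete bands below the marsh surface:
    shallow 5-20 cm, medium 35-50 cm, deep 65-80 cm.
    """

    SHALLOW = "shallow"
    MEDIUM = "medium"
    DEEP = "deep"


#: Centimeter bands corresponding to each depth class.
DEPTH_BANDS_CM: dict[DepthClass, tuple[int, int]] = {
    DepthClass.SHALLOW: (5, 20),
    DepthClass.MEDIUM: (35, 50),
    DepthClass.DEEP: (65, 80),
}


@dataclass(frozen=True)
class SalinityObservation:
    """One field salinity measurement (psu == ppt for these purposes)."""

    site_id: str
    date: dt.date
    transect_id: str
    depth_class: DepthClass
    salinity: float  # psu

    def __post_init__(self) -> None:
        require_finite("salinity", self.salinity)
        if self.salinity < 0:
            raise ValidationError(
                f"salinity must be >= 0 psu, got {self.salinity!r} "
                f"(site {self.site_id}, {self.date})"
            )
        object.__setattr__(self, "depth_class", DepthClass(self.depth_class))
        if not isinstance(self.date, dt.date):
            raise ValidationError(f"date must be a datetime.date, got {self.date!r}")


@dataclass(frozen=True)
class SiteRecord:
    """A restoration site with its monitoring summary.

    ``pre_mean``/``post_mean`` are pooled means of every observation before /
    on-or-after the restoration date, regardless of transect, depth or season.
    ``post_restoration_years`` is the count of monitored post-restoration
    years that qualify for abatement accounting (annual mean above threshold).
    """

    site_id: str
    name: str
    area_m2: float
    restoration_date: dt.date
    monitoring_start: int
    monitoring_end: int
    post_restoration_years: int
    pre_mean: float
    pre_se: float
    post_mean: float
    post_se: float

    def __post_init__(self) -> None:
        require_positive("area_m2", self.area_m2)
        require_non_negative("pre_se", self.pre_se)
        require_non_negative("post_se", self.post_se)
        require_finite("pre_mean", self.pre_mean)
        require_finite("post_mean", self.post_mean)
        year = self.restoration_date.year
        if not self.monitoring_start <= year <= self.monitoring_end:
            raise ValidationError(
                f"restoration year {year} outside monitoring window "
                f"{self.monitoring_start}-{self.monitoring_end} ({self.site_id})"
            )
        if self.post_restoration_years > self.monitoring_end - year + 1:
            raise ValidationError(
                f"post_restoration_years={self.post_restoration_years} exceeds the "
                f"monitored post-restoration span ({self.site_id})"
            )

    @property
    def area_ha(self) -> float:
        return self.area_m2 / M2_PER_HA


@dataclass(frozen=True)
class SalinitySummary:
    """Mean salinity over a pre or post window, optionally stratified."""

    mean: float  # psu
    standard_error: float  # psu
    n: int
    window: str  # "pre" | "post"
    stratum: str | None = None  # depth class name or calendar year

    def __post_init__(self) -> None:
        require_non_negative("standard_error", self.standard_error)
        if self.n < 1:
            raise ValidationError(f"summary requires n >= 1, got {self.n}")
        if self.window not in ("pre", "post"):
            raise ValidationError(f"window must be 'pre' or 'post', got {self.window!r}")


class OutcomeCategory(str, enum.Enum):
    """Restoration outcome relative to the salinity threshold."""

    SUCCESS = "SUCCESS"
    FAILED_BELOW_THRESHOLD = "FAILED_BELOW_THRESHOLD"
    NOT_IMPAIRED = "NOT_IMPAIRED"


@dataclass(frozen=True)
class RestorationOutcome:
    category: OutcomeCategory
    threshold: float = SALINITY_THRESHOLD_PSU


class MassBasis(str, enum.Enum):
    """Mass basis of an areal methane flux.

    Source emission factors are commonly reported as grams of carbon; the
    crediting methodology's defaults are grams of methane. ``CARBON`` values
    become methane mass when multiplied by 16/12.
    """

    CARBON = "carbon_as_reported"
    METHANE = "methane"


@dataclass(frozen=True)
class EmissionFactor:
    """Areal methane emission rate assigned by salinity regime."""

    value: float  # g m^-2 yr^-1 on `mass_basis`
    mass_basis: MassBasis
    label: str
    salinity_regime: str = ""  # display only, e.g. "<18 psu", "(18, 20] psu"

    def __post_init__(self) -> None:
        require_non_negative("emission factor value", self.value)
        object.__setattr__(self, "mass_basis", MassBasis(self.mass_basis))


@dataclass(frozen=True)
class EmissionScenario:
    """Paired pre/post emission factors used to compute avoided emissions."""

    ef_pre: EmissionFactor
    ef_post: EmissionFactor
    stoichiometric_correction: bool = False

    @property
    def label(self) -> str:
        return f"{self.ef_pre.label}->{self.ef_post.label}"


@dataclass(frozen=True)
class AvoidedEmissions:
    """Avoided methane for one site under one scenario (metric tons CH4)."""

    annual_t: float
    per_hectare_t: float
    cumulative_t: float
    years: int

    def __post_init__(self) -> None:
        if self.years < 0:
            raise ValidationError(f"years must be >= 0, got {self.years}")


class Gas(str, enum.Enum):
    CO2 = "CO2"
    CH4_NONFOSSIL = "CH4_nonfossil"
    N2O = "N2O"


@dataclass(frozen=True)
class GWPEntry:
    """One global-warming-potential entry from an IPCC assessment report."""

    gas: Gas
    horizon: int  # years: 20 or 100
    report: str  # "AR4" | "AR5" | "AR6"
    value: float
    uncertainty: float | None = None

    def __post_init__(self) -> None:
        require_positive("GWP value", self.value)
        if self.horizon not in (20, 100):
            raise ValidationError(f"GWP horizon must be 20 or 100, got {self.horizon}")
        if self.gas == Gas.CO2 and self.value != 1:
            raise ValidationError("CO2 GWP must be 1 for every report and horizon")


@dataclass(frozen=True)
class AdditionalCO2e:
    """Optional additional CO2e terms (soil carbon, N2O, ...), t CO2e yr^-1.

    ``c0`` is the pre-restoration term and ``c1`` the post-restoration term;
    their difference adds to the credit total. Defaults to zero: the avoided
    methane analysis does not derive them.
    """

    c0: float = 0.0
    c1: float = 0.0

    def __post_init__(self) -> None:
        require_finite("c0", self.c0)
        require_finite("c1", self.c1)


@dataclass(frozen=True)
class CreditResult:
    """Verified Carbon Units (1 VCU == 1 t CO2e avoided) and market revenue."""

    vcus_per_year: float
    cumulative_vcus: float
    revenue: float  # $, undiscounted
    price: float  # $ per t CO2e


@dataclass(frozen=True)
class SCMSchedule:
    """Year -> $/t social-cost-of-methane valuation table (2021 dollars)."""

    discount_rate: float  # percent
    entries: dict[int, float]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValidationError("SCM schedule has no entries")
        years = sorted(self.entries)
        gaps = [y for y in range(years[0], years[-1] + 1) if y not in self.entries]
        if gaps:
            from .errors import CoverageError

            raise CoverageError(f"SCM schedule has non-contiguous years; missing {gaps}")
        for year, value in self.entries.items():
            if value <= 0:
                raise ValidationError(f"SCM value for {year} must be positive, got {value}")

    @property
    def start(self) -> int:
        return min(self.entries)

    @property
    def end(self) -> int:
        return max(self.entries)

    def value(self, year: int) -> float:
        try:
            return self.entries[year]
        except KeyError:
            from .errors import CoverageError

            raise CoverageError(
                f"SCM schedule ({self.label or self.discount_rate}%) has no value "
                f"for {year}; covers {self.start}-{self.end}"
            ) from None


@dataclass(frozen=True)
class SocialBenefitResult:
    """Per-year and cumulative avoided social cost for one emission stream."""

    per_year: dict[int, float]
    cumulative: float
    discount_rate: float
    emission_scenario_label: str = ""


@dataclass(frozen=True)
class MarshInventory:
    """Regional inventory of tidally restricted marshes above an effect score."""

    n_marshes: int
    total_area_ha: float
    effect_threshold: float = 0.5
    source_label: str = ""

    def __post_init__(self) -> None:
        require_positive("total_area_ha", self.total_area_ha)
        if not 0.0 <= self.effect_threshold <= 1.0:
            raise ValidationError(
                f"effect_threshold must be in [0, 1], got {self.effect_threshold}"
            )


@dataclass(frozen=True)
class StatewideEstimate:
    """Upper-bound regional estimate from scaling per-hectare rates."""

    abatement_t_per_year: float
    vcus_per_year: float
    revenue_per_year: float
    cumulative_social_benefit: float
    scenario_label: str = ""
    discount_rate: float | None = None
    success_rate: float = 1.0
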