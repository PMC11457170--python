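"""Avoided-methane accounting under configurable emission-factor scenarios.

Avoided annual emissions for a successfully restored site are

    (EF_pre - EF_post) * area / 10^6   [metric tons per year]

with factors in g m^-2 yr^-1. The packaged pre-restoration factors (salinity
below 18 psu) are a meta-analysis geometric mean of 19.4 and a true mean of
41.6, both reported on a carbon-mass basis; the post-restoration factor is
0.46 for any site above the threshold, or the tiered VM0033 defaults
(1.1 g CH4 for 18-20 psu, 0.56 g CH4 above 20 psu).

Replication mode (the default) treats the factor values as output mass
directly, which is how the published tables were produced; pass
``stoichiometric_correction=True`` to convert carbon-basis factors to methane
mass by 16/12.
"""

from __future__ import annotations

import math
from importlib import resources

import yaml

from ._util import require_finite, require_non_negative, require_positive
from .constants import CH4_PER_C, SALINITY_THRESHOLD_PSU
from .errors import ConfigError, UnitError, ValidationError
from .types import (
    AvoidedEmissions,
    EmissionFactor,
    EmissionScenario,
    MassBasis,
    OutcomeCategory,
    SiteRecord,
)


def load_emission_factors(path=None) -> dict[str, EmissionFactor]:
    """Load emission factors keyed by label from YAML (packaged defaults)."""
    if path is None:
        text = resources.files("marshcarbon.data").joinpath("emission_factors.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    factors = {}
    for label, spec in raw["factors"].items():
        factors[label] = EmissionFactor(
            value=float(spec["value"]),
            mass_basis=MassBasis(spec["mass_basis"]),
            label=label,
            salinity_regime=spec.get("salinity_regime", ""),
        )
    return factors


_DEFAULTS = load_emission_factors()

#: Pre-restoration factor, geometric mean of source studies (gC m^-2 yr^-1).
EF_GEOMETRIC_MEAN = _DEFAULTS["geometric_mean"]
#: Pre-restoration factor, true mean of source studies (gC m^-2 yr^-1).
EF_TRUE_MEAN = _DEFAULTS["true_mean"]
#: Post-restoration factor for any site above 18 psu (gC m^-2 yr^-1).
EF_POST_RESTORATION = _DEFAULTS["post_restoration"]
#: VM0033 tiered post-restoration defaults (g CH4 m^-2 yr^-1).
EF_VM0033_18_20 = _DEFAULTS["vm0033_18_20"]
EF_VM0033_GT20 = _DEFAULTS["vm0033_gt20"]

#: The two published pre/post scenarios.
SCENARIO_GEOMETRIC = EmissionScenario(EF_GEOMETRIC_MEAN, EF_POST_RESTORATION)
SCENARIO_TRUE_MEAN = EmissionScenario(EF_TRUE_MEAN, EF_POST_RESTORATION)


def select_post_ef(post_mean: float, scheme: str = "kroeger") -> EmissionFactor:
    """Pick the post-restoration factor for a successful site's salinity.

    ``scheme="kroeger"`` applies 0.46 to any post mean above 18 psu;
    ``scheme="vm0033"`` applies the tiered defaults (1.1 for 18-20 psu,
    0.56 above 20 psu). No factor is defined at or below the threshold.
    """
    post_mean = require_finite("post_mean", post_mean)
    if post_mean <= SALINITY_THRESHOLD_PSU:
        raise ValidationError(
            f"no post-restoration factor is defined for post mean {post_mean} psu "
            f"<= {SALINITY_THRESHOLD_PSU} psu (unsuccessful site)"
        )
    if scheme == "kroeger":
        return EF_POST_RESTORATION
    if scheme == "vm0033":
        return EF_VM0033_18_20 if post_mean <= 20.0 else EF_VM0033_GT20
    raise ConfigError(f"unknown post-factor scheme {scheme!r}")


def _as_factor(ef) -> EmissionFactor:
    if isinstance(ef, EmissionFactor):
        return ef
    return EmissionFactor(value=float(ef), mass_basis=MassBasis.CARBON, label="ad_hoc")


def annual_avoided(
    ef_pre,
    ef_post,
    area_m2: float,
    stoichiometric_correction: bool = False,
) -> float:
    """Annual avoided methane, metric tons per year.

    Accepts :class:`EmissionFactor` objects or bare g m^-2 yr^-1 values. With
    the correction off (replication mode) both factors must share a mass
    basis and the reported values pass through unconverted; with it on,
    carbon-basis factors are multiplied by 16/12 first.
    """
    pre, post = _as_factor(ef_pre), _as_factor(ef_post)
    require_positive("area_m2", area_m2)
    if not stoichiometric_correction and pre.mass_basis != post.mass_basis:
        raise UnitError(
            f"mass bases differ ({pre.mass_basis.value} vs {post.mass_basis.value}); "
            "enable stoichiometric_correction to convert carbon-basis factors"
        )

    def mass(f: EmissionFactor) -> float:
        if stoichiometric_correction and f.mass_basis == MassBasis.CARBON:
            return f.value * CH4_PER_C
        return f.value

    return (mass(pre) - mass(post)) * area_m2 / 1e6


def per_hectare_rate(annual_t: float, area_ha: float) -> float:
    """Avoided methane per hectare, t ha^-1 yr^-1 (== (EF_pre-EF_post)/100)."""
    require_finite("annual_t", annual_t)
    require_positive("area_ha", area_ha)
    return annual_t / area_ha


def cumulative_avoided(annual_t: float, years: int) -> float:
    """Unrounded annual abatement times qualifying years, metric tons."""
    require_finite("annual_t", annual_t)
    if years < 0 or int(years) != years:
        raise ValidationError(f"years must be a non-negative integer, got {years!r}")
    return annual_t * int(years)


def site_abatement(
    site: SiteRecord,
    scenario: EmissionScenario,
    outcome_category: OutcomeCategory | None = None,
    years: int | None = None,
) -> AvoidedEmissions:
    """Avoided emissions for one site; non-SUCCESS sites contribute zero.

    ``years`` defaults to the site's recorded qualifying post-restoration
    years. The outcome is derived from the site's pooled means unless given.
    """
    if outcome_category is None:
        from .salinity import classify_site

        outcome_category = classify_site(site.pre_mean, site.post_mean).category
    if outcome_category != OutcomeCategory.SUCCESS:
        return AvoidedEmissions(annual_t=0.0, per_hectare_t=0.0, cumulative_t=0.0, years=0)
    n_years = site.post_restoration_years if years is None else years
    annual = annual_avoided(scenario.ef_pre, scenario.ef_post, site.area_m2,
                            scenario.stoichiometric_correction)
    return AvoidedEmissions(
        annual_t=annual,
        per_hectare_t=per_hectare_rate(annual, site.area_ha),
        cumulative_t=cumulative_avoided(annual, n_years),
        years=n_years,
    )
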