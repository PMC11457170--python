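"""Salinity-monitoring ingest, aggregation, and restoration-outcome rules.

A tidally restricted ("freshening") marsh is considered impaired when its
pooled mean salinity sits below 18 psu, the level at which methanogenesis is
assumed to shut down. A restoration counts as a SUCCESS only when the pooled
pre-restoration mean was below the threshold and the pooled post-restoration
mean strictly surpasses it; boundary equality resolves away from SUCCESS.

The default aggregation pools every observation in a window regardless of
transect, depth class or season (an unweighted mean with standard error
SD/sqrt(n)); depth- and year-stratified variants are opt-in.
"""

from __future__ import annotations

import datetime as dt
import math
from collections import defaultdict
from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import SALINITY_THRESHOLD_PSU
from .errors import EmptyWindowError, SchemaError, ValidationError
from ._util import require_finite
from .types import (
    DepthClass,
    OutcomeCategory,
    RestorationOutcome,
    SalinityObservation,
    SalinitySummary,
)

#: Canonical observation-table columns.
OBSERVATION_COLUMNS = ("site_id", "date", "transect_id", "depth_class", "salinity_psu")


def load_observations(
    path,
    schema: Mapping[str, str] | None = None,
    date_format: str | None = None,
) -> list[SalinityObservation]:
    """Read an observation CSV into validated :class:`SalinityObservation`\\ s.

    Parameters
    ----------
    path
        CSV file with a header row (comma-separated, UTF-8).
    schema
        Optional mapping from canonical column names
        (``site_id, date, transect_id, depth_class, salinity_psu``) to the
        actual column names in the file. Unmapped names are used verbatim.
    date_format
        Optional ``strftime`` pattern; ISO-8601 is parsed by default.

    Raises
    ------
    SchemaError
        If a required column is absent.
    ValidationError
        Listing the 1-based data-row numbers of unparseable or negative
        salinities, unparseable dates, or unknown depth classes.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    mapping = {name: name for name in OBSERVATION_COLUMNS}
    if schema:
        mapping.update({k: v for k, v in schema.items() if k in mapping})
    missing = [v for v in mapping.values() if v not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}; "
                          f"found {list(frame.columns)}")

    problems: list[str] = []
    observations: list[SalinityObservation] = []
    for idx in range(1, len(frame) + 1):
        raw = {k: frame.iloc[idx - 1][v] for k, v in mapping.items()}
        date = pd.to_datetime(raw["date"], format=date_format, errors="coerce")
        if pd.isna(date):
            problems.append(f"row {idx}: unparseable date {raw['date']!r}")
            continue
        try:
            salinity = float(raw["salinity_psu"])
        except ValueError:
            problems.append(f"row {idx}: unparseable salinity {raw['salinity_psu']!r}")
            continue
        try:
            observations.append(
                SalinityObservation(
                    site_id=str(raw["site_id"]),
                    date=date.date(),
                    transect_id=str(raw["transect_id"]),
                    depth_class=DepthClass(str(raw["depth_class"]).strip().lower()),
                    salinity=salinity,
                )
            )
        except (ValidationError, ValueError) as exc:
            problems.append(f"row {idx}: {exc}")
    if problems:
        raise ValidationError(f"{path}: {len(problems)} bad row(s): " + "; ".join(problems))
    return observations


def _window_of(obs: SalinityObservation, restoration_date: dt.date) -> str:
    return "pre" if obs.date < restoration_date else "post"


def _summary(values: Sequence[float], window: str, stratum: str | None) -> SalinitySummary:
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    se = 0.0 if arr.size < 2 else float(arr.std(ddof=1) / math.sqrt(arr.size))
    return SalinitySummary(mean=mean, standard_error=se, n=int(arr.size),
                           window=window, stratum=stratum)


def summarize_salinity(
    observations: Iterable[SalinityObservation],
    restoration_date: dt.date,
    window: str,
    stratify_by: str = "none",
) -> list[SalinitySummary]:
    """Pooled (or stratified) mean salinity for one window of one site.

    ``stratify_by`` is ``"none"`` (pool everything), ``"depth"`` (one summary
    per depth class) or ``"year"`` (one per calendar year). Observations dated
    strictly before ``restoration_date`` are "pre"; on/after are "post".
    """
    if window not in ("pre", "post"):
        raise ValidationError(f"window must be 'pre' or 'post', got {window!r}")
    if stratify_by not in ("none", "depth", "year"):
        raise ValidationError(f"stratify_by must be none|depth|year, got {stratify_by!r}")
    selected = [o for o in observations if _window_of(o, restoration_date) == window]
    if not selected:
        raise EmptyWindowError(
            f"no observations in the {window!r} window relative to {restoration_date}"
        )
    if stratify_by == "none":
        return [_summary([o.salinity for o in selected], window, None)]
    groups: dict[str, list[float]] = defaultdict(list)
    for o in selected:
        key = o.depth_class.value if stratify_by == "depth" else str(o.date.year)
        groups[key].append(o.salinity)
    return [_summary(vals, window, key) for key, vals in sorted(groups.items())]


def classify_site(
    pre_mean: float,
    post_mean: float,
    threshold: float = SALINITY_THRESHOLD_PSU,
) -> RestorationOutcome:
    """Classify a restoration from pooled pre/post mean salinities.

    SUCCESS requires ``pre_mean < threshold`` (the marsh was impaired) and
    ``post_mean > threshold`` (the restoration surpassed the threshold);
    an impaired site whose post mean fails to surpass the threshold is
    FAILED_BELOW_THRESHOLD; a site never below the threshold is NOT_IMPAIRED
    and contributes no avoided emissions.
    """
    pre_mean = require_finite("pre_mean", pre_mean)
    post_mean = require_finite("post_mean", post_mean)
    threshold = require_finite("threshold", threshold)
    if pre_mean >= threshold:
        category = OutcomeCategory.NOT_IMPAIRED
    elif post_mean > threshold:
        category = OutcomeCategory.SUCCESS
    else:
        category = OutcomeCategory.FAILED_BELOW_THRESHOLD
    return RestorationOutcome(category=category, threshold=threshold)


def qualifying_years(
    observations: Iterable[SalinityObservation],
    restoration_date: dt.date,
    threshold: float = SALINITY_THRESHOLD_PSU,
) -> list[tuple[int, float, bool]]:
    """Per-calendar-year post-restoration means and their qualification.

    Returns ``(year, annual mean psu, qualifies)`` tuples ordered by year,
    where a year qualifies when its mean strictly exceeds ``threshold``.
    Years below threshold form the post-restoration "lag phase" and are
    excluded from cumulative abatement accounting.
    """
    summaries = summarize_salinity(observations, restoration_date, "post",
                                   stratify_by="year")
    return [(int(s.stratum), s.mean, s.mean > threshold) for s in summaries]


def count_qualifying_years(
    observations: Iterable[SalinityObservation],
    restoration_date: dt.date,
    threshold: float = SALINITY_THRESHOLD_PSU,
) -> int:
    return sum(1 for _, _, q in qualifying_years(observations, restoration_date, threshold) if q)


def site_summary_frame(
    observations: Iterable[SalinityObservation],
    restoration_dates: Mapping[str, dt.date],
    threshold: float = SALINITY_THRESHOLD_PSU,
) -> pd.DataFrame:
    """Per-site summary table: pre/post mean, SE, n, outcome, qualifying years.

    ``restoration_dates`` maps site_id to its restoration date; sites present
    in the observations but absent from the mapping are skipped.
    """
    by_site: dict[str, list[SalinityObservation]] = defaultdict(list)
    for o in observations:
        by_site[o.site_id].append(o)
    rows = []
    for site_id, obs in sorted(by_site.items()):
        if site_id not in restoration_dates:
            continue
        rdate = restoration_dates[site_id]
        pre = summarize_salinity(obs, rdate, "pre")[0]
        post = summarize_salinity(obs, rdate, "post")[0]
        outcome = classify_site(pre.mean, post.mean, threshold)
        rows.append({
            "site_id": site_id,
            "pre_mean_psu": pre.mean,
            "pre_se_psu": pre.standard_error,
            "pre_n": pre.n,
            "post_mean_psu": post.mean,
            "post_se_psu": post.standard_error,
            "post_n": post.n,
            "outcome": outcome.category.value,
            "qualifying_years": count_qualifying_years(obs, rdate, threshold),
        })
    return pd.DataFrame(rows)
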