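# Methods

## Scope and model

`marshcarbon` values one intervention: restoring tidal flushing to a
freshening salt marsh so that salinity rises back above the threshold at
which methanogenesis is assumed to stop. The chain is

1. **Classification.** Pool every salinity observation before / on-or-after
   the restoration date into one pre and one post mean (unweighted across
   transect, depth class, and season; standard error = sample SD/√n).
   SUCCESS requires `pre_mean < 18 psu` and `post_mean > 18 psu` — both
   strict, so boundary equality resolves away from SUCCESS (a site whose pre
   mean sits exactly at or above 18 is treated as never impaired, matching
   how an 18.3 psu pre-restoration site is handled in the packaged table).
   Only SUCCESS sites proceed; FAILED and NOT_IMPAIRED sites contribute
   exactly zero abatement.
2. **Avoided emissions.** `(EF_pre − EF_post) × area / 10⁶` t yr⁻¹, factors
   in g m⁻² yr⁻¹, assumed uniform over the whole marsh area.
3. **Crediting.** Avoided tons × GWP_CH₄ (+ net additional CO₂e terms) =
   VCUs yr⁻¹; one VCU ≡ 1 t CO₂e. Credits accumulate over qualifying years
   and sell undiscounted at a flat price (default $20/t).
4. **Social valuation.** Avoided tons × the year's social cost of methane,
   summed 2021–2050. The emission rate is held constant across the window;
   restorations that predate the schedule are valued forward from 2021 by
   convention (the schedule's base year), not from their completion date.
5. **Scaling.** Per-hectare rate × the area of a regional tidal-restriction
   inventory (restriction effect score > 0.5), optionally multiplied by a
   success fraction (the observed 2-of-6 ≈ 1/3 to 4-of-6 ≈ 2/3 range).

## Parameters

| parameter | default | units | notes |
|---|---|---|---|
| salinity threshold | 18 | psu | methanogenesis cutoff; psu ≡ ppt here |
| EF_pre (geometric mean) | 19.4 | g m⁻² yr⁻¹ | meta-analysis, salinity < 18 |
| EF_pre (true mean) | 41.6 | g m⁻² yr⁻¹ | same studies, arithmetic mean |
| EF_post ("kroeger") | 0.46 | g m⁻² yr⁻¹ | any post mean > 18 |
| EF_post (VM0033 tiers) | 1.1 / 0.56 | g CH₄ m⁻² yr⁻¹ | (18, 20] / > 20 psu |
| GWP_CH₄ | 27.2 | – | AR6 100-yr, non-fossil (±11 stored, not propagated) |
| credit price | 20 | $/t CO₂e | undiscounted |
| discount rate | 3 | % | 2.5 and 5 % schedules also packaged |
| inventory | 475 marshes, 2,304 acres | – | effect score > 0.5 |

The full IPCC GWP table (AR4/AR5/AR6 × 20/100-yr for CO₂, CH₄, N₂O) ships as
data; swapping reports rescales credits by exactly the GWP ratio. AR5
entries use the no-feedback values (28, 84, 265, 264); AR6 uncertainty bands
are stored for optional low/high runs but not propagated by default.

## Mass-basis convention

The pre-restoration factors are reported in the source literature as grams
of *carbon*, while credits are denominated in methane mass. Replication
mode — the default — passes the reported factor values through unconverted,
because that is how the reference tables this package reproduces were
computed. The chemically explicit alternative
(`stoichiometric_correction=True`) multiplies carbon-basis factors by 16/12
before differencing, and is also the only way to mix a carbon-basis pre
factor with the methane-basis VM0033 post tiers (otherwise a `UnitError` is
raised). "Mt" in some source material means metric tons, not megatons; all
interfaces here say metric tons explicitly.

## Rounding and rendering

Accounting carries full precision end to end; only the report layer rounds,
and it reproduces the published tables' exact rendering chain:

- displayed annual emissions: 2 d.p.; displayed annual VCUs: the *displayed*
  emissions × GWP, to 1 d.p. (0.21 × 27.2 → 5.7);
- totals rows sum displayed cells (0.21 + 3.07 = 3.28);
- cumulative credits/benefits use unrounded annual values rounded once at
  the end (985 VCUs, not 987 from pre-rounded parts);
- revenue prices whole credits (985 × $20 = $19,700); dollars render
  half-up to whole dollars; combined dollar totals sum per-site
  whole-dollar totals ($14,151 + $209,102 = $223,253).

Half-up (spreadsheet) rounding is used for rendered figures, not Python's
banker's rounding.

## Data shipped with the package

- **Six-site monitoring table** (areas, restoration dates, pooled pre/post
  means ± SE, qualifying post-restoration years 12 and 11 for the two
  successful sites). When raw observations are supplied, qualifying years
  are recomputed per calendar year (January–December; the restoration year
  belongs to the post window from the restoration date onward); the table's
  printed counts are used otherwise.
- **SCM schedules** at 2.5/3/5 %, 2021–2050, $/t in 2021 dollars. The 3 %
  schedule's first decade is the published sequence (1500, 1600, 1600, 1700,
  1700, 1800, 1800, 1900, 1900, 2000). Later years are reconstructed by
  linear interpolation of the five-year Interagency Working Group anchor
  values rounded to the nearest $100 — the rule that generates the published
  first decade — constrained to the published cumulative value of
  68,200 $/t over 2021–2050 (the interpolant for 2034, 2,160, is taken as
  2,100). The 2.5 % and 5 % schedules are reconstructed the same way from
  their anchors and feed only the discount-rate monotonicity property, not
  any headline number. A social-cost-of-carbon schedule can be supplied
  through the identical CSV mechanism to value a sequestration stream; none
  ships with the package.
- **Inventory summary**: 2,304 acres converted at 4,047 m²/acre
  (932.4288 ha). The rounded-up survey conversion, rather than the exact
  4,046.86, is what reconciles the statewide dollar column digit-for-digit;
  a per-marsh CSV (id, area, effect score) filtered at effect > 0.5 is the
  alternative input.

## Synthetic data generator

`generate_site` draws observations as *yearly true mean + depth offset +
seasonal sinusoid + independent N(0, σ) noise*, truncated at 0 psu, on a
deterministic calendar/transect/depth grid, so identical (scenario, seed)
yields byte-identical CSVs. A lag phase (first *k* post-restoration years
forced below threshold) emulates the delayed salinity response seen at some
sites. The generator emulates the *structure* of real monitoring data —
means, SEs, depth strata, annual variation — but not serial correlation,
tidal-stage or temperature covariates, spatial gradients beyond fixed depth
offsets, or non-Gaussian error; passing recovery tests therefore shows the
pipeline is correct given its model, not that the model captures every
feature of field data. Default scenario sizes (16 monitored years, 48
observations/year, σ = 2 psu) echo the packaged sites' data density; the
replication experiments in the test suite use a reduced grid (10 years ×
12 obs/year, 200 seeds) chosen so the |mean − threshold| > 3·SE margin
clearly holds, which keeps the whole suite under a few seconds.

## Numerical and design choices

- Duplicate same-day, same-depth measurements are treated as independent
  observations (the aggregation rule is a plain pooled mean).
- The VM0033 tier boundary is inclusive at 20 psu ((18, 20] → 1.1; > 20 →
  0.56); no post factor exists at or below 18, which raises instead of
  silently crediting an unsuccessful site.
- A single pre-restoration factor applies however far below threshold a
  site sits; no interpolation in salinity is defined or attempted.
- Depth-stratified and per-year aggregation are opt-in flags; the
  depth-stratified mode is provided for exploration without asserting that
  the emission-factor framework is valid per depth band.
- Credits are kept real-valued internally and rounded at rendering;
  registry practice issues integral credits, hence `revenue()` prices whole
  units by default.
- Statewide per-year credit revenue is reported from unrounded
  intermediates; marsh extent is assumed fixed (no boundary migration).

## Limitations

Salinity is a proxy: the pipeline never observes methane, and its validity
inherits from the emission-factor literature, which brackets a wide range
(19.4 vs 41.6 g m⁻² yr⁻¹ — a factor of ~2.2 in every downstream number).
Applying three transects' data to a whole marsh ignores spatial
heterogeneity in flux. The statewide figure is an upper bound that assumes
every restriction is remediated successfully; the success-rate adjustment
is a blunt correction. SCM values beyond the packaged schedules'
reconstruction, buffer pools, leakage, and verification costs of a full
crediting workflow are out of scope.
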