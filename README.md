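# marshcarbon

Methane-abatement accounting and valuation for salt-marsh restoration,
using salinity as the emission proxy.

Tidally restricted ("freshening") salt marshes turn from carbon sinks into
methane sources: once pore-water salinity drops below about 18 psu,
methanogenesis switches on. Restoring tidal flushing (e.g. culvert widening)
can push salinity back above the threshold and shut those emissions down.
`marshcarbon` turns ordinary pre/post-restoration salinity monitoring into a
greenhouse-gas ledger for that intervention: avoided methane, Verified Carbon
Unit (VCU) credits under a VM0033-style proxy methodology, dollar value at the
social cost of methane, and an upper-bound regional scale-up against a
tidal-restriction inventory. It is written for restoration practitioners,
state GHG-inventory analysts, and blue-carbon researchers.

## The model

A restoration is a **SUCCESS** when the pooled pre-restoration mean salinity
was below the threshold *T* = 18 psu and the pooled post-restoration mean
strictly surpasses it. Successful sites avoid methane at

```
E_avoided = (EF_pre − EF_post) · A / 10⁶        [t CH₄ yr⁻¹]
```

with areal emission factors EF in g m⁻² yr⁻¹ (pre: 19.4 geometric-mean or
41.6 true-mean for < 18 psu marsh; post: 0.46 above threshold, or the tiered
VM0033 defaults 1.1 / 0.56 g CH₄) and marsh area *A* in m². Credits and
social value follow

```
VCU yr⁻¹ = (E₀ − E₁)·A · GWP_CH₄ + (C₀ − C₁)·A        (GWP_CH₄ = 27.2, AR6 100-yr)
SCM      = Σ_{i=2021}^{2050} (E₀ − E₁)·A · Y_{i,a%}
```

where `Y_{i,a%}` is the social cost of methane ($/t, 2021 dollars) for year
*i* at discount rate *a* (2.5 / 3 / 5 %; 3 % default), and the optional
C-terms accept user-supplied additional CO₂e streams (soil carbon, N₂O).
Cumulative abatement multiplies the annual rate by the number of qualifying
post-restoration years (annual mean above threshold; below-threshold "lag"
years are excluded).

## Worked example

The package ships the six-site Massachusetts monitoring table, emission
factors, IPCC GWP table, and SCM schedules, so the whole analysis runs from
one call:

```python
>>> from marshcarbon import replicate_study
>>> r = replicate_study()
>>> r["successful_site_ids"]
['eastern_point', 'mill_pond']
>>> low = r["scenarios"]["EF 19.4"]
>>> low["per_site"]["eastern_point"]["annual_t_printed"]
0.21
>>> low["cumulative_vcus"]
985.0733395199999
>>> low["revenue_usd"]
19700.0
>>> low["statewide"]["social_2021_2050_usd"]
12044257.0
```

Of the six monitored restorations, two (Eastern Point, Mill Pond; 17.3 ha
combined) crossed the 18 psu threshold. Under the conservative
geometric-mean factor they avoid 0.21 and 3.07 t CH₄ yr⁻¹ respectively —
0.19 t CH₄ ha⁻¹ yr⁻¹ — worth 5.7 and 83.5 VCUs yr⁻¹ at GWP 27.2. Over their
12 and 11 qualifying years that is 36 t CH₄, 985 VCUs, and $19,700 at
$20/t CO₂e; valued at the 3 % social cost of methane over 2021–2050 the same
stream is worth $223,253. Scaling the per-hectare rate to all 475
Massachusetts marshes with a severe tidal restriction (2,304 acres) bounds
the statewide potential at 176.6 t CH₄ yr⁻¹ and $12.0M of avoided social
cost by 2050 (the true-mean factor roughly doubles each figure).

The same computations are available from a shell:

```sh
marshcarbon simulate --preset table1 --out sites.csv
marshcarbon credit --gwp-report AR6 --horizon 100
marshcarbon value --discount-rate 3
marshcarbon scale --area-acres 2304 --success-rate 0.33
```

and `marshcarbon classify obs.csv --restoration-date 2003-11-01` summarizes
and classifies a raw observation CSV
(`site_id,date,transect_id,depth_class,salinity_psu`).

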