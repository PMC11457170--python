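# Areal methane emission factors by salinity regime, g m^-2 yr^-1.
#
# Pre-restoration (freshening, < 18 psu) factors come from published
# meta-analyses and are reported on a carbon-mass basis (gC); the tiered
# post-restoration defaults of the VM0033 tidal-wetland crediting methodology
# are reported as methane mass (g CH4).
factors:
  geometric_mean:
    value: 19.4
    mass_basis: carbon_as_reported
    salinity_regime: "<18 psu"
    role: pre
  true_mean:
    value: 41.6
    mass_basis: carbon_as_reported
    salinity_regime: "<18 psu"
    role: pre
  post_restoration:
    value: 0.46
    mass_basis: carbon_as_reported
    salinity_regime: ">18 psu"
    role: post
    scheme: kroeger
  vm0033_18_20:
    value: 1.1
    mass_basis: methane
    salinity_regime: "(18, 20] psu"
    role: post
    scheme: vm0033
  vm0033_gt20:
    value: 0.56
    mass_basis: methane
    salinity_regime: ">20 psu"
    role: post
    scheme: vm0033
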