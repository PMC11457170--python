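site_id,name,monitoring_start,monitoring_end,restoration_date,post_restoration_years,n_observations,pre_mean_psu,pre_se_psu,post_mean_psu,post_se_psu,area_m2
conomo_point,"Essex, MA, Conomo Point Road",1998,2015,2000-11-01,15,961,18.3,0.94,23.7,0.41,54197
eastern_point,"Gloucester, MA, Eastern Point",2000,2015,2003-11-01,12,764,10.2,0.52,19.0,0.3,10955
cedar_point,"Ipswich, MA, Cedar Point",1999,2015,2000-04-01,15,249,12.6,0.75,9.8,0.63,12869
town_farm,"Ipswich, MA, Town Farm Road",1996,2015,2005-04-01,10,829,27.4,0.51,25.7,0.36,97128
seaview_street,"Rockport, MA, Seaview Street",1998,2015,2003-10-01,12,371,17.7,1.7,16.9,0.42,12141
mill_pond,"Gloucester, MA, Mill Pond",1998,2015,2004-04-01,11,808,17.4,0.44,19.7,0.32,161880
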