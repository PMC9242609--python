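incentive_id,count,probability
anc_series,0,0.15
anc_series,1,0.35
anc_series,2,0.25
anc_series,3,0.15
anc_series,4,0.10
pnc_home_visits,0,0.10
pnc_home_visits,1,0.20
pnc_home_visits,2,0.16
pnc_home_visits,3,0.14
pnc_home_visits,4,0.12
pnc_home_visits,5,0.10
pnc_home_visits,6,0.10
pnc_home_visits,7,0.08
full_immunization_year1,0,0.05
full_immunization_year1,1,0.06
full_immunization_year1,2,0.07
full_immunization_year1,3,0.08
full_immunization_year1,4,0.10
full_immunization_year1,5,0.12
full_immunization_year1,6,0.14
full_immunization_year1,7,0.38
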