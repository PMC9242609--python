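key,value,provenance
anc_home_visit,0.55,SYNTHETIC placeholder
anc4_completion_given_contact,0.264,government statistics (placeholder for conditional rate)
counsel_facility_delivery,0.6,linked household survey
facility_delivery_given_counseling,0.66,linked household survey
pnc_visit_coverage,0.54,SYNTHETIC placeholder
sick_newborn_identification,0.4,SYNTHETIC placeholder
sncu_admission_given_referral,0.5,SYNTHETIC placeholder
sncu_discharge_followup,0.35,SYNTHETIC placeholder
underweight_child_visit_rate,0.3,SYNTHETIC placeholder
counsel_nrc_referral,0.3,SYNTHETIC placeholder
nrc_attendance_given_counseling,0.25,SYNTHETIC placeholder
counsel_limiting_methods,0.4,SYNTHETIC placeholder
female_sterilization_given_counseling,0.05,SYNTHETIC placeholder
male_sterilization_given_counseling,0.005,SYNTHETIC placeholder
counsel_ppiucd,0.3,SYNTHETIC placeholder
ppiucd_adoption_given_counseling,0.1,SYNTHETIC placeholder
counsel_spacing_methods,0.4,SYNTHETIC placeholder
spacing_adherence_given_counseling,0.08,SYNTHETIC placeholder
deliver_contraceptives,0.35,SYNTHETIC placeholder
fp_followup_visit,0.3,SYNTHETIC placeholder
method_continuation_given_followup,0.5,SYNTHETIC placeholder
mobilize_immunization,0.6,SYNTHETIC placeholder
full_immunization_given_mobilization,0.511,national family health survey (placeholder for conditional rate)
dpt_booster_given_mobilization,0.45,SYNTHETIC placeholder
vhnd_mobilization_done,0.7,SYNTHETIC placeholder
measles2_given_mobilization,0.4,SYNTHETIC placeholder
recordkeeping_maintained,0.75,independent recordkeeping audit
attend_monthly_meeting,0.8,SYNTHETIC placeholder
attend_block_meeting,0.65,program monitoring data (placeholder)
village_census_updated,0.6,SYNTHETIC placeholder
couple_list_updated,0.6,SYNTHETIC placeholder
vhir_maintained,0.55,SYNTHETIC placeholder
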