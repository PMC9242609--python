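key,value,basis,description,source
PREGNANCY,27.28,PER_1000_PER_YEAR,annual crude birth rate used as a proxy for pregnant-woman incidence,vital-registration bulletin (fixture value)
NEWBORN,27.28,PER_1000_PER_YEAR,annual live births,vital-registration bulletin (fixture value)
SICK_NEWBORN,2.0,PER_1000_PER_YEAR,newborns needing sick-newborn-care-unit admission,service statistics (placeholder)
INFANT_MORTALITY,43.0,PER_1000_PER_YEAR,infant deaths per 1000 live births scaled to population,vital-registration bulletin (placeholder)
NEONATAL_MORTALITY,30.0,PER_1000_PER_YEAR,neonatal deaths per 1000 live births scaled to population,vital-registration statistical report (placeholder)
CHILD_U5,0.136,PROPORTION,proportion of the population aged five years or younger,census projection (placeholder)
ELIGIBLE_COUPLE,0.17,PROPORTION,proportion of the population that is an eligible family-planning couple,government order on contraceptive home delivery (placeholder)
SEVERE_WASTING_U5,0.006,PROPORTION,proportion of the population that is a severely wasted child under five,rapid child survey (placeholder)
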