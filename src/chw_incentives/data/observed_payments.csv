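category,fiscal_year,mean_monthly_inr,source
ROUTINE,2017-2018,941,state payment records (published decomposition)
ANC_ID,2017-2018,789,state payment records (published decomposition)
PNC,2017-2018,376,state payment records (published decomposition)
IMMUNIZATION,2017-2018,387,state payment records (published decomposition)
FP,2017-2018,87,residual of published total 2580 minus named categories
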