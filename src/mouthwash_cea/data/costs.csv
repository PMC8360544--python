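name,setting,source_currency,source_year,raw_value,adjusted_2020_intl_usd,unit,distribution
pneumonia_episode,USA,USD,2011,23030,3752,per_episode,gamma
bed_day,South Africa,USD,2008,58,71,per_day,gamma
icu_day,UK,GBP,2015,487,1210,per_day,gamma
chlorhexidine,UK,GBP,2020,8,3,per_patient,gamma
mv_episode,UK,GBP,2018,242,89,per_episode,gamma
procedure,South Africa,GBP,2015,1670,1423,per_patient,gamma
covid,South Africa,USD,2019,248,254,per_patient,gamma
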