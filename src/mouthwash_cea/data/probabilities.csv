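name,arm,printed_value,events,total,distribution,derivation
pneumonia,no_mouthwash,0.04,39,931,beta,source
pn_ccu,no_mouthwash,0.54,21,39,beta,source
pn_mv,no_mouthwash,0.25,,,beta,source
pn_died_mv,no_mouthwash,0.48,10,21,beta,source
pn_died_ccu_nomv,no_mouthwash,0.40,17,42,beta,source
pn_died_ward,no_mouthwash,0.04,3,75,beta,source
np_ccu,no_mouthwash,0.10,85,887,beta,source
np_mv,no_mouthwash,0.24,,,fixed,source
np_died_mv,no_mouthwash,0.04,,,fixed,source
np_died_ccu_nomv,no_mouthwash,0.34,29,85,beta,source
np_died_ward,no_mouthwash,0.03,25,802,beta,source
pneumonia,mouthwash,0.03,27,931,beta,rrr
pn_ccu,mouthwash,0.38,15,39,beta,rrr
pn_mv,mouthwash,0.18,,,fixed,rrr
pn_died_mv,mouthwash,0.33,7,21,beta,rrr
pn_died_ccu_nomv,mouthwash,0.28,12,42,beta,rrr
pn_died_ward,mouthwash,0.04,3,75,beta,copy
np_ccu,mouthwash,0.10,85,887,beta,copy
np_mv,mouthwash,0.24,,,fixed,copy
np_died_mv,mouthwash,0.04,,,fixed,copy
np_died_ccu_nomv,mouthwash,0.34,29,85,beta,copy
np_died_ward,mouthwash,0.03,25,802,beta,copy
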