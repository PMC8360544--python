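kind,arm,target,base,lower,upper
cost,,pneumonia_episode,3752,121,5804
cost,,bed_day,71,57,85
prob,no_mouthwash,pneumonia,0.04,0.03,0.05
prob,no_mouthwash,pn_ccu,0.54,0.43,0.64
prob,no_mouthwash,pn_mv,0.25,0.10,0.40
prob,no_mouthwash,np_ccu,0.10,0.08,0.11
prob,no_mouthwash,np_mv,0.24,0.14,0.30
prob,no_mouthwash,np_died_ccu_nomv,0.04,0.01,0.08
los,no_mouthwash,pneumonia_ward,11.36,9.09,13.63
los,no_mouthwash,pneumonia_ccu_nomv,18.99,15.19,22.79
los,no_mouthwash,pneumonia_ccu_mv,21.12,16.90,25.34
prob,mouthwash,pneumonia,0.04,0.03,0.05
prob,mouthwash,pn_ccu,0.53,0.43,0.64
prob,mouthwash,pn_mv,0.25,0.10,0.40
prob,mouthwash,np_ccu,0.10,0.08,0.11
prob,mouthwash,np_mv,0.24,0.14,0.30
prob,mouthwash,np_died_ccu_nomv,0.04,0.01,0.08
los,mouthwash,pneumonia_ward,11.36,9.09,13.63
los,mouthwash,pneumonia_ccu_nomv,18.99,15.19,22.79
los,mouthwash,pneumonia_ccu_mv,21.12,16.90,25.34
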