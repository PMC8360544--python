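pathway_class,mean_days
pneumonia_ccu_mv,21.12
pneumonia_ccu_nomv,18.31
pneumonia_ward,11.36
nopneumonia_ccu_mv,15.32
nopneumonia_ccu_nomv,12.51
nopneumonia_ward,6.69
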