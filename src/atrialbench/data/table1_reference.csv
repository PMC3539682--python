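property,C,N,M,K,G
amplitude_mV,110.11,116.14,119.14,120.77,81.38
rmp_mV,-81.04,-74.15,-73.82,-76.13,-73.53
apd50_ms,165.16,29.55,29.77,20.98,125.30
apd90_ms,294.83,220.34,197.09,259.58,330.13
dvdt_max_V_s,186.58,149.77,160.66,168.54,92.50
cat_diastolic_uM,0.115,0.065,0.065,0.136,0.208
cat_amplitude_uM,0.649,1.235,1.227,0.496,0.257
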