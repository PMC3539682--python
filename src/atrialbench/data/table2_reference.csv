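property,C,N,M,K,G
amplitude_mV,121.58,134.92,137.10,138.08,133.28
rmp_mV,-84.34,-80.29,-79.65,-81.30,-81.99
apd50_ms,74.99,30.14,35.33,29.17,39.54
apd90_ms,143.87,115.13,115.59,109.21,85.70
dvdt_max_V_s,211.38,174.96,182.47,179.26,359.53
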