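model,variant,cv_mm_s,erp_ms,wl_mm
C,control,751.9,302,227.1
N,control,657.9,234,153.9
M,control,680.2,207,140.8
K,control,714.3,192,137.1
G,control,,,
C,caf,602.4,152,91.6
N,caf,588.2,137,80.6
M,caf,595.2,133,79.2
K,caf,578.0,123,71.1
G,caf,909.1,116,105.4
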