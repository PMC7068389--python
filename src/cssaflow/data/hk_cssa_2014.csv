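age_band,p_enter,q_leave
0-9,0.0145,0.1775
10-19,0.0478,0.1356
20-29,0.0015,0.2103
30-39,0.0033,0.1959
40-49,0.0032,0.1379
50-59,0.0028,0.1217
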