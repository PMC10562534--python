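time,n_risk
0.0,400
6.0,346
12.0,302
18.0,266
24.0,244
30.0,223
36.0,202
42.0,189
48.0,171
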