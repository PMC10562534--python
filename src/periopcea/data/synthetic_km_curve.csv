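time,survival
0.0,1.0
1.587433,0.992347
2.294079,0.984573
2.593574,0.976759
4.179975,0.968803
4.503198,0.960811
5.209184,0.955444
5.862148,0.947339
8.554744,0.939035
8.760733,0.933378
9.921776,0.924814
10.028816,0.919025
11.316638,0.910262
11.635697,0.904351
12.533778,0.895456
12.881446,0.889476
13.659607,0.880491
14.674262,0.87447
15.347704,0.865382
16.120793,0.859299
16.127488,0.853204
16.746073,0.844052
16.846136,0.837936
18.063606,0.828659
18.27118,0.822405
20.229173,0.816065
21.797064,0.8096
24.488394,0.799753
25.814123,0.793047
26.975365,0.78621
32.118799,0.779219
32.729645,0.772086
33.401845,0.76492
34.32164,0.757704
35.3252,0.750418
37.341623,0.742895
40.625507,0.735275
42.750447,0.727494
45.685465,0.719476
47.659802,0.711346
47.70978,0.707258
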