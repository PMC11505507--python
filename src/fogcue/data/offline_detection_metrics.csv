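person,accuracy,precision,sensitivity,specificity,f1,num_ps
1,0.941,0.010,0.006,0.951,0.016,30
2,0.986,0.008,0.005,0.994,0.007,60
3,0.959,0.024,0.018,0.982,0.020,15
4,0.913,0.050,0.067,0.934,0.057,30
5,0.947,0.024,0.031,0.971,0.026,40
6,0.958,0.023,0.022,0.980,0.021,30
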