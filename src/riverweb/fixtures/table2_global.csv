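section,step,n_nodes,links,density,clustering,distance,small_world
Upper,raw,149,1162,0.105,0.002,2.367,0.001
Upper,T1,146,1162,0.110,0.053,2.311,0.023
Upper,T2,144,1008,0.098,0.037,2.325,0.016
Upper,T3,127,410,0.051,0.056,2.349,0.024
Upper,T4,16,41,0.333,0.271,1.783,0.152
Upper,T5,14,39,0.418,0.323,1.648,0.196
Middle,raw,156,1274,0.105,0.000,2.381,0.000
Middle,T1,152,1274,0.111,0.015,2.301,0.007
Middle,T2,151,1266,0.112,0.015,2.300,0.007
Middle,T3,124,377,0.049,0.036,2.000,0.018
Middle,T4,20,46,0.232,0.191,1.921,0.099
Middle,T5,18,44,0.275,0.286,1.850,0.155
Lower,raw,58,314,0.190,0.004,2.267,0.002
Lower,T1,55,314,0.211,0.043,2.137,0.020
Lower,T2,55,314,0.211,0.043,2.137,0.020
Lower,T3,37,108,0.161,0.130,2.006,0.065
Lower,T4,16,32,0.258,0.241,2.008,0.120
Lower,T5,13,30,0.372,0.344,1.718,0.200
Master,raw,219,2229,0.093,0.002,2.417,0.001
Master,T1,213,2229,0.099,0.041,2.333,0.018
Master,T2,211,2074,0.094,0.029,2.339,0.012
Master,T3,181,681,0.042,0.042,2.101,0.020
Master,T4,23,65,0.249,0.243,1.929,0.126
Master,T5,20,61,0.311,0.308,1.779,0.173
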