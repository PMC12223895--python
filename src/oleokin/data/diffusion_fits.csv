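temperature_C,A,B_per_s,sse,r_squared,r_squared_adj,rmse
25,0.999,1.18e-4,0.0113,0.810,0.783,0.1062
50,0.944,2.71e-4,0.0091,0.903,0.889,0.0952
60,0.954,3.78e-4,0.0048,0.954,0.947,0.0693
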