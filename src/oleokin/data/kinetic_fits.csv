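temperature_C,model,k,k_std,n,n_std,r_squared,r_squared_adj,sse,rmse
25,pseudo_first_order,0.00703,0.001,,,0.4947,,0.1425,0.1688
50,pseudo_first_order,0.01782,0.002,,,0.8538,,0.07697,0.1241
60,pseudo_first_order,0.02197,0.002,,,0.9405,,0.03617,0.08505
25,brimberg,0.2614,0.05,0.2468,0.08,0.9952,0.994,0.00134,0.01833
50,brimberg,0.1945,0.03,0.4247,0.06,0.9849,0.984,0.00793,0.04451
60,brimberg,0.1453,0.05,0.528,0.06,0.9906,0.9883,0.528,0.03774
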