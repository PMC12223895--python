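component,percent,std
total_lipids,64.19,3.77
protein,22.53,2.66
carbohydrates,11.06,1.57
ash,3.11,0.24
moisture,2.04,0.03
hexane_extractable_lipids,55.68,2.44
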