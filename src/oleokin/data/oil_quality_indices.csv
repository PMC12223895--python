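parameter,unit,temperature_C,value,std
peroxide_value,mEq_peroxides_per_kg_oil,25,0.08,0.01
peroxide_value,mEq_peroxides_per_kg_oil,50,0.09,0.00
peroxide_value,mEq_peroxides_per_kg_oil,60,0.10,0.00
saponification_value,mg_KOH_per_g,25,240.08,1.41
saponification_value,mg_KOH_per_g,50,240.23,1.79
saponification_value,mg_KOH_per_g,60,242.96,1.90
free_fatty_acid,pct_oleic_acid,25,2.87,0.05
free_fatty_acid,pct_oleic_acid,50,2.82,0.06
free_fatty_acid,pct_oleic_acid,60,2.76,0.09
iodine_value,cgI2_per_g,25,6.74,0.81
iodine_value,cgI2_per_g,50,7.31,0.99
iodine_value,cgI2_per_g,60,8.71,0.72
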