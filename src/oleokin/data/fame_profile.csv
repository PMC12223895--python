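name,shorthand,area_pct,std,temperature_C
caproic acid,C6:0,0.28,0.07,25
caprylic acid,C8:0,7.14,0.81,25
capric acid,C10:0,6.78,0.21,25
undecylic acid,C11:0,0.03,0.00,25
lauric acid,C12:0,49.65,1.5,25
tridecylic acid,C13:0,0.03,0.00,25
myristic acid,C14:0,14.61,0.82,25
palmitic acid,C16:0,7.42,0.23,25
stearic acid,C18:0,3.18,0.53,25
oleic acid,C18:1,8.62,0.91,25
linoleic acid,C18:2,2.10,0.13,25
arachidic acid,C20:0,0.06,0.01,25
eicosenoic acid,C20:1,0.04,0.00,25
heneicosanoic acid,C21:0,0.00,0.00,25
behenic acid,C22:0,0.02,0.00,25
lignoceric acid,C24:0,0.05,0.00,25
caproic acid,C6:0,0.38,0.03,50
caprylic acid,C8:0,8.05,0.63,50
capric acid,C10:0,7.12,0.13,50
undecylic acid,C11:0,0.03,0.00,50
lauric acid,C12:0,50.07,4.0,50
tridecylic acid,C13:0,0.04,0.00,50
myristic acid,C14:0,14.16,1.35,50
palmitic acid,C16:0,6.98,0.99,50
stearic acid,C18:0,2.95,0.76,50
oleic acid,C18:1,8.04,1.02,50
linoleic acid,C18:2,1.92,0.17,50
arachidic acid,C20:0,0.06,0.00,50
eicosenoic acid,C20:1,0.04,0.00,50
heneicosanoic acid,C21:0,0.07,0.00,50
behenic acid,C22:0,0.03,0.00,50
lignoceric acid,C24:0,0.07,0.01,50
caproic acid,C6:0,0.35,0.03,60
caprylic acid,C8:0,8.19,0.62,60
capric acid,C10:0,6.97,0.25,60
undecylic acid,C11:0,0.03,0.00,60
lauric acid,C12:0,49.60,2.1,60
tridecylic acid,C13:0,0.04,0.00,60
myristic acid,C14:0,14.28,0.52,60
palmitic acid,C16:0,7.12,0.78,60
stearic acid,C18:0,3.04,0.41,60
oleic acid,C18:1,8.24,0.54,60
linoleic acid,C18:2,2.02,0.09,60
arachidic acid,C20:0,0.05,0.00,60
eicosenoic acid,C20:1,0.04,0.00,60
heneicosanoic acid,C21:0,0.00,0.00,60
behenic acid,C22:0,0.00,0.00,60
lignoceric acid,C24:0,0.03,0.00,60
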