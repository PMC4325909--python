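Reference,AIS maximum fast Na+ conductance (S/cm2),Soma maximum fast Na+ conductance (S/cm2)
Dodge and Cooley 1973,0.6,0.07
Traub 1977,0.6,0.2
Fleshman et al. 1988,,0.03
Booth et al. 1997,,0.12
Safronov et al. 2000,1.32,0.002
McIntyre and Grill 2002,0.5,0.05
ElBasiouny et al. 2005,1.34,0.06
Shapiro and Lee 2007,0.005,0.006
Cisi and Kohn 2008,,0.03
Powers et al. 2012,0.55,0.044
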