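product,capsaicin,dihydrocapsaicin,total,study
Tabasco sauce,12,8,20,Betts 1999
sweet hot chili sauce,1.44,0.90,2.34,Ham et al. 2011
sweet hot chili sauce,0.49,0.37,0.86,Ham et al. 2011
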