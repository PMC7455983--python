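cultivar,color,study,is_mean,capsaicin_dry,dihydrocapsaicin_dry,total_dry,dhc_imputed,moisture_factor,capsaicin_wet,dihydrocapsaicin_wet,total_wet
Korean chili pepper,green,Jeon and Lee 2009,0,32.03,16.61,48.64,0,0.10,3.20,1.66,4.86
Korean chili pepper,red,Lee et al. 2016,0,38.07,19.04,57.11,1,0.17,6.47,3.24,9.71
Cheongyang chili pepper,red,Jeon and Lee 2009,0,278.81,72.01,350.82,0,0.11,30.67,7.92,38.59
Cheongyang chili pepper,red,Chung and Kang 2000,0,200,60,260,1,0.11,22.00,6.60,28.60
Cheongyang chili pepper,red,Hwang et al. 2011,0,195.27,67.01,262.28,0,0.11,21.48,7.37,28.85
Cheongyang chili pepper,red,Park et al. 2016,0,117.30,22.98,140.28,0,0.11,12.90,2.53,15.43
Cheongyang chili pepper,red,Mean,1,,55.50,253.35,0,,21.76,6.11,27.87
Shishito pepper,red,Kim et al. 2014,0,,,,0,,0.66,0.48,1.14
Shishito pepper,red,Park et al. 2016,0,15.35,7.79,23.14,0,0.12,1.84,0.93,2.78
Cucumber chili pepper,green,Park et al. 2016,0,0.00,0.00,0.00,0,0.08,0.00,0.00,0.00
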